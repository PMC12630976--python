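"""Bayesian-network core: ordering, sampling, fitting, exact inference."""

import numpy as np
import pandas as pd
import pytest

from simcalib import (
    BayesianNetwork,
    CPT,
    DAGStructure,
    TabularDataset,
    Variable,
    exact_marginals,
    fit_cpts,
    forward_sample,
    markov_boundary,
    topological_order,
)
from simcalib.fixtures import FixtureSpec, random_network

from conftest import TOY_NAMES, binary_dataset


class TestTopologicalOrder:
    def test_single_node(self):
        dag = DAGStructure(("A",), frozenset())
        assert topological_order(dag) == ["A"]

    def test_chain_has_unique_order(self):
        dag = DAGStructure(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}))
        assert topological_order(dag) == ["A", "B", "C"]

    @pytest.mark.parametrize("seed", range(5))
    def test_parents_precede_children_on_random_dags(self, seed):
        net = random_network(FixtureSpec(n_nodes=8, edge_probability=0.4, seed=seed))
        order = topological_order(net.structure)
        pos = {n: i for i, n in enumerate(order)}
        # brute-force edge scan
        assert all(pos[p] < pos[c] for p, c in net.structure.edges)

    def test_cycle_is_rejected_and_named(self):
        with pytest.raises(ValueError, match="cycle"):
            DAGStructure(("A", "B"), frozenset({("A", "B"), ("B", "A")}))


class TestDomainTypes:
    def test_cpt_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CPT("A", (), np.array([0.5, 0.4]))

    def test_cpt_entries_must_be_probabilities(self):
        with pytest.raises(ValueError, match="outside"):
            CPT("A", (), np.array([1.5, -0.5]))

    def test_network_validates_cpt_parent_match(self):
        a, b = Variable("A", ("0", "1")), Variable("B", ("0", "1"))
        dag = DAGStructure(("A", "B"), frozenset({("A", "B")}))
        cpts = {
            "A": CPT("A", (), np.array([0.5, 0.5])),
            "B": CPT("B", (), np.array([0.5, 0.5])),  # should have parent A
        }
        with pytest.raises(ValueError, match="parents"):
            BayesianNetwork((a, b), dag, cpts)

    def test_dataset_rejects_undeclared_levels(self):
        frame = pd.DataFrame({"A": ["0", "2"]})
        with pytest.raises(ValueError, match="undeclared"):
            TabularDataset(frame, {"A": ("0", "1")})


class TestForwardSample:
    def test_degenerate_cpts_give_constant_rows(self):
        a, b = Variable("A", ("0", "1")), Variable("B", ("0", "1"))
        dag = DAGStructure(("A", "B"), frozenset({("A", "B")}))
        cpts = {
            "A": CPT("A", (), np.array([0.0, 1.0])),
            "B": CPT("B", ("A",), np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        bn = BayesianNetwork((a, b), dag, cpts)
        ds = forward_sample(bn, 50, 0)
        assert (ds.data["A"] == "1").all() and (ds.data["B"] == "1").all()

    def test_same_seed_is_bit_identical(self, toys):
        d1 = forward_sample(toys["sprinkler4"], 500, 7)
        d2 = forward_sample(toys["sprinkler4"], 500, 7)
        pd.testing.assert_frame_equal(d1.data, d2.data)

    @pytest.mark.parametrize("name", TOY_NAMES)
    def test_empirical_marginals_match_enumeration(self, toys, name):
        """Sampling consistency: within 4 SE of the exact marginal at n=20k."""
        bn = toys[name]
        n = 20_000
        ds = forward_sample(bn, n, 11)
        exact = exact_marginals(bn)
        for var in bn.variables:
            counts = ds.data[var.name].value_counts()
            for j, level in enumerate(var.levels):
                p = exact[var.name][j]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                emp = counts.get(level, 0) / n
                assert abs(emp - p) < 4 * se + 1e-9

    def test_rejects_nonpositive_n(self, toys):
        with pytest.raises(ValueError):
            forward_sample(toys["chain3"], 0, 0)


class TestFitCpts:
    def test_point_mass_single_node(self):
        ds = binary_dataset({"A": np.ones(100)})
        dag = DAGStructure(("A",), frozenset())
        bn = fit_cpts(dag, ds)
        assert np.allclose(bn.cpts["A"].probs, [0.0, 1.0])

    def test_unseen_parent_config_falls_back_to_uniform(self):
        # A constant at 0, so config A=1 for B is never observed
        ds = binary_dataset({"A": np.zeros(50), "B": np.ones(50)})
        dag = DAGStructure(("A", "B"), frozenset({("A", "B")}))
        bn = fit_cpts(dag, ds)
        assert np.allclose(bn.cpts["B"].probs[1], [0.5, 0.5])
        assert np.allclose(bn.cpts["B"].probs[0], [0.0, 1.0])

    def test_pseudo_count_smooths(self):
        ds = binary_dataset({"A": np.ones(10)})
        dag = DAGStructure(("A",), frozenset())
        bn = fit_cpts(dag, ds, pseudo_count=1.0)
        assert np.allclose(bn.cpts["A"].probs, [1 / 12, 11 / 12])

    def test_domains_override_keeps_rare_levels(self):
        frame = pd.DataFrame({"A": ["0"] * 20})
        ds = TabularDataset(frame, {"A": ("0", "1")})
        dag = DAGStructure(("A",), frozenset())
        bn = fit_cpts(dag, ds, domains={"A": ("0", "1", "2")})
        assert bn.variable("A").levels == ("0", "1", "2")
        assert np.allclose(bn.cpts["A"].probs, [1.0, 0.0, 0.0])

    def test_recovery_error_decreases_with_n(self, toys):
        """Parameter recovery converges on data sampled from the truth."""
        bn = toys["chain3"]
        errs = []
        for n in (1_000, 10_000, 100_000):
            ds = forward_sample(bn, n, 13)
            fitted = fit_cpts(bn.structure, ds, domains=bn.domains)
            errs.append(
                max(
                    float(np.abs(fitted.cpts[v].probs - bn.cpts[v].probs).max())
                    for v in bn.structure.nodes
                )
            )
        assert errs[0] > errs[1] > errs[2]


class TestExactMarginals:
    def test_single_node(self):
        a = Variable("A", ("x", "y"))
        bn = BayesianNetwork(
            (a,),
            DAGStructure(("A",), frozenset()),
            {"A": CPT("A", (), np.array([0.3, 0.7]))},
        )
        assert np.allclose(exact_marginals(bn)["A"], [0.3, 0.7])

    def test_two_node_hand_enumeration(self, toys):
        # P(B=1) = 0.6 * 0.9 + 0.4 * 0.2 = 0.62
        m = exact_marginals(toys["chain3"])
        assert np.isclose(m["B"][1], 0.62)
        assert np.isclose(m["C"][1], 0.62 * 0.8 + 0.38 * 0.1)

    def test_vectors_sum_to_one(self, toys):
        for name in TOY_NAMES:
            for vec in exact_marginals(toys[name]).values():
                assert np.isclose(vec.sum(), 1.0, atol=1e-9)

    def test_refuses_large_state_space(self):
        net = random_network(FixtureSpec(n_nodes=25, edge_probability=0.1, seed=0))
        with pytest.raises(ValueError, match="state space"):
            exact_marginals(net, max_states=10_000)


class TestMarkovBoundary:
    def test_isolated_node(self):
        dag = DAGStructure(("A", "B"), frozenset())
        mb = markov_boundary(dag, "A")
        assert mb == {"parents": (), "children": (), "spouses": ()}

    def test_collider_child(self, toys):
        mb = markov_boundary(toys["collider3"].structure, "C")
        assert mb["parents"] == ("A", "B")
        assert mb["children"] == () and mb["spouses"] == ()

    def test_hub_spouses(self, toys):
        mb = markov_boundary(toys["sprinkler4"].structure, "sprinkler")
        assert mb["parents"] == ("cloudy",)
        assert mb["children"] == ("wet",)
        assert mb["spouses"] == ("rain",)
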