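"""Meta-simulation orchestrator.

Runs the full loop under one configuration: the ground-truth reference
(``N_truth`` fresh draws from the known DGP), the limited-real strategy
(``N_practitioner`` small datasets shared by all strategies), and one
SL-based strategy per registered learner — then assembles bias, centred
performance, ranking and fidelity reports. Everything derives from one root
seed through the hierarchical seeding scheme, so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import (
    MLMethodSpec,
    StrategyEstimates,
    centered_estimates,
    default_methods,
    delta_bias,
    ground_truth_estimate,
    methods_from_config,
    practitioner_estimate,
    rank_consistency,
    rank_orders,
    sl_estimate,
)
from .bn import BayesianNetwork, TabularDataset, forward_sample, markov_boundary
from .bif import read_bif
from .fidelity import FidelitySummary, fidelity_report
from .fixtures import FixtureSpec, auto_target, random_network, toy_network
from .seeding import child_rng
from .structure import LEARNERS

__all__ = ["ExperimentConfig", "ResultBundle", "run_metasimulation", "select_target_report", "emit_reports"]

log = logging.getLogger("simcalib")

#: Desk-scale preset: completes in minutes on one CPU while preserving the
#: nesting of the full design (the full-scale defaults live on
#: ExperimentConfig itself).
DESK_PRESET = {"n_truth": 50, "n_practitioner": 5, "n_sl": 10, "n_train": 100, "n_test": 100}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one meta-simulation run."""

    network: "str | dict | BayesianNetwork"  # BIF path, fixture spec, toy name
    target: str | None = None  # None -> auto (largest Markov boundary)
    learners: tuple[str, ...] = ("hc", "tabu", "pc.stable", "mmhc")
    methods: tuple[MLMethodSpec, ...] = ()
    n_train: int = 200
    n_test: int = 200
    n_practitioner: int = 10
    n_sl: int = 500
    n_truth: int = 1000
    seed: int = 42
    pseudo_count: float = 0.0
    learner_config: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            self.methods = tuple(default_methods())
        for c in (self.n_train, self.n_test, self.n_practitioner, self.n_sl, self.n_truth):
            if c < 1:
                raise ValueError("all counts must be >= 1")
        unknown = [l for l in self.learners if l not in LEARNERS]
        if unknown:
            raise ValueError(f"unknown learners {unknown}; registry has {sorted(LEARNERS)}")

    @staticmethod
    def from_yaml(path: "str | Path") -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        methods = ()
        if "methods" in raw:
            methods = tuple(methods_from_config(raw.pop("methods")))
        known = {
            "network", "target", "learners", "n_train", "n_test",
            "n_practitioner", "n_sl", "n_truth", "seed", "pseudo_count",
            "learner_config", "output_dir",
        }
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys {sorted(extra)}")
        if "learners" in raw:
            raw["learners"] = tuple(raw["learners"])
        return ExperimentConfig(methods=methods, **raw)

    def resolve_network(self) -> BayesianNetwork:
        if isinstance(self.network, BayesianNetwork):
            return self.network
        if isinstance(self.network, dict):
            return random_network(FixtureSpec(**self.network))
        if isinstance(self.network, str) and self.network.endswith(".bif"):
            return read_bif(self.network)
        return toy_network(str(self.network))

    def resolve_target(self, bn: BayesianNetwork) -> str:
        if self.target is None:
            return auto_target(bn)
        if self.target not in bn.structure.nodes:
            raise ValueError(f"target {self.target!r} not a node of the network")
        return self.target

    def fingerprint(self) -> str:
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("network", "output_dir")
        }
        payload["network"] = self.network if not isinstance(self.network, BayesianNetwork) else "<inline>"
        payload["methods"] = [[m.id, m.algorithm, list(m.params)] for m in self.methods]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All outputs of one run, sufficient to re-derive every report."""

    config_fingerprint: str
    target: str
    truth: StrategyEstimates
    practitioner: StrategyEstimates
    sl: dict[str, StrategyEstimates]
    fidelity: list[FidelitySummary]
    learned_structures: dict[str, list]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def strategies(self) -> dict[str, StrategyEstimates]:
        out = {"true": self.truth, "prac": self.practitioner}
        out.update(self.sl)
        return out

    def delta_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.strategies.items():
            if name == "true":
                continue
            for m, d in delta_bias(est, self.truth).items():
                rows.append({"strategy": name, "method": m, "delta": d})
        return pd.DataFrame(rows)

    def centred_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.strategies.items():
            for m, v in centered_estimates(est).items():
                rows.append({"strategy": name, "method": m, "centred": v})
        return pd.DataFrame(rows)

    def rank_table(self) -> pd.DataFrame:
        frames = []
        for name, est in self.strategies.items():
            per_rep = name != "true"
            ranks = rank_orders(est, per_repetition=per_rep)
            ranks.insert(0, "repetition", range(len(ranks)))
            ranks.insert(0, "strategy", name)
            frames.append(ranks)
        return pd.concat(frames, ignore_index=True)

    def accuracy_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.strategies.items():
            for m, vals in est.values.items():
                for rep, acc in enumerate(vals):
                    rows.append(
                        {"method": m, "strategy": name, "repetition": rep, "accuracy": acc}
                    )
        return pd.DataFrame(rows)

    def rank_consistency_summary(self) -> pd.DataFrame:
        truth_ranks = rank_orders(self.truth)
        rows = []
        for name, est in self.strategies.items():
            if name == "true":
                continue
            rc = rank_consistency(rank_orders(est, per_repetition=True), truth_ranks)
            rows.append(
                {
                    "strategy": name,
                    "exact_match_fraction": rc.exact_match_fraction,
                    "mean_displacement": rc.mean_displacement,
                }
            )
        return pd.DataFrame(rows)


def select_target_report(bn: BayesianNetwork, candidate: str) -> dict:
    """Markov-boundary description of a candidate target node."""
    mb = markov_boundary(bn.structure, candidate)
    return {
        "node": candidate,
        **{k: list(v) for k, v in mb.items()},
        "boundary_size": sum(len(v) for v in mb.values()),
    }


def run_metasimulation(config: ExperimentConfig) -> ResultBundle:
    """Execute the full meta-simulation loop for one configuration.

    Stages: (1) ground-truth reference; (2) draw the ``N_practitioner``
    limited datasets once — every strategy consumes the same ones (paired
    comparison); (3) limited-real estimates; (4) per learner, the SL
    estimates plus structural/distributional fidelity; (5) reports are then
    derivable from the bundle. A learner that fails on every practitioner
    dataset is recorded in ``failures`` and the bundle stays partial.
    """
    bn = config.resolve_network()
    target = config.resolve_target(bn)
    seed = config.seed
    methods = list(config.methods)

    log.info("ground-truth reference: %d repetitions", config.n_truth)
    truth = ground_truth_estimate(
        bn, methods, target, config.n_truth, config.n_train, config.n_test, seed
    )

    # one shared set of limited datasets; each is a practitioner's whole world
    limited: list[TabularDataset] = []
    for i in range(config.n_practitioner):
        rng = child_rng(seed, "practitioner", i)
        ds = forward_sample(bn, config.n_train + config.n_test, rng)
        limited.append(ds.with_split(config.n_train, config.n_test, target))

    log.info("limited-real strategy: %d practitioners", config.n_practitioner)
    prac = practitioner_estimate(limited, methods, seed)

    sl: dict[str, StrategyEstimates] = {}
    learned: dict[str, list] = {}
    synthetic: dict[str, list] = {}
    failures: dict[str, str] = {}
    for learner in config.learners:
        log.info("SL strategy %r: %d x %d repetitions", learner, config.n_practitioner, config.n_sl)
        try:
            est, structures, synth = sl_estimate(
                limited,
                learner,
                methods,
                config.n_sl,
                config.n_train,
                config.n_test,
                seed,
                domains=bn.domains,
                learner_config=config.learner_config,
                pseudo_count=config.pseudo_count,
                collect_structures=True,
                collect_synthetic=True,
            )
        except Exception as exc:  # noqa: BLE001 — partial bundles are a contract
            log.error("learner %r failed: %s", learner, exc)
            failures[learner] = str(exc)
            continue
        sl[learner] = est
        learned[learner] = structures
        synthetic[learner] = synth

    fidelity = fidelity_report(
        bn, learned, real_data=limited[0] if limited else None,
        synthetic_data=synthetic,
    ) if learned else []

    return ResultBundle(
        config_fingerprint=config.fingerprint(),
        target=target,
        truth=truth,
        practitioner=prac,
        sl=sl,
        fidelity=fidelity,
        learned_structures=learned,
        failures=failures,
    )


_F = "%.12g"  # stable float formatting so identical runs emit identical bytes


def emit_reports(bundle: ResultBundle, outdir: "str | Path") -> list[Path]:
    """Write the bundle's CSV tables and JSON summary under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format=_F)
        written.append(path)

    _csv("accuracies.csv", bundle.accuracy_table())
    _csv("delta.csv", bundle.delta_table())
    _csv("centred.csv", bundle.centred_table())
    _csv("ranks.csv", bundle.rank_table())
    _csv("rank_consistency.csv", bundle.rank_consistency_summary())

    fid_rows = []
    for s in bundle.fidelity:
        for rep, v in enumerate(s.shd_values):
            js = s.js_values[rep] if rep < len(s.js_values) else float("nan")
            fid_rows.append({"learner": s.learner, "repetition": rep, "shd": v, "js": js})
    _csv("fidelity.csv", pd.DataFrame(fid_rows, columns=["learner", "repetition", "shd", "js"]))

    summary = {
        "config_fingerprint": bundle.config_fingerprint,
        "target": bundle.target,
        "mu": {name: est.mu for name, est in bundle.strategies.items()},
        "inter_practitioner_variance": {
            name: est.variance for name, est in bundle.strategies.items() if name != "true"
        },
        "skipped_repetitions": {name: est.skipped for name, est in bundle.sl.items()},
        "fidelity": {
            s.learner: {
                "shd_median": s.shd_median,
                "js_mean": s.js_mean,
                "js_variance": s.js_variance,
            }
            for s in bundle.fidelity
        },
        "failures": bundle.failures,
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written


def plot_reports(bundle: ResultBundle, outdir: "str | Path") -> list[Path]:
    """Optional convenience figures (boxplots of delta and centred values)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    delta = bundle.delta_table()
    if not delta.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        pivot = delta.pivot(index="method", columns="strategy", values="delta")
        pivot.plot.bar(ax=ax)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("bias in estimated accuracy")
        fig.tight_layout()
        p = out / "delta.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    acc = bundle.accuracy_table()
    fig, ax = plt.subplots(figsize=(7, 4))
    strategies = list(acc["strategy"].unique())
    data = [acc[acc["strategy"] == s]["accuracy"] for s in strategies]
    ax.boxplot(data, tick_labels=strategies)
    ax.set_ylabel("accuracy")
    fig.tight_layout()
    p = out / "accuracy_by_strategy.png"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)
    return written
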