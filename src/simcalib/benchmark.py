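"""Benchmark engine: train/evaluate candidate ML methods and compute the
strategy estimators.

Three estimators of a method's accuracy are compared:

* ``mu_true``  — asymptotic ground truth: mean accuracy over ``N_truth``
  fresh train/test draws from the known DGP;
* ``mu_prac``  — practitioner estimate: mean accuracy over the limited
  real datasets;
* ``mu_L``     — structure-learner (SL) estimate: for each limited dataset,
  infer a DGP, sample ``N_SL`` synthetic train/test pairs, average the
  accuracies, then average over practitioners (a double mean).

From these come the bias ``delta = mu_L - mu_true``, the centred
performance ``mu_tilde`` (per-strategy mean removed, isolating relative
ordering), and rank orders for ranking-consistency analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .bn import BayesianNetwork, TabularDataset, fit_cpts, forward_sample
from .seeding import child_int_seed, child_rng
from .structure import learn_structure

__all__ = [
    "MLMethodSpec",
    "AccuracyRecord",
    "StrategyEstimates",
    "default_methods",
    "build_estimator",
    "encode_features",
    "evaluate_accuracy",
    "evaluate_all",
    "ground_truth_estimate",
    "practitioner_estimate",
    "sl_estimate",
    "delta_bias",
    "centered_estimates",
    "rank_orders",
    "rank_consistency",
]

_ALGORITHMS = {
    "random-forest",
    "decision-tree",
    "multilayer-perceptron",
    "adaboost",
}


@dataclass(frozen=True)
class MLMethodSpec:
    """One candidate method: an algorithm plus a hyperparameter setting.

    Distinct hyperparameter settings of the same algorithm (e.g. the
    decision tree's gini vs entropy split criterion) are distinct candidates.
    """

    id: str
    algorithm: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {sorted(_ALGORITHMS)}"
            )

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @staticmethod
    def make(id: str, algorithm: str, **params) -> "MLMethodSpec":
        return MLMethodSpec(id, algorithm, tuple(sorted(params.items())))


def default_methods() -> list[MLMethodSpec]:
    """The default K=5 candidate roster.

    Four algorithm families; the decision tree appears twice (gini and
    entropy split criteria) as separate candidates. Ensemble sizes and the
    lbfgs-solver perceptron are sized for the few-hundred-row categorical
    tasks this package benchmarks, where small ensembles already saturate
    and lbfgs converges quickly and deterministically.
    """
    return [
        MLMethodSpec.make("random-forest", "random-forest", n_estimators=25),
        MLMethodSpec.make("decision-tree-gini", "decision-tree", criterion="gini"),
        MLMethodSpec.make("decision-tree-entropy", "decision-tree", criterion="entropy"),
        MLMethodSpec.make(
            "mlp", "multilayer-perceptron",
            solver="lbfgs", hidden_layer_sizes=(16,), max_iter=200,
        ),
        MLMethodSpec.make("adaboost", "adaboost", n_estimators=20),
    ]


def build_estimator(spec: MLMethodSpec, seed: int):
    params = spec.param_dict
    if spec.algorithm == "random-forest":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.algorithm == "decision-tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if spec.algorithm == "multilayer-perceptron":
        return MLPClassifier(random_state=seed, **params)
    return AdaBoostClassifier(random_state=seed, **params)


def methods_from_config(entries: "list[dict]") -> list[MLMethodSpec]:
    """Build the method roster from config entries ``{id, algorithm, params}``."""
    specs = [
        MLMethodSpec.make(e["id"], e["algorithm"], **e.get("params", {}))
        for e in entries
    ]
    keys = [(s.algorithm, s.params) for s in specs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (algorithm, hyperparameters) pair in method roster")
    if len({s.id for s in specs}) != len(specs):
        raise ValueError("duplicate method id in roster")
    return specs


@dataclass(frozen=True)
class AccuracyRecord:
    method: str
    dataset: str
    accuracy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def encode_features(dataset: TabularDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-hot encode non-target columns over the declared level domains.

    Column order is deterministic: variables in dataset order, levels in
    declaration order — so encodings are comparable across datasets sharing
    a domain. Returns ``(X, y, feature_columns)`` with X covering all rows
    (callers slice the train/test split).
    """
    feat_cols = [c for c in dataset.columns if c != dataset.target]
    codes = dataset.codes(feat_cols)
    blocks = []
    for j, col in enumerate(feat_cols):
        card = len(dataset.domains[col])
        onehot = np.zeros((codes.shape[0], card))
        onehot[np.arange(codes.shape[0]), codes[:, j]] = 1.0
        blocks.append(onehot)
    X = np.hstack(blocks) if blocks else np.zeros((len(dataset.data), 0))
    y = dataset.data[dataset.target].to_numpy()
    return X, y, np.asarray(feat_cols, dtype=object)


def evaluate_accuracy(
    method: MLMethodSpec, dataset: TabularDataset, seed: int = 42
) -> AccuracyRecord:
    """Train on the train split, score accuracy on the test split.

    A single-class training target is legal: the fitted model is then a
    constant predictor.
    """
    if dataset.target is None:
        raise ValueError("dataset has no target column")
    if dataset.n_test < 1:
        raise ValueError("dataset has no test split")
    X, y, _ = encode_features(dataset)
    acc = _fit_score(method, X, y, dataset.n_train, dataset.n_test, seed)
    return AccuracyRecord(method.id, "dataset", acc)


def _fit_score(method, X, y, n_tr, n_te, seed) -> float:
    est = build_estimator(method, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings logged, not raised
        est.fit(X[:n_tr], y[:n_tr])
        pred = est.predict(X[n_tr : n_tr + n_te])
    return float(np.mean(pred == y[n_tr : n_tr + n_te]))


def evaluate_all(
    methods: "list[MLMethodSpec]", dataset: TabularDataset, seed: int = 42
) -> dict[str, float]:
    """Accuracy of every method on one dataset (features encoded once)."""
    X, y, _ = encode_features(dataset)
    return {
        m.id: _fit_score(m, X, y, dataset.n_train, dataset.n_test, seed)
        for m in methods
    }


@dataclass
class StrategyEstimates:
    """Per-method accuracy summaries for one strategy.

    ``values[m]`` holds one accuracy per repetition: ground-truth draws for
    the truth strategy, practitioner datasets for the limited-real strategy,
    and per-practitioner *inner means* (over the N_SL synthetic samples) for
    an SL strategy.
    """

    strategy: str
    values: dict[str, np.ndarray]
    n_inner: int = 1  # N_SL for SL strategies, 1 otherwise
    skipped: int = 0  # practitioner repetitions skipped due to learner failure

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.values.values()}
        if len(lengths) > 1:
            raise ValueError("methods disagree on repetition count")
        self.values = {m: np.asarray(v, dtype=float) for m, v in self.values.items()}

    @property
    def methods(self) -> list[str]:
        return list(self.values)

    @property
    def n_repetitions(self) -> int:
        return len(next(iter(self.values.values())))

    @property
    def mu(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.values.items()}

    @property
    def variance(self) -> dict[str, float]:
        """Inter-repetition (e.g. inter-practitioner) variance per method."""
        return {
            m: float(np.var(v, ddof=1)) if len(v) > 1 else 0.0
            for m, v in self.values.items()
        }


def _split_sample(
    bn: BayesianNetwork, target: str, n_train: int, n_test: int, rng
) -> TabularDataset:
    ds = forward_sample(bn, n_train + n_test, rng)
    return ds.with_split(n_train, n_test, target)


def ground_truth_estimate(
    bn: BayesianNetwork,
    methods: "list[MLMethodSpec]",
    target: str,
    n_truth: int,
    n_train: int,
    n_test: int,
    root_seed: int,
) -> StrategyEstimates:
    """Asymptotic reference: mean accuracy over ``n_truth`` fresh draws."""
    if n_truth < 1:
        raise ValueError("n_truth must be >= 1")
    vals: dict[str, list[float]] = {m.id: [] for m in methods}
    for i in range(n_truth):
        rng = child_rng(root_seed, "truth", i)
        ds = _split_sample(bn, target, n_train, n_test, rng)
        accs = evaluate_all(methods, ds, child_int_seed(root_seed, "ml-eval"))
        for m, a in accs.items():
            vals[m].append(a)
    return StrategyEstimates("true", {m: np.array(v) for m, v in vals.items()})


def practitioner_estimate(
    limited_datasets: "list[TabularDataset]",
    methods: "list[MLMethodSpec]",
    root_seed: int = 42,
) -> StrategyEstimates:
    """Limited-real strategy: mean accuracy across the practitioner datasets."""
    if not limited_datasets:
        raise ValueError("need at least one limited dataset")
    vals: dict[str, list[float]] = {m.id: [] for m in methods}
    for i, ds in enumerate(limited_datasets):
        accs = evaluate_all(methods, ds, child_int_seed(root_seed, "ml-eval"))
        for m, a in accs.items():
            vals[m].append(a)
    return StrategyEstimates("prac", {m: np.array(v) for m, v in vals.items()})


def sl_estimate(
    limited_datasets: "list[TabularDataset]",
    learner: str,
    methods: "list[MLMethodSpec]",
    n_sl: int,
    n_train: int,
    n_test: int,
    root_seed: int,
    domains: "dict[str, tuple[str, ...]] | None" = None,
    learner_config: "dict | None" = None,
    pseudo_count: float = 0.0,
    collect_structures: bool = False,
    collect_synthetic: bool = False,
):
    """SL-based strategy: learn a DGP per practitioner, benchmark on samples.

    For practitioner i: learn a structure on the full limited dataset, fit
    CPTs (level domains from ``domains`` if given, e.g. the ground truth's
    codebook), forward-sample ``n_sl`` fresh train/test pairs, and average
    accuracy over them. ``mu`` is then the mean of those inner means. A
    learner failure on one dataset skips that practitioner repetition (with
    a warning) and is counted in ``skipped``.

    Returns ``StrategyEstimates`` — plus the learned structures and/or the
    first synthetic dataset per practitioner when the collect flags are set.
    """
    if n_sl < 1:
        raise ValueError("n_sl must be >= 1")
    if not limited_datasets:
        raise ValueError("need at least one limited dataset")
    target = limited_datasets[0].target
    vals: dict[str, list[float]] = {m.id: [] for m in methods}
    structures = []
    synthetic = []
    skipped = 0
    for i, real in enumerate(limited_datasets):
        cfg = dict(learner_config or {})
        cfg.setdefault("seed", child_int_seed(root_seed, "sl-learn", i))
        try:
            dag = learn_structure(learner, real, cfg)
            fitted = fit_cpts(dag, real, pseudo_count=pseudo_count, domains=domains)
        except Exception as exc:  # noqa: BLE001 — learner failures are data-dependent
            warnings.warn(
                f"learner {learner!r} failed on practitioner dataset {i}: {exc}",
                stacklevel=2,
            )
            skipped += 1
            continue
        structures.append(dag)
        inner: dict[str, list[float]] = {m.id: [] for m in methods}
        for j in range(n_sl):
            rng = child_rng(root_seed, "sl-sample", i, j)
            ds = _split_sample(fitted, target, n_train, n_test, rng)
            if collect_synthetic and j == 0:
                synthetic.append(ds)
            accs = evaluate_all(methods, ds, child_int_seed(root_seed, "ml-eval"))
            for m, a in accs.items():
                inner[m].append(a)
        for m in inner:
            vals[m].append(float(np.mean(inner[m])))
    if all(len(v) == 0 for v in vals.values()):
        raise RuntimeError(f"learner {learner!r} failed on every practitioner dataset")
    est = StrategyEstimates(
        learner, {m: np.array(v) for m, v in vals.items()}, n_inner=n_sl, skipped=skipped
    )
    out = [est]
    if collect_structures:
        out.append(structures)
    if collect_synthetic:
        out.append(synthetic)
    return est if len(out) == 1 else tuple(out)


def delta_bias(
    estimate: StrategyEstimates, truth: StrategyEstimates
) -> dict[str, float]:
    """Bias in absolute performance: ``delta = mu_estimate - mu_true``.

    Positive values mean the strategy *overestimates* accuracy.
    """
    if set(estimate.values) != set(truth.values):
        raise ValueError("method sets differ between strategies")
    mu_e, mu_t = estimate.mu, truth.mu
    return {m: mu_e[m] - mu_t[m] for m in estimate.values}


def centered_estimates(est: StrategyEstimates) -> dict[str, float]:
    """Centred performance: each method's mean minus the across-method mean.

    The centred values sum to zero, isolating relative ordering from the
    strategy's absolute bias.
    """
    if len(est.values) < 2:
        raise ValueError("centring needs at least two methods")
    mu = est.mu
    grand = float(np.mean(list(mu.values())))
    return {m: mu[m] - grand for m in mu}


def _rank_descending(values: np.ndarray) -> np.ndarray:
    # rank 1 = highest accuracy; ties get the average rank
    return rankdata(-values, method="average")


def rank_orders(
    est: StrategyEstimates, per_repetition: bool = False
) -> pd.DataFrame:
    """Rank methods by accuracy (1 = best, ties averaged).

    With ``per_repetition`` the ranking is computed within each repetition
    (each practitioner), yielding one row per repetition; otherwise a single
    row ranks the per-method means.
    """
    if len(est.values) < 2:
        raise ValueError("ranking needs at least two methods")
    methods = est.methods
    if per_repetition:
        mat = np.column_stack([est.values[m] for m in methods])
        ranks = np.vstack([_rank_descending(row) for row in mat])
        return pd.DataFrame(ranks, columns=methods)
    mu = np.array([est.mu[m] for m in methods])
    return pd.DataFrame([_rank_descending(mu)], columns=methods)


@dataclass
class RankConsistency:
    """Agreement between a strategy's rankings and the truth ranking."""

    exact_match_fraction: float
    mean_displacement: float
    rank_frequency: pd.DataFrame  # methods x ranks, counts over repetitions


def rank_consistency(
    strategy_ranks: pd.DataFrame, truth_ranks: pd.DataFrame
) -> RankConsistency:
    """Compare per-repetition rankings against the (single-row) truth ranking."""
    if list(strategy_ranks.columns) != list(truth_ranks.columns):
        raise ValueError("rank tables must cover the same methods in the same order")
    truth = truth_ranks.iloc[0].to_numpy()
    mat = strategy_ranks.to_numpy()
    exact = float(np.mean([np.array_equal(row, truth) for row in mat]))
    displacement = float(np.mean(np.abs(mat - truth)))
    methods = list(strategy_ranks.columns)
    k = len(methods)
    freq = np.zeros((k, k), dtype=int)
    for row in mat:
        for j, r in enumerate(row):
            freq[j, int(round(r)) - 1] += 1
    table = pd.DataFrame(
        freq, index=methods, columns=[f"rank_{i + 1}" for i in range(k)]
    )
    return RankConsistency(exact, displacement, table)
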