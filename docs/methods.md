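# Methods

## The meta-simulation model

`simcalib` studies a question about *benchmarking itself*: when a
practitioner has only a small observational sample, how should they choose
among candidate ML classifiers? The package frames this as a
meta-simulation. A known discrete Bayesian network — a DAG over categorical
variables with one conditional probability table (CPT) per node — plays the
role of the true data-generating process (DGP). Three estimators of each
method's accuracy are then compared:

- **ground truth** `mu^true_M = (1/N_truth) * sum_i Acc(M, D_GT^(i))`,
  the mean accuracy over `N_truth` fresh train/test pairs forward-sampled
  from the true DGP — the asymptotic reference an all-knowing investigator
  could compute;
- **limited-real** `mu^prac_M = (1/N_prac) * sum_i Acc(M, D_small^(i))`,
  the mean over the `N_prac` small datasets the practitioners actually hold;
- **SL-based** `mu^L_M = (1/N_prac) * sum_i (1/N_SL) * sum_j Acc(M, D_L^(i,j))`,
  where each practitioner first runs a structural learner `L` on their
  limited data, fits CPTs to obtain an approximated DGP, and benchmarks on
  `N_SL` synthetic train/test pairs sampled from it (a double mean).

Derived statistics: the bias `delta^L_M = mu^L_M - mu^true_M` (positive =
overestimation), the centred performance
`mu~^X_M = mu^X_M - (1/K) sum_k mu^X_{M_k}` (sums to zero per strategy;
isolates relative ordering from absolute bias), and rank orders
`r^X(M) = rank(mu^X_M)` with rank 1 = best and average ranks on ties.
Ranking consistency against the truth ranking is summarised by the
exact-match fraction, the mean absolute rank displacement, and a
method-by-rank frequency table.

The limited-real strategy is unbiased by construction (its datasets are
draws from the true DGP) but has high inter-practitioner variance at small
n; the SL strategies may be biased (the inferred DGP is wrong) but can
resample arbitrarily, trading bias for variance. Quantifying that
trade-off is the purpose of the orchestrated experiment.

### Loop structure and the shared-sample discipline

One run draws the `N_practitioner` limited datasets **once** and feeds the
same datasets to the limited-real strategy and to every SL strategy, so
strategy comparisons are paired. Per-practitioner values are retained: for
the limited-real strategy these are single accuracies, for an SL strategy
they are the inner means over the `N_SL` synthetic samples. Rankings for
SL strategies are computed on those per-practitioner inner means (the
alternative — ranking each synthetic sample separately — measures a
different, noisier quantity; the inner mean is what a practitioner would
act on).

Each practitioner holds `N_train + N_test` rows. The limited-real strategy
trains on the first `N_train` and tests on the rest; the structural learner
consumes **all** of the practitioner's rows (a practitioner calibrating a
simulator would not discard their test split). This choice is configurable
and documented rather than hidden.

## Data model and sampling

Variables are categorical with a fixed, declaration-ordered level list;
rows store level labels, and encoding happens only at the ML boundary.
Forward (ancestral) sampling draws each node in topological order by
inverse-CDF lookup against the parent-configuration row of its CPT,
vectorised across rows. CPT fitting is maximum likelihood with an optional
symmetric pseudo-count `a`: `(count + a) / (total + a*card)`; a parent
configuration never observed (with `a = 0`) falls back to a uniform vector.
In meta-simulation mode the level domains come from the ground-truth
network's declarations, not from the limited sample — the practitioner is
assumed to know the variable codebooks, and rare unobserved levels must not
silently shrink the state space.

`exact_marginals` computes marginals by building the full joint as a
broadcast product over the topological order; it refuses state spaces above
10^6 configurations and exists as an oracle for tests, not as an inference
engine.

Networks round-trip through BIF (Bayesian Interchange Format 0.15) in the
repository dialect: `property` lines ignored, both `table` and
per-configuration `( ... )` probability rows accepted, rows validated to
sum to 1 within 1e-4 and renormalised exactly.

## Structure learning

One representative per family, implemented from first principles:

- **BIC score** (score-based searches): maximised multinomial
  log-likelihood of each family minus `(r-1) * q * ln(n) / 2`. The score is
  decomposable and direction-equivalent (A->B and B->A tie), which the
  tests assert.
- **Hill climbing**: greedy over add/delete/reverse single-edge moves from
  the empty graph, acyclicity preserved, `max_parents` capped (default 8 —
  the benchmark networks' in-degrees are small and the cap bounds CPT
  blow-up). Equal-score moves break ties by the lexicographically smallest
  `(operation, parent, child)` triple, so runs are reproducible.
- **Tabu search**: the same neighbourhood, but after the local optimum up
  to `max_worsening_moves` non-improving moves may be taken while a list of
  the last `tabu_length` inverse moves is forbidden; the best DAG visited
  is returned. Defaults `tabu_length = 10`, `max_worsening_moves = 10`;
  with both set to 0 it reduces exactly to hill climbing.
- **G² conditional-independence test** (constraint-based methods):
  `G2 = 2 * sum O ln(O/E)` within each conditioning stratum, compared to a
  chi-square. Degrees of freedom use the sparse-table correction — rows and
  columns with zero margins inside a stratum are dropped — keeping p-values
  conservative in sparse tables. Default `alpha = 0.05`.
- **PC-stable**: adjacency sets are frozen per conditioning-set size and
  removals applied at the end of each level, making the skeleton
  order-independent (asserted by a column-permutation test). V-structures
  are oriented from separating sets, then Meek rules 1–4 run to closure.
  Conditioning sets are capped at 3 by default: a few hundred rows cannot
  support larger contingency tables.
- **MMPC / MMHC**: the max-min heuristic grows a parents-and-children set
  by adding the candidate whose worst-case association over conditioning
  subsets is strongest, prunes false positives backward, applies the
  symmetric-AND correction, and hands the allowed-pair skeleton to hill
  climbing.

Constraint-based output is a partially directed graph; `pdag_to_dag`
extends it via Dor–Tarsi (choosing the largest-name eligible sink so
symmetric ties orient low-name -> high-name) with a deterministic
name-order fallback when no consistent extension exists. `cpdag_of` maps a
DAG to its Markov-equivalence class (v-structures + Meek closure).

The learner registry exposes `hc`, `tabu`, `pc.stable`, `mmhc` — one
score-based pair, one constraint-based and one hybrid representative.
`rsmax2`, `h2pc` and `gs` are deliberately not implemented; the registry is
a plain dict so they can be added without touching the orchestrator.

## Fidelity metrics

- **SHD** between DAGs compares each unordered node pair's state
  (absent / a->b / b->a); every mismatch is one edit (reversal costs 1).
  A CPDAG-vs-CPDAG variant behind `equivalence_class=True` additionally
  distinguishes compelled from reversible marks, for comparisons that
  should not punish within-class orientation differences.
- **Jensen–Shannon divergence** between real and synthetic data is the
  mean over variables of the base-2 JS divergence of the per-variable
  empirical marginals, so it lies in [0, 1]. Joint-distribution JS is
  intractable for networks of realistic size; the per-variable average is
  the package's documented choice, and summaries report the mean and
  variance across repetitions.

## Benchmark engine

Features are one-hot encoded over the *declared* level domains in
deterministic order (variable order x level order), avoiding spurious
ordinality and keeping encodings comparable across datasets. Accuracy is
the fraction correct on the test split after fitting on the train split —
no inner cross-validation (one fold by design). A single-class training
target is legal and yields a constant predictor.

The default roster has K = 5 candidates: random forest (25 trees), decision
tree with gini and with entropy split criteria (two distinct candidates —
hyperparameter variants are first-class methods), a one-hidden-layer
perceptron (16 units, lbfgs solver, max 200 iterations), and AdaBoost
(20 stumps). Ensemble sizes and the lbfgs solver are sized for the
few-hundred-row categorical tasks this package benchmarks: on such inputs
small ensembles already saturate accuracy, and lbfgs converges quickly and
deterministically where first-order solvers need many epochs. The roster is
YAML-configurable (`methods: [{id, algorithm, params}]`), so larger
variants are one config edit away.

The classifier seed is derived once per run from the root seed and shared
across repetitions: repetition-to-repetition variation should reflect
*dataset* resampling — the quantity under study — not classifier-internal
randomness, and identical datasets must yield identical accuracies.

## Determinism and seeding

All randomness derives from one root seed (default 42) through a named
tree of `numpy.random.SeedSequence` spawn keys: stage name (CRC-32 of a
string) then counters, e.g. `("sl-sample", i, j)` for practitioner i,
synthetic repetition j. Any single repetition can be re-created in
isolation, and two runs with the same configuration and root seed emit
byte-identical reports (asserted by the test suite). Integer seeds handed
to scikit-learn are reduced below 2^31.

## Fixtures and what they do (not) show

The fixture generator draws a DAG by Bernoulli edges along a random
permutation (acyclic by construction, in-degree capped) and fills CPTs with
symmetric-Dirichlet rows — small concentration gives strong, near-degenerate
dependencies; large gives near-uniform noise. The toy catalogue (`chain3`,
`collider3`, `sprinkler4`, `hub5`) is hand-specified with documented exact
marginals (e.g. chain3: P(B=1) = 0.6*0.9 + 0.4*0.2 = 0.62) for oracle
tests. `hub5` — a hub with four children of graded signal strength — is the
desk-scale benchmarking fixture; its hub node has the largest Markov
boundary and is auto-selected as the prediction target.

These fixtures emulate the *mechanics* of benchmarking on Bayesian-network
DGPs: categorical variables, sparse dependence, targets whose Markov
boundary drives predictability. They do not emulate the scale (tens to
hundreds of nodes), the heterogeneous CPT shapes, or the many
target-irrelevant variables of the repository networks, nor missingness or
selection effects of real clinical data. Passing tests therefore establish
correctness of the machinery and the direction of the variance/bias
effects at small scale, not effect sizes on any particular real network.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full
suite completes on a single CPU in minutes: the strategy-comparison
experiment uses hub5 with `N_truth = 200`, `N_practitioner = 10`,
`N_SL = 20`, train/test 100/100 and 20 meta-repetitions; the acceptance
script runs `N_truth = 100` with learners `hc` and `pc.stable`. The
full-scale configuration of record (`N_train = N_test = 200`,
`N_practitioner = 10`, `N_SL = 500`, `N_truth = 1000`, root seed 42) is
accepted by the config validator and runs unchanged — only wall-clock time
separates it from the presets.

## Numerical choices and degenerate inputs

- CPT rows must sum to 1 within 1e-9 internally (1e-4 on BIF ingest, then
  renormalised); sampling clamps the top of each row's CDF to 1 against
  round-off.
- Score and skeleton ties break lexicographically; improving moves require
  a gain above 1e-9 so float noise cannot cycle the search.
- G² with an empty effective table (all margins zero) reports df = 0 and
  p = 1 (no evidence against independence).
- `fit_cpts` on a structure node absent from the data, or a cell value
  outside the declared domain, is an error — never silently coerced.
- A structural learner that throws on one practitioner dataset skips that
  repetition (logged, counted in `skipped`); a learner failing on every
  dataset is recorded in the bundle's failure manifest and the remaining
  strategies still report.

## Known limitations

- Discrete variables only; no continuous or conditional-Gaussian nodes,
  and no latent-variable or interventional reasoning.
- Learner implementations follow the standard algorithm statements, not
  any particular library's internals; structure outputs can legitimately
  differ from other implementations in tie-break order.
- Per-variable-marginal JS cannot detect dependence-structure divergence
  between real and synthetic data at matched marginals.
- The rank exact-match fraction is strict (all K ranks must coincide);
  with closely matched candidates it is small for every strategy, and the
  displacement and frequency-table summaries are the informative ones.
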