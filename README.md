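# simcalib

Meta-simulation benchmarking of ML method selection for data-limited
settings.

## The problem

In domains like clinical research, practitioners often must choose an ML
method from a handful of candidates using only a small observational
sample — a few hundred rows. Benchmarking directly on that sample is
unbiased but extremely noisy; the method that wins on one 200-row split may
lose in deployment. An alternative is to *calibrate a simulator from the
data*: run a Bayesian-network structural learner (SL) on the sample, fit
conditional probability tables (CPTs), and benchmark candidates on
unlimited synthetic data from the inferred data-generating process (DGP).
That trades the sample-splitting variance for a bias whose size depends on
how well the learner recovered the DGP.

`simcalib` makes this trade-off measurable. It sets up a meta-simulation in
which the true DGP — a discrete Bayesian network — is known, so three
estimators of each method `M`'s accuracy can be compared:

- ground truth: `mu_M^true = mean_i Acc(M, D_GT^(i))` over `N_truth` fresh
  train/test draws from the true network,
- limited-real: `mu_M^prac = mean_i Acc(M, D_small^(i))` over
  `N_practitioner` small datasets,
- SL-based: `mu_M^L = mean_i mean_j Acc(M, D_L^(i,j))`, where each small
  dataset is used to infer a DGP from which `N_SL` synthetic train/test
  pairs are drawn.

Derived statistics: the bias `delta_M^L = mu_M^L - mu_M^true`, centred
performance `mu~_M^X` (per-strategy mean removed; isolates relative
ordering), rank orders `r^X(M)`, and two fidelity diagnostics — the
Structural Hamming Distance (SHD) between learned and true DAGs, and the
per-variable Jensen–Shannon divergence between real and synthetic data.

Everything is a plain Python API; structure learning (hill climbing, tabu
search, PC-stable, MMHC — each implemented from first principles with BIC
scoring and G² independence tests), BIF network I/O, forward sampling,
fixture generation and the experiment orchestrator are all importable.
A thin `simcalib` CLI wraps the orchestrator for shell use.

## Worked example

`examples/04_metasimulation.py` runs a desk-scale meta-simulation on the
bundled `hub5` fixture (a hub node with four children of graded signal
strength; the hub is the prediction target) with `N_truth=50`,
`N_practitioner=5`, `N_SL=10`, 100/100-row train/test splits, comparing
the limited-real strategy against hill-climb SL benchmarking:

```
$ python examples/04_metasimulation.py
target node: H

mean accuracy per strategy:
  true  random-forest=0.873  decision-tree-gini=0.870  decision-tree-entropy=0.871  mlp=0.874  adaboost=0.891
  prac  random-forest=0.852  decision-tree-gini=0.856  decision-tree-entropy=0.856  mlp=0.876  adaboost=0.884
  hc    random-forest=0.861  decision-tree-gini=0.856  decision-tree-entropy=0.858  mlp=0.858  adaboost=0.871

ranking consistency vs truth ranking:
strategy  exact_match_fraction  mean_displacement
    prac                   0.0               1.24
      hc                   0.0               1.00

fidelity of the hc-inferred DGPs:
  hc: SHD per practitioner [1, 1, 0, 2, 1], JS mean 0.0028
```

Reading it: all strategies agree AdaBoost is the strongest candidate here;
the SL strategy's per-method means sit within ~0.02 of the truth (the
`delta` table in the full output gives the signed bias per method), its
rankings displace methods by 1.0 rank on average versus 1.24 for the
limited-real strategy, and the inferred DGPs are structurally close to the
truth (SHD ≤ 2 of 4 true edges) with near-zero marginal JS divergence.

The other examples each demonstrate one capability: `01_sample_and_fit.py`
(forward sampling, CPT refitting, the exact-inference oracle),
`02_structure_learning.py` (all four learners and SHD),
`03_fidelity.py` (JS divergence of synthetic data). A YAML-configured run
is available from the shell:

```
simcalib run -c config.yaml --preset desk -o results/
```

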