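# Methods

## Dependence measures

### Distance correlation

For sample blocks X (n × p) and Y (n × q) the package computes the
empirical distance covariance from double-centered Euclidean distance
matrices,

    a_kl = |X_k − X_l|,   A_kl = a_kl − ā_k· − ā_·l + ā_··
    dCov²_n(X, Y) = (1/n²) Σ_kl A_kl B_kl,

and standardizes to dCor_n = dCov_n / √(dVar_n(X)·dVar_n(Y)), clamped
to [0, 1]. Distances are plain Euclidean norms (the definitional
weight exponent at its standard value); no bias-corrected or unbiased
dCov variant is offered. `dcov`/`dcor` accept multivariate blocks,
but network inference stays pairwise (p = q = 1).

Numerical conventions:

- A dCov² that comes out negative is floating round-off (magnitude
  below ~1e-12 in practice) and is clamped to 0 before the square root.
- If either block has zero distance variance (a constant gene), dCor
  is defined as 0: a degenerate variable is treated as independent of
  everything, so a flat expression profile can never be ranked as an
  edge.
- `dc_dependence_matrix` centers each gene's distance matrix once and
  reuses it across all pairs; cost is O(g·n² + g²·n²) time, O(g·n²)
  memory.

Estimator facts that matter for interpretation: dCor_n is consistent
but positively biased at finite n — under independence it concentrates
around c·n^(−1/2) (≈ 0.04 at n = 2000), while dCor²_n is unbiased to
O(1/n). Comparisons against the population closed form for bivariate
normal data are therefore made on the squared scale, which is also the
scale on which the closed form is published in the energy-statistics
literature. None of this affects inference, which only uses ranks.

### Mutual information

MI between two genes is estimated by discretizing each gene
independently and plugging the observed cell frequencies into the
discrete definition; results are in nats (the unit cancels in
rank-based inference). Defaults, both exposed as options:

- **Binning**: equal-width over [min, max], ⌈√n⌉ bins (`auto`); the
  last bin is closed so the maximum is included. Equal-frequency
  (quantile) binning is available for sensitivity checks.
- **Estimator**: plug-in. The Miller–Madow alternative applies the
  (K − 1)/(2n) entropy bias correction per term, adding
  (K_x + K_y − K_xy − 1)/(2n) to the MI (K_* = non-empty rows, columns,
  cells); negative corrected values are floored at 0.

Shrinkage, Schurmann–Grassberger, kernel and k-NN estimators, and MIC
are out of scope.

### The dependence matrix

Both measures produce a symmetric genes × genes matrix with the
diagonal forced to 0, so a self-pair can never enter the edge ranking
(the gold standards evaluated here contain no self-regulation).

## Network inference

All three algorithms map a dependence matrix to a symmetric
nonnegative score matrix; no thresholding is ever applied inside
inference because evaluation sweeps the entire ranking.

- **REL** passes the off-diagonal dependence values through unchanged
  (any rescaling would not change the ranking).
- **CLR**: for gene i, μ_i and σ_i are the mean and *population*
  standard deviation (divisor = the number of entries, n − 1 of them)
  of its off-diagonal row; z_i(j) = max(0, (M_ij − μ_i)/σ_i), with
  z = 0 when σ_i = 0; score_ij = √(z_i(j)² + z_j(i)²). This makes CLR
  exactly invariant to a global affine shift-and-scale of the matrix.
- **MRNET**: for each target t, regulators are forward-selected
  greedily maximizing s_j = M_tj − mean_{k∈selected} M_jk (redundancy
  0 at the first step), recording s_j at selection time; selection
  stops when the best criterion is ≤ 0 (so an all-zero matrix yields
  an empty network); ties break toward the lowest gene index for
  determinism. Unselected pairs score 0 and the final matrix is the
  elementwise maximum over the two target roles.

ARACNE-style DPI pruning, conditional/three-way MI variants and any
directionality assignment are out of scope.

## Evaluation

Gold standards are directed but every method here emits symmetric
scores, so directed gold edges are collapsed onto unordered pairs: a
pair is positive iff either direction is a labeled true regulation.
This is the only evaluation mode — offering a directed mode against
symmetric predictions would silently inflate metrics. Explicit
0-labeled rows and absent pairs are both negatives.

Every unordered pair of network genes becomes one ranking item, sorted
by descending score with lexicographic tie-break. Curves sweep the
distinct score thresholds; tied scores always enter the confusion
counts as a whole block and are never split. The ROC curve is
prepended (0, 0) and ends at (1, 1); its trapezoidal area equals the
tie-corrected Mann–Whitney probability (asserted against an
independent rank-based oracle in the tests). The PR area integrates
the same threshold sweep with linear interpolation in recall,
anchoring recall 0 at the first point's precision; step-function
(conservative) interpolation would give slightly lower PR areas, a
known source of small cross-implementation discrepancies in reported
PR values.

`confusion_at_threshold` cuts the ranking at the smallest whole-block
prefix whose TP rate reaches a target (e.g. 0.8) and reports the
confusion counts there — the fixed-TP-rate false-positive comparison
used for network plots.

## Synthetic benchmark generator

The simulator is a documented **stand-in** for external benchmark
generators (the DREAM in-silico pipelines, SynTReN): it reproduces
their experimental *design* — known acyclic topologies, knockout-style
steady-state expression, a noise knob — not their kinetics libraries,
and no number obtained on it should be read as a reproduction of any
external benchmark value.

**Topology.** `sample_topology(n_genes, n_edges, seed)` orders genes
G1..Gn and samples edges uniformly among pairs pointing from a lower
to a higher index (ordered-ancestor constraint ⇒ acyclic by
construction). Activation/repression signs are equiprobable. Kinetic
parameters per edge are drawn once, seeded: strength k ~ U(0.5, 2.0),
threshold θ ~ U(0.3, 1.5), Hill coefficient h ∈ {1, 2, 3, 4};
baselines ~ U(0.2, 1.0), all in the same arbitrary expression units.
Ranges were chosen once so that regulator levels straddle their
thresholds (responses are neither saturated nor flat) and effect sizes
are comparable to baselines.

**Steady state.** Genes are evaluated in topological order:

    x_t = max(0, baseline_t + Σ_regulators sign · k · link(x_reg))

with link built from the Hill occupancy u = x^h/(θ^h + x^h): `hill` →
u, `quadratic` → u², `sine` → sin(πu/2). Regulator aggregation is
additive (multiplicative AND-logic is a possible extension, not
implemented). Expression is floored at 0 to mimic nonnegative
abundance.

**Designs.** `knockout` = one wild-type sample plus one sample per
gene with that gene clamped to exactly 0 (null mutant), the clamp
propagating downstream — n_genes + 1 samples, emulating knockout
compendia. `random` = regulator-free genes drawn U(0, 2) per sample.
`pooled` = the knockout block padded with random samples up to
n_samples (the benchmark default: 11 + 39 = 50 samples for 10 genes).

**Noise.** `noise_sd` is *measurement* noise: centered Gaussian added
to the observed matrix after the noise-free latent steady states are
computed, then floored at 0; a null mutant still reads exactly 0.
Noise deliberately does not feed back into regulation — process noise
would add regulator variance and thus *signal*, making performance
non-monotone in the noise level, which contradicts what a noise knob
on a benchmark generator is meant to model. Consequences: at
noise_sd = 0 the knockout block is deterministic, and increasing noise
can only degrade inference.

**What passing benchmarks do and do not show.** The generator shares
with real knockout data the nonlinear, sparse, acyclic, signed
regulation structure and the perturbation design, but not: feedback
loops, combinatorial logic, unobserved regulators, mRNA/protein
dynamics, realistic microarray noise (multiplicative, correlated), or
SynTReN's interaction kinetics. The DC-vs-MI ordering measured on it
(30 replicates, 10 genes/10 edges, 50 pooled samples, noise 0.1:
mean ROC area ≈ 0.77–0.80 for DC vs ≈ 0.62–0.71 for MI across
REL/CLR/MRNET, recomputed by `scripts/acceptance.py`) demonstrates the
direction of the effect at desk scale, not any external benchmark's
absolute numbers. Reproduction of published DREAM3 knockout values
requires downloading that challenge's data and running the same
`infer`/`eval` pipeline on it (see the data/dream3 paths in
`tests/test_acceptance.py`).

**Determinism.** Every simulator output is a pure function of its
arguments and seed; `benchmark_ensemble` derives per-replicate seeds
from its single seed via `numpy` seed sequences, and CLI runs are
byte-identical at fixed seed and config.

## Problem sizes

Test-suite and acceptance-script runs use 10-gene/10-edge networks
with 50 samples and 30 replicates, and n = 2000 for the bivariate
normal check — sizes at which every quantity asserted (oracle
identities, closed-form limits, ensemble mean orderings) is stable
under the fixed seeds while the whole suite runs in seconds. The
implementation itself handles hundreds of genes; `mrnet_network` is
O(g³) per matrix and `dc_dependence_matrix` O(g²n²), so SynTReN-scale
inputs (200 genes, ~100 samples) remain practical.

## Known limitations

- Inference is pairwise and undirected; the multivariate capability of
  `dcov` (gene-set blocks) is exposed but unused by the algorithms.
- No significance testing (permutation p-values for dCor, per-edge
  confidence) — ranking quality only.
- The plug-in MI baseline inherits discretization bias; its absolute
  values depend on the bin rule, so only its ranking behaviour is
  comparable across settings.
- PR areas depend mildly on the interpolation convention (linear in
  recall here).
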