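# dcgrn

Gene regulatory network (GRN) inference from expression data using
**distance correlation** as the pairwise dependence measure, with
discretization-based **mutual information** as the baseline it is
compared against.

## The problem

Reverse-engineering which genes regulate which from expression
profiles requires a measure of statistical dependence that captures
the nonlinear relationships typical of transcriptional regulation.
Mutual information (MI) is the classical choice in relevance-network
methods, but estimating it from continuous expression values requires
discretization and a density estimate, which is biased and unstable at
the sample sizes of real experiments. Distance correlation (dCor),
from the energy-statistics literature, detects arbitrary nonlinear
dependence between variables of any dimension, is zero iff the
variables are independent, and needs no distribution assumption or
binning.

For an i.i.d. sample (X_k, Y_k), k = 1..n, let a_kl = |X_k − X_l| and
b_kl = |Y_k − Y_l| be Euclidean distance matrices and A, B their
double-centered versions (A_kl = a_kl − ā_k· − ā_·l + ā_··). Then

    dCov²_n(X, Y) = (1/n²) Σ_kl A_kl B_kl
    dCor_n(X, Y)  = dCov_n(X, Y) / √(dVar_n(X) · dVar_n(Y))  ∈ [0, 1]

The dependence matrix M with M_ij = dCor(gene_i, gene_j) (or MI of the
discretized genes) feeds three standard relevance-network algorithms:

- **REL** — rank all gene pairs by M_ij directly;
- **CLR** — z-score M_ij against the background of the two genes' rows
  and combine the floored z-scores in quadrature;
- **MRNET** — per-target mRMR forward selection (relevance minus mean
  redundancy), symmetrized by the maximum.

Ranked predictions are scored against a gold standard with ROC and
precision–recall curves and their areas. A seeded simulator of
acyclic Hill-kinetics networks with knockout-style sampling makes the
whole DC-vs-MI comparison runnable with no external data.

## Worked example

```sh
dcgrn simulate --genes 10 --edges 10 --seed 7 --design pooled --samples 50 \
    --out-expression expr.tsv --out-gold gold.tsv
dcgrn infer expr.tsv --measure dc --method clr --out edges.tsv
dcgrn eval edges.tsv gold.tsv --out metrics.txt
```

which prints

```
wrote expr.tsv (50 samples x 10 genes) and gold.tsv (10 edges)
wrote edges.tsv (10 genes, 45 ranked pairs)
roc_area: 0.8657  pr_area: 0.8456  -> metrics.txt
```

The 10-gene network has 45 unordered gene pairs, 10 of them true
regulations; an ROC area of 0.87 means a randomly chosen true edge
outranks a randomly chosen non-edge 87% of the time, and the PR area
summarizes precision over the full recall range (a no-skill ranker
would sit near the 10/45 ≈ 0.22 prevalence). Repeating with
`--measure mi` gives `roc_area: 0.8000  pr_area: 0.6998` on the same
data — the distance-correlation ranking separates true from spurious
edges better than the binned-MI ranking.

The same `infer`/`eval` commands run on any samples × genes TSV (header
row of gene names; `--transpose` for the genes-in-rows dialect) and
DREAM-style three-column gold standard, e.g. the DREAM3 in-silico
challenge downloads.

As a library:

```python
import dcgrn

net = dcgrn.sample_topology(n_genes=10, n_edges=10, seed=7)
expr = dcgrn.simulate_expression(
    net, dcgrn.SimulationConfig(seed=7, design="pooled", n_samples=50))
m = dcgrn.dc_dependence_matrix(expr)
scores = dcgrn.clr_network(m)
print(dcgrn.evaluate(scores, net.to_gold_standard()))
```

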