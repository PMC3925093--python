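"""Relevance-network inference: REL, CLR and MRNET.

All three algorithms consume a symmetric dependence matrix (dCor or MI
— they are agnostic to the measure) and emit a symmetric nonnegative
edge-score matrix.  No thresholding happens here: evaluation sweeps the
full ranking, so only the ordering of scores matters.

* REL ranks gene pairs by the raw dependence value.
* CLR z-scores each dependence value against the background of its two
  genes' rows and combines the two (floored) z-scores in quadrature.
* MRNET runs a per-target mRMR forward selection, scoring each selected
  regulator by relevance minus mean redundancy at selection time and
  symmetrizing by the maximum over the two target roles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dependence import DependenceMatrix
from .errors import InvalidInputError

METHODS = ("rel", "clr", "mrnet")


@dataclass
class ScoreNetwork:
    """Symmetric nonnegative edge-score matrix produced by an inference method."""

    scores: np.ndarray
    gene_names: list[str]
    method: str
    measure: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        g = len(self.gene_names)
        if self.scores.shape != (g, g):
            raise InvalidInputError(
                f"score shape {self.scores.shape} does not match {g} genes"
            )
        if self.method not in METHODS:
            raise InvalidInputError(f"unknown method tag {self.method!r}")
        if not np.allclose(self.scores, self.scores.T, atol=1e-9):
            raise InvalidInputError("score matrix must be symmetric")
        if np.any(self.scores < 0):
            raise InvalidInputError("scores must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def ranked_edges(self) -> list[tuple[str, str, float]]:
        """All unordered pairs by descending score, ties lexicographic.

        Pairs are canonicalized with the lexicographically smaller gene
        first so the ordering is deterministic.
        """
        g = self.n_genes
        edges = []
        for i in range(g):
            for j in range(i + 1, g):
                a, b = sorted((self.gene_names[i], self.gene_names[j]))
                edges.append((a, b, float(self.scores[i, j])))
        edges.sort(key=lambda e: (-e[2], e[0], e[1]))
        return edges


def rel_network(m: DependenceMatrix) -> ScoreNetwork:
    """Relevance network: pass the dependence values through unchanged."""
    scores = m.values.copy()
    np.fill_diagonal(scores, 0.0)
    return ScoreNetwork(
        scores=scores, gene_names=list(m.gene_names), method="rel", measure=m.measure
    )


def clr_network(m: DependenceMatrix) -> ScoreNetwork:
    """Context likelihood of relatedness.

    Each gene's off-diagonal row supplies a background mean and standard
    deviation (population sd over the n-1 off-diagonal entries).  The
    z-score of m_ij against gene i's background is floored at 0; the
    final score combines the two directions as sqrt(z_i(j)^2 + z_j(i)^2).
    A gene whose background has zero spread contributes z = 0.
    """
    g = m.n_genes
    if g < 3:
        raise InvalidInputError(f"CLR needs at least 3 genes, got {g}")
    vals = m.values.astype(float).copy()
    np.fill_diagonal(vals, np.nan)
    mu = np.nanmean(vals, axis=1)
    sd = np.nanstd(vals, axis=1)  # ddof=0 over the off-diagonal entries
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu[:, None]) / sd[:, None]
    z[sd == 0, :] = 0.0
    z = np.nan_to_num(z, nan=0.0)
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return ScoreNetwork(
        scores=scores, gene_names=list(m.gene_names), method="clr", measure=m.measure
    )


def _mrnet_target_scores(vals: np.ndarray, target: int) -> dict[int, float]:
    """Greedy mRMR forward selection for one target gene.

    At each step the candidate j maximizing u_j - r_j is selected, where
    u_j is the dependence with the target and r_j the mean dependence
    with the already-selected regulators (0 at the first step).  Ties
    break toward the lowest gene index; selection stops when the best
    criterion is <= 0.  Returns the criterion recorded at selection time.
    """
    g = vals.shape[0]
    candidates = [j for j in range(g) if j != target]
    selected: list[int] = []
    recorded: dict[int, float] = {}
    while candidates:
        best_j, best_s = None, None
        for j in candidates:
            u = vals[target, j]
            r = float(np.mean(vals[j, selected])) if selected else 0.0
            s = u - r
            if best_s is None or s > best_s:
                best_j, best_s = j, s
        if best_s is None or best_s <= 0.0:
            break
        recorded[best_j] = best_s
        selected.append(best_j)
        candidates.remove(best_j)
    return recorded


def mrnet_network(m: DependenceMatrix) -> ScoreNetwork:
    """MRNET: per-target mRMR forward selection, max-symmetrized."""
    g = m.n_genes
    vals = m.values
    scores = np.zeros((g, g))
    for t in range(g):
        for j, s in _mrnet_target_scores(vals, t).items():
            if s > scores[t, j]:
                scores[t, j] = s
    scores = np.maximum(scores, scores.T)
    np.fill_diagonal(scores, 0.0)
    return ScoreNetwork(
        scores=scores, gene_names=list(m.gene_names), method="mrnet", measure=m.measure
    )


def infer_network(m: DependenceMatrix, method: str) -> ScoreNetwork:
    """Dispatch on the method tag."""
    if method == "rel":
        return rel_network(m)
    if method == "clr":
        return clr_network(m)
    if method == "mrnet":
        return mrnet_network(m)
    raise InvalidInputError(f"unknown method {method!r}; expected one of {METHODS}")
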