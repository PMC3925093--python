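"""Pairwise dependence measures between genes.

Two families of measures populate the symmetric dependence matrix
``M`` with ``M[i, j] = dependence(gene_i, gene_j)`` that drives the
network inference algorithms:

* **Distance correlation (dCor)** — an energy-statistics measure that is
  zero iff the variables are independent and needs no density estimate.
  The empirical estimator works from double-centered Euclidean distance
  matrices: with ``a_kl = |X_k - X_l|`` and
  ``A_kl = a_kl - rowmean_k - colmean_l + grandmean``,

      dCov_n^2(X, Y) = (1/n^2) * sum_{k,l} A_kl * B_kl
      dCor_n(X, Y)   = dCov_n(X, Y) / sqrt(dVar_n(X) * dVar_n(Y))

  dCor lies in [0, 1] and accepts multivariate blocks (p, q >= 1).

* **Mutual information (MI)** — estimated by discretizing each gene into
  equal-width bins and plugging the observed cell frequencies into the
  discrete definition; reported in nats.  The Miller–Madow entropy bias
  correction is available as an alternative estimator.  MI units and the
  plug-in bias cancel in the rank-based inference downstream.

Conventions: the diagonal of every dependence matrix is forced to 0 so
self-edges can never be ranked, and a degenerate (constant) gene has
dCor 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError
from .expression import ExpressionMatrix

# negative dCov^2 of at most this magnitude is round-off and clamped to 0
_DCOV_ROUNDOFF = 1e-12

MI_ESTIMATORS = ("plugin", "miller_madow")


def _as_block(x) -> np.ndarray:
    """Coerce a sample block to (n, p) float; 1-D input becomes (n, 1)."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise InvalidInputError(f"sample block must be 1-D or 2-D, got {arr.ndim}-D")
    if arr.shape[0] < 2:
        raise InvalidInputError(f"need at least 2 samples, got {arr.shape[0]}")
    return arr


def pairwise_distance_matrix(block) -> np.ndarray:
    """n x n matrix of Euclidean distances between sample rows."""
    arr = _as_block(block)
    return squareform(pdist(arr, metric="euclidean"))


def double_center(d: np.ndarray) -> np.ndarray:
    """Subtract row and column means and add back the grand mean.

    The result has all row and column sums equal to zero; applied to a
    distance matrix it yields the ``A_kl`` ingredient of empirical dCov.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidInputError(f"matrix must be square, got shape {d.shape}")
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def _centered_distances(block) -> np.ndarray:
    return double_center(pairwise_distance_matrix(block))


def _dcov_sq_from_centered(a: np.ndarray, b: np.ndarray) -> float:
    v2 = float(np.mean(a * b))
    if v2 < 0.0:
        # estimator is a mean of products of exact intermediates; any
        # negativity here is floating round-off
        v2 = 0.0
    return v2


def dcov(x, y) -> float:
    """Empirical distance covariance dCov_n(X, Y) (the square root form)."""
    ax, ay = _as_block(x), _as_block(y)
    if ax.shape[0] != ay.shape[0]:
        raise InvalidInputError(
            f"row-count mismatch: {ax.shape[0]} vs {ay.shape[0]}"
        )
    a = _centered_distances(ax)
    b = _centered_distances(ay)
    return sqrt(_dcov_sq_from_centered(a, b))


def dvar(x) -> float:
    """Distance standard deviation dVar_n(X) = dCov_n(X, X)."""
    a = _centered_distances(_as_block(x))
    return sqrt(_dcov_sq_from_centered(a, a))


def dcor(x, y) -> float:
    """Empirical distance correlation in [0, 1].

    Returns 0 when either variable has zero distance variance (a
    constant variable is treated as independent of everything).
    """
    ax, ay = _as_block(x), _as_block(y)
    if ax.shape[0] != ay.shape[0]:
        raise InvalidInputError(
            f"row-count mismatch: {ax.shape[0]} vs {ay.shape[0]}"
        )
    a = _centered_distances(ax)
    b = _centered_distances(ay)
    vx = _dcov_sq_from_centered(a, a)
    vy = _dcov_sq_from_centered(b, b)
    denom_sq = vx * vy
    if denom_sq <= 0.0:
        return 0.0
    r = sqrt(_dcov_sq_from_centered(a, b)) / denom_sq ** 0.25
    return min(max(r, 0.0), 1.0)


@dataclass
class DependenceMatrix:
    """Symmetric genes x genes matrix of pairwise dependence scores.

    ``measure`` records which statistic filled it ("dc" or "mi"); the
    diagonal is 0 by convention and entries are nonnegative (and <= 1
    for dCor).
    """

    values: np.ndarray
    gene_names: list[str]
    measure: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.gene_names)
        if self.values.shape != (g, g):
            raise InvalidInputError(
                f"matrix shape {self.values.shape} does not match {g} genes"
            )
        if self.measure not in ("dc", "mi"):
            raise InvalidInputError(f"unknown measure tag {self.measure!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise InvalidInputError("dependence matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InvalidInputError("dependence matrix diagonal must be 0")
        if np.any(self.values < 0):
            raise InvalidInputError("dependence values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


def dc_dependence_matrix(e: ExpressionMatrix) -> DependenceMatrix:
    """Dependence matrix with M[i, j] = dCor(gene_i, gene_j).

    The centered distance matrix of each gene is computed once and
    reused across all pairs.
    """
    g = e.n_genes
    centered = [_centered_distances(e.values[:, j]) for j in range(g)]
    dvar_sq = np.array([_dcov_sq_from_centered(a, a) for a in centered])
    m = np.zeros((g, g))
    for i in range(g):
        if dvar_sq[i] <= 0.0:
            continue
        for j in range(i + 1, g):
            denom_sq = dvar_sq[i] * dvar_sq[j]
            if denom_sq <= 0.0:
                continue
            v = sqrt(_dcov_sq_from_centered(centered[i], centered[j]))
            m[i, j] = m[j, i] = min(max(v / denom_sq ** 0.25, 0.0), 1.0)
    return DependenceMatrix(values=m, gene_names=list(e.gene_names), measure="dc")


def discretize_equal_width(values, n_bins: int) -> np.ndarray:
    """Bin a vector into ``n_bins`` equal-width bins over [min, max].

    Bins are half-open except the last, which is closed so the maximum
    lands in bin ``n_bins - 1``.  A constant vector maps to bin 0.
    """
    if n_bins < 1:
        raise InvalidInputError(f"n_bins must be >= 1, got {n_bins}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidInputError("values must be a non-empty 1-D vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.size, dtype=int)
    idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def discretize_equal_frequency(values, n_bins: int) -> np.ndarray:
    """Quantile binning alternative, for sensitivity checks."""
    if n_bins < 1:
        raise InvalidInputError(f"n_bins must be >= 1, got {n_bins}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidInputError("values must be a non-empty 1-D vector")
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


@dataclass
class ContingencyTable:
    """Joint counts of two discretized variables."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise InvalidInputError("counts must be a non-empty 2-D table")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        if int(self.counts.sum()) != self.n:
            raise InvalidInputError(
                f"counts sum to {int(self.counts.sum())}, expected n={self.n}"
            )


def joint_counts(bx, by) -> ContingencyTable:
    """Contingency table of two equal-length bin-index vectors."""
    bx = np.asarray(bx, dtype=int)
    by = np.asarray(by, dtype=int)
    if bx.shape != by.shape or bx.ndim != 1:
        raise InvalidInputError(
            f"bin vectors must be 1-D and equal length, got {bx.shape} vs {by.shape}"
        )
    kx, ky = int(bx.max()) + 1, int(by.max()) + 1
    counts = np.zeros((kx, ky), dtype=int)
    np.add.at(counts, (bx, by), 1)
    return ContingencyTable(counts=counts, n=bx.size)


def mi_plugin(t: ContingencyTable) -> float:
    """Plug-in mutual information in nats from observed cell frequencies."""
    if t.n < 1:
        raise InvalidInputError("empty contingency table")
    p = t.counts / t.n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


def mi_miller_madow(t: ContingencyTable) -> float:
    """Plug-in MI plus the Miller–Madow entropy bias correction.

    Applying the per-entropy correction (K - 1)/(2n) to H(X), H(Y) and
    H(X, Y) adds (K_x + K_y - K_xy - 1)/(2n) to the MI, where each K
    counts non-empty rows, columns and cells respectively.
    """
    if t.n < 1:
        raise InvalidInputError("empty contingency table")
    kx = int(np.count_nonzero(t.counts.sum(axis=1)))
    ky = int(np.count_nonzero(t.counts.sum(axis=0)))
    kxy = int(np.count_nonzero(t.counts))
    return mi_plugin(t) + (kx + ky - kxy - 1) / (2.0 * t.n)


def auto_bins(n_samples: int) -> int:
    """Default bin count ceil(sqrt(n)) for the discretized MI estimators."""
    return ceil(sqrt(n_samples))


def mi_dependence_matrix(
    e: ExpressionMatrix,
    estimator: str = "plugin",
    n_bins: int | str = "auto",
    binning: str = "equal_width",
) -> DependenceMatrix:
    """Dependence matrix with M[i, j] = MI(gene_i, gene_j) in nats.

    Each gene is discretized once; MI comes from ``mi_plugin`` or
    ``mi_miller_madow`` per the ``estimator`` tag.  Negative
    Miller–Madow values are floored at 0.
    """
    if estimator not in MI_ESTIMATORS:
        raise InvalidInputError(
            f"unknown MI estimator {estimator!r}; expected one of {MI_ESTIMATORS}"
        )
    if binning == "equal_width":
        binner = discretize_equal_width
    elif binning == "equal_frequency":
        binner = discretize_equal_frequency
    else:
        raise InvalidInputError(f"unknown binning {binning!r}")
    bins = auto_bins(e.n_samples) if n_bins == "auto" else int(n_bins)
    if bins < 1:
        raise InvalidInputError(f"n_bins must be >= 1, got {bins}")
    est = mi_plugin if estimator == "plugin" else mi_miller_madow
    binned = [binner(e.values[:, j], bins) for j in range(e.n_genes)]
    g = e.n_genes
    m = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            mi = est(joint_counts(binned[i], binned[j]))
            m[i, j] = m[j, i] = max(mi, 0.0)
    return DependenceMatrix(values=m, gene_names=list(e.gene_names), measure="mi")


def dependence_matrix(
    e: ExpressionMatrix,
    measure: str,
    mi_estimator: str = "plugin",
    n_bins: int | str = "auto",
) -> DependenceMatrix:
    """Dispatch on the measure tag ("dc" or "mi")."""
    if measure == "dc":
        return dc_dependence_matrix(e)
    if measure == "mi":
        return mi_dependence_matrix(e, estimator=mi_estimator, n_bins=n_bins)
    raise InvalidInputError(f"unknown measure {measure!r}; expected 'dc' or 'mi'")
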