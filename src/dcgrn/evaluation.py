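"""ROC and precision-recall evaluation of a ranked network.

The gold standards of the DREAM-style benchmarks are directed
(regulator -> target) while all inference methods here emit symmetric
scores, so evaluation collapses the gold standard onto unordered pairs:
a pair is a positive if either direction is a labeled true regulation.
Pairs labeled 0 explicitly and pairs absent from the gold file are both
negatives.

Curves sweep every distinct score threshold; tied scores always enter
the confusion counts as a block.  The ROC area is the trapezoidal area
(equivalently the tie-corrected Mann–Whitney probability); the PR area
integrates the same threshold sweep with linear interpolation in
recall, anchoring recall 0 at the first attained precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .inference import ScoreNetwork


@dataclass
class GoldStandard:
    """Labeled regulator -> target edges plus the node namespace."""

    edges: list[tuple[str, str, int]]
    node_names: list[str]

    def __post_init__(self) -> None:
        nodes = set(self.node_names)
        labels: dict[tuple[str, str], int] = {}
        for reg, tgt, lab in self.edges:
            if reg == tgt:
                raise InvalidInputError(f"self-edge {reg!r} -> {tgt!r} in gold standard")
            if lab not in (0, 1):
                raise InvalidInputError(f"non-binary label {lab!r} for {reg}->{tgt}")
            if reg not in nodes or tgt not in nodes:
                missing = reg if reg not in nodes else tgt
                raise InvalidInputError(f"edge references unknown node {missing!r}")
            key = (reg, tgt)
            if key in labels and labels[key] != lab:
                raise InvalidInputError(
                    f"conflicting labels for duplicate edge {reg}->{tgt}"
                )
            labels[key] = lab

    def positive_pairs(self) -> set[tuple[str, str]]:
        """Unordered (sorted) pairs with a 1 label in either direction."""
        return {
            tuple(sorted((r, t))) for r, t, lab in self.edges if lab == 1
        }


@dataclass
class LabeledRanking:
    """Unordered gene pairs sorted by descending score with 0/1 labels."""

    items: list[tuple[tuple[str, str], float, int]]
    n_pos: int = field(init=False)
    n_neg: int = field(init=False)

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.items]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise InvalidInputError("ranking scores must be non-increasing")
        self.n_pos = sum(lab for _, _, lab in self.items)
        self.n_neg = len(self.items) - self.n_pos
        if self.n_pos < 1 or self.n_neg < 1:
            raise InvalidInputError(
                f"degenerate ranking: {self.n_pos} positives, {self.n_neg} negatives"
            )

    def _threshold_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative (tp, fp) after each distinct-score block."""
        scores = np.array([s for _, s, _ in self.items])
        labels = np.array([lab for _, _, lab in self.items])
        cum_tp = np.cumsum(labels)
        cum_fp = np.cumsum(1 - labels)
        ends = np.append(np.flatnonzero(np.diff(scores) != 0), scores.size - 1)
        return cum_tp[ends], cum_fp[ends]


@dataclass
class Curve:
    """An ROC or PR curve as ordered (x, y) points in the unit square."""

    points: list[tuple[float, float]]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("roc", "pr"):
            raise InvalidInputError(f"unknown curve kind {self.kind!r}")
        xs = [x for x, _ in self.points]
        if any(a > b for a, b in zip(xs, xs[1:])):
            raise InvalidInputError("curve x values must be non-decreasing")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tp_rate(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fp_rate(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp_rate


def align_gold(
    net: ScoreNetwork, gold: GoldStandard, mode: str = "undirected"
) -> LabeledRanking:
    """Label every unordered gene pair of the network against the gold standard.

    Sorting is by descending score with lexicographic tie-break, so the
    result is independent of the network's gene order.
    """
    if mode != "undirected":
        raise InvalidInputError(f"unknown evaluation mode {mode!r}")
    genes = set(net.gene_names)
    for node in gold.node_names:
        if node not in genes:
            raise InvalidInputError(f"gold-standard node {node!r} not in network")
    positives = gold.positive_pairs()
    if not positives:
        raise InvalidInputError("gold standard contains no positive edges")
    items = [
        (pair := (a, b), score, 1 if pair in positives else 0)
        for a, b, score in net.ranked_edges()
    ]
    return LabeledRanking(items=items)


def roc_points(r: LabeledRanking) -> Curve:
    """ROC curve: one point per distinct threshold, (0,0) to (1,1)."""
    tp, fp = r._threshold_counts()
    pts = [(0.0, 0.0)]
    pts += [(f / r.n_neg, t / r.n_pos) for t, f in zip(tp, fp)]
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return Curve(points=pts, kind="roc")


def pr_points(r: LabeledRanking) -> Curve:
    """PR curve: (recall, precision) at each distinct threshold."""
    tp, fp = r._threshold_counts()
    pts = [(t / r.n_pos, t / (t + f)) for t, f in zip(tp, fp)]
    return Curve(points=pts, kind="pr")


def auc(c: Curve) -> float:
    """Area under a curve.

    ROC: trapezoidal area over FP rate.  PR: trapezoidal area over
    recall, with recall 0 anchored at the first point's precision so
    the integral covers the full [0, 1] recall range.
    """
    if len(c.points) < 2 and c.kind == "roc":
        raise InvalidInputError("need at least 2 points for an area")
    pts = list(c.points)
    if c.kind == "pr":
        if not pts:
            raise InvalidInputError("empty PR curve")
        if pts[0][0] > 0.0:
            pts = [(0.0, pts[0][1])] + pts
        if len(pts) < 2:
            raise InvalidInputError("need at least 2 points for an area")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    area = float(np.trapezoid(y, x))
    return min(max(area, 0.0), 1.0)


def auroc(r: LabeledRanking) -> float:
    return auc(roc_points(r))


def aupr(r: LabeledRanking) -> float:
    return auc(pr_points(r))


def confusion_at_threshold(r: LabeledRanking, target_tp_rate: float) -> ConfusionCounts:
    """Counts at the smallest whole-block prefix reaching a TP rate.

    Mirrors the fixed-TP-rate comparison protocol: cut the ranking at
    the shortest prefix (never splitting tied scores) whose TP rate
    meets the target and report the confusion counts there.
    """
    if not 0.0 < target_tp_rate <= 1.0:
        raise InvalidInputError(
            f"target TP rate must be in (0, 1], got {target_tp_rate}"
        )
    tp, fp = r._threshold_counts()
    for t, f in zip(tp, fp):
        if t / r.n_pos >= target_tp_rate:
            return ConfusionCounts(
                tp=int(t), fp=int(f), tn=r.n_neg - int(f), fn=r.n_pos - int(t)
            )
    # full list always attains TP rate 1 >= target; not reachable
    t, f = int(tp[-1]), int(fp[-1])
    return ConfusionCounts(tp=t, fp=f, tn=r.n_neg - f, fn=r.n_pos - t)


def evaluate(net: ScoreNetwork, gold: GoldStandard) -> dict[str, float]:
    """Convenience: ROC and PR areas plus counts for a network vs gold."""
    ranking = align_gold(net, gold)
    return {
        "roc_area": auroc(ranking),
        "pr_area": aupr(ranking),
        "n_pairs": float(len(ranking.items)),
        "n_pos": float(ranking.n_pos),
        "n_neg": float(ranking.n_neg),
    }
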