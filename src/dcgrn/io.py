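"""Text-file formats: expression TSV, DREAM-style gold standards,
ranked edge lists, dependence-matrix dumps, metrics reports and curve
point files.

The canonical dialect is tab-separated UTF-8 with Unix newlines;
comma-separated input is accepted via ``delimiter=","``.  Every file
dcgrn writes starts with ``#`` header comments recording the tool
version and the run configuration, and readers skip ``#`` lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .dependence import DependenceMatrix
from .errors import DataFormatError, InvalidInputError
from .evaluation import Curve, GoldStandard
from .expression import ExpressionMatrix
from .inference import ScoreNetwork


def _header_comment(**meta) -> str:
    fields = " ".join(f"{k}={v}" for k, v in meta.items() if v is not None)
    return f"# dcgrn v{__version__}" + (f" | {fields}" if fields else "") + "\n"


def _read_table(path, delimiter: str, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"{path}: malformed table ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc


def read_expression(
    path, transpose: bool = False, delimiter: str = "\t"
) -> ExpressionMatrix:
    """Read a samples x genes expression table.

    The first non-comment row is the gene-name header; every following
    cell must be numeric.  With ``transpose=True`` the file is the
    genes-in-rows dialect (first column gene names, header row sample
    names) and is flipped on read.
    """
    if transpose:
        raw_df = _read_table(path, delimiter, header=0, index_col=0, dtype=str)
        names = [str(g) for g in raw_df.index]
        df = raw_df.T
        df.columns = names
    else:
        with open(path, encoding="utf-8") as fh:
            header_line = next(
                (ln for ln in fh if ln.strip() and not ln.startswith("#")), None
            )
        if header_line is None:
            raise DataFormatError(f"{path}: empty file")
        names = [c.strip() for c in header_line.rstrip("\n").split(delimiter)]
        df = _read_table(path, delimiter, header=0, dtype=str)
        df.columns = names
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise DataFormatError(f"{path}: duplicate gene name {name!r}")
        seen.add(name)
    raw = df.to_numpy()
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(numeric))
    if bad.size:
        r, c = bad[0]
        raise DataFormatError(
            f"{path}: non-numeric or missing value {raw[r, c]!r} "
            f"at data row {r + 1}, column {df.columns[c]!r}"
        )
    try:
        return ExpressionMatrix(values=numeric, gene_names=[str(c) for c in df.columns])
    except InvalidInputError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_expression(e: ExpressionMatrix, path, **meta) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(**meta))
        fh.write("\t".join(e.gene_names) + "\n")
        for row in e.values:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def read_gold(path, delimiter: str = "\t") -> GoldStandard:
    """Read a DREAM-style three-column gold standard (regulator, target, 0/1)."""
    df = _read_table(path, delimiter, header=None, dtype=str)
    if df.shape[1] != 3:
        raise DataFormatError(
            f"{path}: expected 3 columns (regulator, target, label), got {df.shape[1]}"
        )
    edges: list[tuple[str, str, int]] = []
    nodes: list[str] = []
    seen: set[str] = set()
    for line_no, (reg, tgt, lab) in enumerate(df.itertuples(index=False), start=1):
        reg, tgt = str(reg).strip(), str(tgt).strip()
        if str(lab).strip() not in ("0", "1"):
            raise DataFormatError(
                f"{path}: non-binary label {lab!r} on line {line_no}"
            )
        for node in (reg, tgt):
            if node not in seen:
                seen.add(node)
                nodes.append(node)
        edges.append((reg, tgt, int(str(lab).strip())))
    try:
        return GoldStandard(edges=edges, node_names=nodes)
    except InvalidInputError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_gold(gold: GoldStandard, path, **meta) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(**meta))
        for reg, tgt, lab in gold.edges:
            fh.write(f"{reg}\t{tgt}\t{lab}\n")


def write_edge_list(net: ScoreNetwork, path, **meta) -> None:
    """Ranked three-column edge list: gene_a, gene_b, score (descending)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(method=net.method, measure=net.measure, **meta))
        for a, b, score in net.ranked_edges():
            fh.write(f"{a}\t{b}\t{score:.12g}\n")


def read_edge_list(path, delimiter: str = "\t") -> ScoreNetwork:
    """Rebuild a ScoreNetwork from a ranked edge list.

    Method/measure tags are recovered from the header comment when
    present; pairs absent from the file score 0.
    """
    method, measure = "rel", "dc"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.split("|")[-1].split():
            if token.startswith("method="):
                method = token.split("=", 1)[1]
            elif token.startswith("measure="):
                measure = token.split("=", 1)[1]
    df = _read_table(path, delimiter, header=None, dtype=str)
    if df.shape[1] != 3:
        raise DataFormatError(
            f"{path}: expected 3 columns (gene_a, gene_b, score), got {df.shape[1]}"
        )
    genes = sorted(set(df[0].astype(str)) | set(df[1].astype(str)))
    idx = {g: i for i, g in enumerate(genes)}
    scores = np.zeros((len(genes), len(genes)))
    for line_no, (a, b, s) in enumerate(df.itertuples(index=False), start=1):
        try:
            val = float(s)
        except ValueError:
            raise DataFormatError(
                f"{path}: non-numeric score {s!r} on line {line_no}"
            ) from None
        if val < 0:
            raise DataFormatError(f"{path}: negative score on line {line_no}")
        i, j = idx[str(a)], idx[str(b)]
        if i == j:
            raise DataFormatError(f"{path}: self-pair {a!r} on line {line_no}")
        scores[i, j] = scores[j, i] = val
    try:
        return ScoreNetwork(scores=scores, gene_names=genes, method=method, measure=measure)
    except InvalidInputError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_dependence_matrix(m: DependenceMatrix, path, **meta) -> None:
    """Square TSV dump with gene names as both header row and column."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(measure=m.measure, **meta))
        fh.write("\t" + "\t".join(m.gene_names) + "\n")
        for name, row in zip(m.gene_names, m.values):
            fh.write(name + "\t" + "\t".join(format(v, ".12g") for v in row) + "\n")


def write_metrics(metrics: dict, path, **meta) -> None:
    """Key: value text report."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(**meta))
        for key, value in metrics.items():
            if isinstance(value, float):
                fh.write(f"{key}: {value:.6g}\n")
            else:
                fh.write(f"{key}: {value}\n")


def write_curve(curve: Curve, path, **meta) -> None:
    """Two-column TSV of curve points (x, y)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_comment(kind=curve.kind, **meta))
        for x, y in curve.points:
            fh.write(f"{x:.10g}\t{y:.10g}\n")
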