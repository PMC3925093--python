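"""The samples x genes expression matrix, raw input to every stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass
class ExpressionMatrix:
    """A validated samples x genes matrix of expression values.

    Parameters
    ----------
    values : (n_samples, n_genes) array of finite floats
        Expression in arbitrary units; at least 2 samples and 2 genes,
        no missing values.
    gene_names : list of str
        Unique column labels, one per gene.
    sample_names : list of str, optional
        Row labels; purely descriptive.
    """

    values: np.ndarray
    gene_names: list[str]
    sample_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError(
                f"expression values must be 2-D, got shape {self.values.shape}"
            )
        n, g = self.values.shape
        if n < 2:
            raise InvalidInputError(f"need at least 2 samples, got {n}")
        if g < 2:
            raise InvalidInputError(f"need at least 2 genes, got {g}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InvalidInputError(
                f"missing/non-finite value at sample {bad[0]}, gene column {bad[1]}"
            )
        self.gene_names = [str(x) for x in self.gene_names]
        if len(self.gene_names) != g:
            raise InvalidInputError(
                f"{len(self.gene_names)} gene names for {g} columns"
            )
        seen: set[str] = set()
        for name in self.gene_names:
            if name in seen:
                raise InvalidInputError(f"duplicate gene name {name!r}")
            seen.add(name)
        if self.sample_names is not None:
            self.sample_names = [str(x) for x in self.sample_names]
            if len(self.sample_names) != n:
                raise InvalidInputError(
                    f"{len(self.sample_names)} sample names for {n} rows"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene: str) -> np.ndarray:
        """Expression vector of a single gene."""
        try:
            j = self.gene_names.index(gene)
        except ValueError:
            raise InvalidInputError(f"unknown gene {gene!r}") from None
        return self.values[:, j]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame with genes in columns, samples in rows."""
        sample_names = None
        if not isinstance(df.index, pd.RangeIndex):
            sample_names = [str(i) for i in df.index]
        return cls(
            values=df.to_numpy(dtype=float),
            gene_names=[str(c) for c in df.columns],
            sample_names=sample_names,
        )

    def to_dataframe(self) -> pd.DataFrame:
        index = self.sample_names if self.sample_names is not None else None
        return pd.DataFrame(self.values, columns=self.gene_names, index=index)
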