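"""Core data containers and plain-text IO.

The whole pipeline consumes one universe object: a raw integer
gene-by-sample count matrix.  Everything downstream (size factors,
variance-stabilized expression, mixed pseudo-samples) is derived from it
and carried as plain :class:`pandas.DataFrame` objects indexed by gene
and sample identifiers, so interoperability with the scientific Python
stack is free.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


class CountMatrix:
    """Raw gene-by-sample count matrix (genes as rows, samples as columns).

    Parameters
    ----------
    data
        DataFrame of non-negative integral counts; the index holds gene
        identifiers, the columns sample identifiers.  Duplicated gene or
        sample identifiers, negative entries and non-integral entries are
        rejected.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise CountMatrixError("counts must be supplied as a pandas DataFrame")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene identifiers: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate sample identifiers: {dupes[:5]}")
        values = data.to_numpy()
        if values.size and np.any(values < 0):
            raise CountMatrixError("counts must be non-negative")
        if not np.allclose(values, np.round(values), atol=1e-8):
            raise CountMatrixError("counts must be integral")
        self._df = pd.DataFrame(
            values.astype(np.int64),
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    # -- basic access -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> pd.Index:
        return self._df.index

    @property
    def samples(self) -> pd.Index:
        return self._df.columns

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        m, n = self.shape
        return f"CountMatrix({m} genes x {n} samples)"

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self._df.columns]
        if missing:
            raise CountMatrixError(f"unknown samples: {missing[:5]}")
        return CountMatrix(self._df.loc[:, list(samples)])

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self._df.index]
        if missing:
            raise CountMatrixError(f"unknown genes: {missing[:5]}")
        return CountMatrix(self._df.loc[genes])

    def concat(self, other: "CountMatrix") -> "CountMatrix":
        """Append another matrix column-wise (gene sets must be identical)."""
        if not self.genes.equals(other.genes):
            raise CountMatrixError("gene sets differ between matrices")
        return CountMatrix(pd.concat([self._df, other._df], axis=1))

    # -- IO ------------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        """Write genes-as-rows TSV with a header row of sample IDs."""
        self._df.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_mtx(self, prefix: str) -> None:
        """Write MatrixMarket ``<prefix>.mtx`` plus row/column sidecars."""
        spio.mmwrite(prefix + ".mtx", sparse.csr_matrix(self.values))
        with open(prefix + ".rows.txt", "w") as fh:
            fh.write("\n".join(self.genes) + "\n")
        with open(prefix + ".cols.txt", "w") as fh:
            fh.write("\n".join(self.samples) + "\n")

    @classmethod
    def from_mtx(cls, prefix: str) -> "CountMatrix":
        mat = spio.mmread(prefix + ".mtx")
        if sparse.issparse(mat):
            mat = mat.toarray()
        for side in (".rows.txt", ".cols.txt"):
            if not os.path.exists(prefix + side):
                raise CountMatrixError(f"missing sidecar file {prefix + side}")
        with open(prefix + ".rows.txt") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        with open(prefix + ".cols.txt") as fh:
            samples = [line.strip() for line in fh if line.strip()]
        return cls(pd.DataFrame(np.asarray(mat), index=genes, columns=samples))


def read_table(path: str, index_col: int | None = 0) -> pd.DataFrame:
    """Read a metadata/annotation TSV."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
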