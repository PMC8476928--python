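"""Core in-memory containers shared across the pipeline.

A :class:`CountsMatrix` holds raw UMI counts (cells x genes, sparse integer),
an :class:`ExpressionMatrix` holds a dense real-valued transform of it
(log-normalized or z-scaled), and a :class:`GeneSignature` is a named, ordered,
duplicate-free list of gene symbols used for module scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountsMatrix:
    """Sparse cell-by-gene matrix of unique-molecule counts.

    Parameters
    ----------
    values
        Non-negative integer matrix, cells as rows, genes as columns.
    barcodes
        Unique cell identifiers, one per row.
    genes
        Unique gene symbols, one per column.
    """

    values: sparse.csr_matrix
    barcodes: pd.Index
    genes: pd.Index

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        self.genes = pd.Index(self.genes, name="gene")
        n_cells, n_genes = self.values.shape
        if len(self.barcodes) != n_cells or len(self.genes) != n_genes:
            raise ValueError(
                f"axis mismatch: matrix {self.values.shape}, "
                f"{len(self.barcodes)} barcodes, {len(self.genes)} genes"
            )
        _check_unique(self.barcodes, "barcodes")
        _check_unique(self.genes, "gene symbols")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValueError("negative counts")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.all(np.mod(data, 1) == 0):
                    raise ValueError("counts must be integral")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        barcodes: Sequence[str] | pd.Index | None = None,
        genes: Sequence[str] | pd.Index | None = None,
    ) -> "CountsMatrix":
        """Return a new matrix restricted to the given barcodes and/or genes."""
        rows = slice(None) if barcodes is None else self.barcodes.get_indexer(barcodes)
        cols = slice(None) if genes is None else self.genes.get_indexer(genes)
        if barcodes is not None and np.any(np.asarray(rows) < 0):
            missing = pd.Index(barcodes).difference(self.barcodes)
            raise KeyError(f"barcodes not in matrix: {missing[:5].tolist()}")
        if genes is not None and np.any(np.asarray(cols) < 0):
            missing = pd.Index(genes).difference(self.genes)
            raise KeyError(f"genes not in matrix: {missing[:5].tolist()}")
        vals = self.values[rows][:, cols]
        new_bc = self.barcodes if barcodes is None else self.barcodes[rows]
        new_genes = self.genes if genes is None else self.genes[cols]
        return CountsMatrix(vals, new_bc, new_genes)


@dataclass
class ExpressionMatrix:
    """Dense real-valued cell-by-gene matrix (normalized or scaled values)."""

    values: np.ndarray
    barcodes: pd.Index
    genes: pd.Index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        self.genes = pd.Index(self.genes, name="gene")
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError(
                f"axis mismatch: matrix {self.values.shape}, "
                f"{len(self.barcodes)} barcodes, {len(self.genes)} genes"
            )
        _check_unique(self.barcodes, "barcodes")
        _check_unique(self.genes, "gene symbols")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(
        self,
        barcodes: Sequence[str] | pd.Index | None = None,
        genes: Sequence[str] | pd.Index | None = None,
    ) -> "ExpressionMatrix":
        rows = slice(None) if barcodes is None else self.barcodes.get_indexer(barcodes)
        cols = slice(None) if genes is None else self.genes.get_indexer(genes)
        if barcodes is not None and np.any(np.asarray(rows) < 0):
            missing = pd.Index(barcodes).difference(self.barcodes)
            raise KeyError(f"barcodes not in matrix: {missing[:5].tolist()}")
        if genes is not None and np.any(np.asarray(cols) < 0):
            missing = pd.Index(genes).difference(self.genes)
            raise KeyError(f"genes not in matrix: {missing[:5].tolist()}")
        vals = self.values[rows][:, cols] if barcodes is not None or genes is not None else self.values
        new_bc = self.barcodes if barcodes is None else self.barcodes[rows]
        new_genes = self.genes if genes is None else self.genes[cols]
        return ExpressionMatrix(vals, new_bc, new_genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.barcodes, columns=self.genes)


@dataclass(frozen=True)
class GeneSignature:
    """Named, ordered, duplicate-free list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError(f"signature '{self.name}' is empty")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dups = [g for g in self.genes if g in seen or seen.add(g)]
            raise ValueError(f"signature '{self.name}' has duplicate genes: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[str]:
        return iter(self.genes)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSignature":
        """Read a signature from a plain-text file, one gene symbol per line."""
        path = Path(path)
        genes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        return cls(name or path.stem, tuple(genes))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.genes) + "\n")
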