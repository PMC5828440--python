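"""Count-matrix I/O and gene-panel selection.

The study operates on integer gene-by-sample count matrices, reduced to
100-gene panels chosen either as the most variable genes (by median
absolute deviation, MAD) or as a uniform random draw from the
upper-half-MAD pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Normal-consistency scaling for the MAD. Panel selection depends only on
#: MAD ranks, so this constant is cosmetic for selection purposes.
MAD_CONSTANT = 1.4826


class CountMatrixError(ValueError):
    """Raised for malformed count matrices (negative, fractional, duplicated)."""


@dataclass(frozen=True, eq=False)
class CountMatrix:
    """Integer gene x sample expression counts with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer array of shape (n_genes, n_samples).
    gene_ids
        Unique row identifiers.
    sample_ids
        Unique column identifiers.
    """

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise CountMatrixError("counts must be a 2-D array")
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)):
                raise CountMatrixError("non-numeric or non-finite cell in counts")
            rounded = np.rint(arr)
            if not np.array_equal(rounded, arr):
                raise CountMatrixError("non-integral count encountered")
            arr = rounded.astype(np.int64)
        elif not np.issubdtype(arr.dtype, np.integer):
            raise CountMatrixError("counts must be numeric")
        arr = arr.astype(np.int64, copy=False)
        if np.any(arr < 0):
            raise CountMatrixError("negative count encountered")
        gene_ids = tuple(str(g) for g in self.gene_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if arr.shape != (len(gene_ids), len(sample_ids)):
            raise CountMatrixError(
                f"shape {arr.shape} does not match {len(gene_ids)} genes x "
                f"{len(sample_ids)} samples"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise CountMatrixError("duplicate gene identifiers")
        if len(set(sample_ids)) != len(sample_ids):
            raise CountMatrixError("duplicate sample identifiers")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        """Return the count vector for one gene."""
        try:
            idx = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.counts[idx]

    def subset(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None
        return CountMatrix(self.counts[rows], tuple(gene_ids), self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        values = df.to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            raise CountMatrixError("non-numeric cell in counts")
        return cls(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene subset selected from a :class:`CountMatrix`."""

    gene_ids: tuple[str, ...]
    selection_mode: str  # "top_mad" | "random_filtered"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in panel")

    def __len__(self) -> int:
        return len(self.gene_ids)


def load_count_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from ``path``.

    The first column holds gene identifiers and the header row holds sample
    identifiers. ``format`` may be ``"xlsx"``, ``"csv"`` or ``"tsv"``; when
    omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix file not found: {path}")
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"xlsx": "xlsx", "csv": "csv", "tsv": "tsv", "txt": "tsv"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    if format == "xlsx":
        df = pd.read_excel(path, index_col=0)
    elif format in ("csv", "tsv"):
        df = pd.read_csv(path, index_col=0, sep="," if format == "csv" else "\t")
    else:
        raise ValueError(f"unsupported format: {format}")
    if df.isna().any().any():
        raise CountMatrixError(f"non-numeric or missing cell in {path.name}")
    return CountMatrix.from_dataframe(df)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write ``matrix`` as tab-separated text with a sample-id header row."""
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


def mad(values: Sequence[float] | np.ndarray, constant: float = MAD_CONSTANT) -> float:
    """Scaled median absolute deviation: median(|x - median(x)|) * constant."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(np.median(np.abs(arr - np.median(arr))) * constant)


def _gene_mads(matrix: CountMatrix, constant: float) -> np.ndarray:
    med = np.median(matrix.counts, axis=1, keepdims=True)
    return np.median(np.abs(matrix.counts - med), axis=1) * constant


def select_top_mad(
    matrix: CountMatrix, m: int, constant: float = MAD_CONSTANT
) -> GenePanel:
    """Select the ``m`` genes with the largest MAD across samples.

    Ties at the selection boundary are broken by ascending gene id, which
    makes the panel deterministic and invariant to gene row order.
    """
    if not 1 <= m <= matrix.n_genes:
        raise ValueError(f"m={m} out of range for {matrix.n_genes} genes")
    mads = _gene_mads(matrix, constant)
    order = sorted(range(matrix.n_genes), key=lambda i: (-mads[i], matrix.gene_ids[i]))
    return GenePanel(tuple(matrix.gene_ids[i] for i in order[:m]), "top_mad")


def select_random_filtered(
    matrix: CountMatrix, m: int, seed: int, constant: float = MAD_CONSTANT
) -> GenePanel:
    """Draw ``m`` genes uniformly from the upper-half-MAD pool.

    The lower 50% of genes by MAD (floor(G/2) genes, ties resolved by gene
    id) are removed first; the draw is without replacement and reproducible
    given ``seed``.
    """
    mads = _gene_mads(matrix, constant)
    ascending = sorted(
        range(matrix.n_genes), key=lambda i: (mads[i], matrix.gene_ids[i])
    )
    pool = ascending[math.floor(matrix.n_genes / 2):]
    if len(pool) < m:
        raise ValueError(
            f"only {len(pool)} genes remain after the lower-50% MAD filter; "
            f"cannot select {m}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=m, replace=False)
    return GenePanel(
        tuple(matrix.gene_ids[pool[i]] for i in chosen), "random_filtered", seed
    )
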