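"""The four count transformations compared by the study.

naive    identity on the counts
log      elementwise log2(x + 1)
blom     rank-based inverse-normal scores, by default within each sample
vst      NB variance-stabilizer (2/sqrt(a)) * asinh(sqrt(a*x)) with a pooled
         method-of-moments dispersion ``a`` estimated from the matrix
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .features import CountMatrix

TRANSFORM_NAMES = ("naive", "log", "blom", "vst")

#: Floor returned when every gene is under-dispersed (no NB signal).
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class TransformedMatrix:
    """Real-valued gene x sample matrix with its transform provenance."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    transform_tag: str
    transform_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("transformed values must be finite")
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifiers")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))


def transform_naive(matrix: CountMatrix) -> TransformedMatrix:
    """No transformation: the counts themselves, as floats."""
    return TransformedMatrix(
        matrix.counts.astype(float), matrix.gene_ids, matrix.sample_ids, "naive"
    )


def transform_log2(matrix: CountMatrix, pseudocount: float = 1.0) -> TransformedMatrix:
    """Elementwise log2(x + pseudocount); the pseudocount guards zeros."""
    return TransformedMatrix(
        np.log2(matrix.counts + pseudocount),
        matrix.gene_ids,
        matrix.sample_ids,
        "log",
        {"pseudocount": pseudocount},
    )


def blom_scores(values) -> np.ndarray:
    """Blom rank-based inverse-normal scores of one vector.

    With average ranks r (ties share the mean rank) and n observations,
    returns Phi^-1((r - 3/8) / (n + 1/4)).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.all(arr == arr[0]):
        raise ValueError("Blom scores are undefined for a constant vector")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.375) / (arr.size + 0.25))


def transform_blom(matrix: CountMatrix, axis: str = "per_sample") -> TransformedMatrix:
    """Blom scores along an axis: each sample's gene profile (default) or
    each gene's sample profile is rank-normalized independently."""
    if axis not in ("per_sample", "per_gene"):
        raise ValueError("axis must be per_sample or per_gene")
    counts = matrix.counts
    out = np.empty(counts.shape, dtype=float)
    if axis == "per_sample":
        for j in range(counts.shape[1]):
            out[:, j] = blom_scores(counts[:, j])
    else:
        for i in range(counts.shape[0]):
            out[i, :] = blom_scores(counts[i, :])
    return TransformedMatrix(
        out, matrix.gene_ids, matrix.sample_ids, "blom", {"axis": axis}
    )


def estimate_common_dispersion(matrix: CountMatrix) -> float:
    """Pooled NB dispersion alpha solving Var = mu + alpha * mu**2.

    Per-gene method-of-moments values (s2 - m) / m**2 are pooled by their
    median over the over-dispersed genes; returns a small floor when no
    gene is over-dispersed.
    """
    counts = matrix.counts.astype(float)
    m = counts.mean(axis=1)
    s2 = counts.var(axis=1, ddof=1)
    ok = m > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 genes with positive mean")
    alpha_g = (s2[ok] - m[ok]) / m[ok] ** 2
    alpha_g = alpha_g[alpha_g > 0]
    if alpha_g.size == 0:
        return DISPERSION_FLOOR
    return float(np.median(alpha_g))


def transform_vst(matrix: CountMatrix, alpha: float | None = None) -> TransformedMatrix:
    """NB variance-stabilizing transform u(x) = (2/sqrt(a)) * asinh(sqrt(a*x)).

    ``u`` is the closed-form integral of 1/sqrt(mu + a*mu^2); as a -> 0 it
    approaches the Poisson stabilizer 2*sqrt(x). ``alpha`` defaults to the
    pooled estimate from the matrix itself.
    """
    if alpha is None:
        alpha = estimate_common_dispersion(matrix)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    values = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * matrix.counts))
    return TransformedMatrix(
        values, matrix.gene_ids, matrix.sample_ids, "vst", {"alpha": alpha}
    )


def get_transform(name: str, **options) -> Callable[[CountMatrix], TransformedMatrix]:
    """Look up a transform by its CLI name."""
    table: dict[str, Callable[[CountMatrix], TransformedMatrix]] = {
        "naive": transform_naive,
        "log": lambda m: transform_log2(m, **options),
        "blom": lambda m: transform_blom(m, **options),
        "vst": lambda m: transform_vst(m, **options),
    }
    if name not in table:
        raise ValueError(f"unknown transform {name!r}; choose from {TRANSFORM_NAMES}")
    return table[name]
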