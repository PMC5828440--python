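"""Per-gene negative-binomial maximum-likelihood estimation.

Parameterization: a gene with mean ``mu`` and dispersion (size) ``k`` has
variance ``mu + mu**2 / k``; ``k -> inf`` recovers the Poisson. The effect
shifts applied by the simulator multiply ``k``, so this convention is
load-bearing and is used everywhere in the package.

With no covariates the generalized-linear-model fit reduces to ``mu_hat =
sample mean`` plus a one-dimensional profile-likelihood maximization in
``log k``, which is what :func:`fit_nb_mle` implements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

#: Dispersion cap used for (near-)Poisson genes, where the NB MLE diverges.
DISPERSION_CAP = 1e8

_LOG_K_LO = -10.0
_LOG_K_HI = math.log(DISPERSION_CAP)


@dataclass(frozen=True)
class NBParams:
    """A fitted (mean, dispersion) pair for one gene."""

    mu: float
    k: float
    converged: bool = True
    boundary: bool = False

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if self.boundary and self.k != DISPERSION_CAP:
            raise ValueError("boundary fits must sit at the dispersion cap")

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.k


@dataclass(frozen=True)
class NBPanelParams:
    """Per-gene NB parameters for a gene panel."""

    params: Mapping[str, NBParams]
    selection_mode: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))

    def __len__(self) -> int:
        return len(self.params)

    def __getitem__(self, gene_id: str) -> NBParams:
        return self.params[gene_id]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.params)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (mu, k) vectors in gene order."""
        mu = np.array([p.mu for p in self.params.values()])
        k = np.array([p.k for p in self.params.values()])
        return mu, k

    def to_table(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "mu": [p.mu for p in self.params.values()],
                "k": [p.k for p in self.params.values()],
            },
            index=list(self.params),
        )
        df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_table(cls, path: str | Path) -> "NBPanelParams":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            {
                str(g): NBParams(mu=float(r["mu"]), k=float(r["k"]),
                                 boundary=float(r["k"]) == DISPERSION_CAP)
                for g, r in df.iterrows()
            }
        )


def nb_loglik(counts: np.ndarray, mu: float, k: float) -> float:
    """NB log-likelihood of ``counts`` under mean ``mu``, dispersion ``k``."""
    x = np.asarray(counts, dtype=float)
    return float(
        np.sum(
            gammaln(x + k)
            - gammaln(k)
            - gammaln(x + 1)
            + k * np.log(k / (k + mu))
            + x * np.log(mu / (k + mu))
        )
    )


def fit_nb_mle(counts_g, tol: float = 1e-8) -> NBParams:
    """Fit an intercept-only NB model to one gene's counts.

    ``mu_hat`` is the sample mean; ``k_hat`` maximizes the profile
    log-likelihood over ``log k`` in [-10, log(1e8)] by bounded Brent
    search. When the sample variance does not exceed the mean the MLE of
    ``k`` diverges, so the fit is pinned at the cap with ``boundary=True``.
    """
    x = np.asarray(counts_g)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.any(x < 0) or not np.array_equal(np.rint(x), np.asarray(x, dtype=float)):
        raise ValueError("counts must be non-negative integers")
    if not np.any(x > 0):
        raise ValueError("all-zero count vector: NB mean is not identifiable")
    x = np.asarray(x, dtype=float)
    mu = float(x.mean())
    var = float(x.var(ddof=1))
    if var <= mu:
        return NBParams(mu=mu, k=DISPERSION_CAP, converged=True, boundary=True)

    def neg_profile(log_k: float) -> float:
        return -nb_loglik(x, mu, math.exp(log_k))

    res = minimize_scalar(
        neg_profile,
        bounds=(_LOG_K_LO, _LOG_K_HI),
        method="bounded",
        options={"xatol": tol},
    )
    log_k = float(res.x)
    if log_k >= _LOG_K_HI - 1e-6:
        return NBParams(mu=mu, k=DISPERSION_CAP, converged=bool(res.success),
                        boundary=True)
    return NBParams(mu=mu, k=math.exp(log_k), converged=bool(res.success))


def estimate_panel_params(matrix, panel) -> NBPanelParams:
    """Fit :func:`fit_nb_mle` to every panel gene's row of ``matrix``.

    All-zero genes are excluded with a warning; any other per-gene failure
    is re-raised with the gene id attached.
    """
    params: dict[str, NBParams] = {}
    for gene_id in panel.gene_ids:
        row = matrix.row(gene_id)
        if not np.any(row > 0):
            warnings.warn(
                f"gene {gene_id} has an all-zero row; excluded from NB fits",
                stacklevel=2,
            )
            continue
        try:
            params[gene_id] = fit_nb_mle(row)
        except Exception as exc:  # attach gene id for diagnosis
            raise RuntimeError(f"NB fit failed for gene {gene_id}: {exc}") from exc
    return NBPanelParams(params, selection_mode=panel.selection_mode)
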