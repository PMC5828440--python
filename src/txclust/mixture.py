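"""Gaussian mixture clustering of samples with BIC model selection.

Four covariance families are supported, the spherical/diagonal analogues
of the classic volume/shape catalog:

==================  ===========================================
spherical_equal     one variance shared by all clusters/features
spherical_varying   one variance per cluster
diag_equal          one per-feature variance vector, shared
diag_varying        one per-feature variance vector per cluster
==================  ===========================================

Full-covariance families are deliberately excluded: with p ~ 100 features
and n = 55 samples they are unidentifiable.

BIC follows the maximization convention BIC = 2*loglik - d*log(n); the
best (K, family) pair is the table's argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

COV_MODELS = ("spherical_equal", "spherical_varying", "diag_equal", "diag_varying")

VAR_FLOOR = 1e-6
DEFAULT_K_RANGE = (1, 2, 3, 4, 5)


class FitError(RuntimeError):
    """Raised when every EM restart collapses."""


@dataclass(frozen=True)
class FittedMixture:
    """One converged EM fit for a (K, covariance family) pair."""

    K: int
    cov_model: str
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, p)
    variances: np.ndarray        # (K, p), expanded to per-cluster diagonals
    loglik: float
    n_params: int
    responsibilities: np.ndarray  # (n, K)
    loglik_trace: tuple[float, ...] = ()
    converged: bool = True

    @property
    def labels(self) -> np.ndarray:
        """Hard assignments by maximum responsibility (ties -> lower index),
        1-based."""
        return np.argmax(self.responsibilities, axis=1) + 1


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    chosen_K: int
    chosen_model: str
    bic_table: dict
    seed: int | None = None


def n_free_params(K: int, p: int, cov_model: str) -> int:
    """Free-parameter count d for the BIC penalty."""
    base = (K - 1) + K * p  # weights + means
    variance_terms = {
        "spherical_equal": 1,
        "spherical_varying": K,
        "diag_equal": p,
        "diag_varying": K * p,
    }
    try:
        return base + variance_terms[cov_model]
    except KeyError:
        raise ValueError(f"unknown covariance model {cov_model!r}") from None


def _log_gauss_diag(X: np.ndarray, means: np.ndarray, variances: np.ndarray
                    ) -> np.ndarray:
    """Per-sample log density under each cluster's diagonal Gaussian."""
    n, p = X.shape
    out = np.empty((n, means.shape[0]))
    for c in range(means.shape[0]):
        var = variances[c]
        out[:, c] = -0.5 * (
            p * math.log(2 * math.pi)
            + np.sum(np.log(var))
            + np.sum((X - means[c]) ** 2 / var, axis=1)
        )
    return out


def _m_step(X: np.ndarray, resp: np.ndarray, cov_model: str
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    nc = resp.sum(axis=0)
    if np.any(nc < 1e-10):
        raise FitError("empty cluster")
    weights = nc / n
    means = (resp.T @ X) / nc[:, None]
    # responsibility-weighted squared deviations, per cluster and feature
    sq = np.empty((means.shape[0], p))
    for c in range(means.shape[0]):
        sq[c] = resp[:, c] @ (X - means[c]) ** 2
    if cov_model == "diag_varying":
        variances = sq / nc[:, None]
    elif cov_model == "diag_equal":
        variances = np.broadcast_to(sq.sum(axis=0) / n, (means.shape[0], p)).copy()
    elif cov_model == "spherical_varying":
        variances = np.broadcast_to(
            (sq.sum(axis=1) / (nc * p))[:, None], (means.shape[0], p)
        ).copy()
    elif cov_model == "spherical_equal":
        variances = np.full((means.shape[0], p), sq.sum() / (n * p))
    else:
        raise ValueError(f"unknown covariance model {cov_model!r}")
    variances = variances + VAR_FLOOR
    # a variance pinned at the floor signals a collapsed (near-singular)
    # component — the unbounded-likelihood degeneracy; treat as a failed run
    if np.any(variances <= VAR_FLOOR * (1 + 1e-3)):
        raise FitError("variance collapse at the floor")
    return weights, means, variances


def _kmeanspp_centers(X: np.ndarray, K: int, rng: np.random.Generator
                      ) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:  # degenerate data: pick uniformly
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _one_em_run(
    X: np.ndarray,
    K: int,
    cov_model: str,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> FittedMixture:
    n, p = X.shape
    centers = _kmeanspp_centers(X, K, rng)
    assign = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    resp = np.zeros((n, K))
    resp[np.arange(n), assign] = 1.0
    weights, means, variances = _m_step(X, resp, cov_model)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logdens = _log_gauss_diag(X, means, variances) + np.log(weights)
        norm = logsumexp(logdens, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(logdens - norm[:, None])
        weights, means, variances = _m_step(X, resp, cov_model)
        if loglik - prev < tol:
            converged = True
            break
        prev = loglik
    logdens = _log_gauss_diag(X, means, variances) + np.log(weights)
    norm = logsumexp(logdens, axis=1)
    loglik = float(norm.sum())
    trace.append(loglik)
    resp = np.exp(logdens - norm[:, None])
    return FittedMixture(
        K=K,
        cov_model=cov_model,
        weights=weights,
        means=means,
        variances=variances,
        loglik=loglik,
        n_params=n_free_params(K, p, cov_model),
        responsibilities=resp,
        loglik_trace=tuple(trace),
        converged=converged,
    )


def gmm_fit(
    data,
    K: int,
    cov_model: str = "diag_varying",
    seed: int | None = None,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FittedMixture:
    """EM fit of a K-component diagonal/spherical Gaussian mixture.

    ``data`` is sample x feature. Runs ``n_init`` k-means++-seeded restarts
    and keeps the best log-likelihood; collapsed restarts are retried with
    fresh seeding and an error is raised only if all restarts fail.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D (samples x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds n_samples={X.shape[0]}")
    if cov_model not in COV_MODELS:
        raise ValueError(f"unknown covariance model {cov_model!r}")
    rng = np.random.default_rng(seed)
    best: FittedMixture | None = None
    failures = []
    for _ in range(n_init):
        try:
            fit = _one_em_run(X, K, cov_model, rng, max_iter, tol)
        except FitError as exc:
            failures.append(exc)
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise FitError(
            f"all {n_init} EM restarts collapsed for K={K}, {cov_model}: "
            f"{failures[-1]}"
        )
    return best


def bic(fit: FittedMixture, n: int) -> float:
    """BIC = 2*loglik - d*log(n); larger is better."""
    return 2.0 * fit.loglik - fit.n_params * math.log(n)


def select_model(
    data,
    K_range=DEFAULT_K_RANGE,
    models=COV_MODELS,
    seed: int | None = None,
    n_init: int = 10,
    max_iter: int = 500,
) -> ClusteringResult:
    """Fit every (K, family) pair and return the BIC argmax with the table.

    Failed fits are recorded as missing in the table and never selected.
    """
    X = np.asarray(data, dtype=float)
    K_range = tuple(K_range)
    models = tuple(models)
    if not K_range or not models:
        raise ValueError("K_range and models must be nonempty")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(K_range) * len(models))
    bic_table: dict[tuple[int, str], float | None] = {}
    best_fit: FittedMixture | None = None
    best_bic = -np.inf
    i = 0
    for K in K_range:
        for model in models:
            try:
                fit = gmm_fit(X, K, model, seed=child_seeds[i],
                              n_init=n_init, max_iter=max_iter)
            except (FitError, ValueError):
                bic_table[(K, model)] = None
                i += 1
                continue
            value = bic(fit, X.shape[0])
            bic_table[(K, model)] = value
            if value > best_bic:
                best_bic = value
                best_fit = fit
            i += 1
    if best_fit is None:
        raise FitError("every (K, model) fit failed")
    return ClusteringResult(
        labels=best_fit.labels,
        chosen_K=best_fit.K,
        chosen_model=best_fit.cov_model,
        bic_table=bic_table,
        seed=seed,
    )
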