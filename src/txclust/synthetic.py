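"""Surrogate count matrices with known NB ground truth, plus fixture loading.

The surrogate generator stands in for the real 100 x 55 ovarian count
matrices: per-gene means span several orders of magnitude (log-normal on
the natural log scale) and every gene carries its own over-dispersion. It
makes the whole pipeline runnable and testable with no external files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import CountMatrix, load_count_matrix
from .nb import NBPanelParams, NBParams

FIXTURE_FILES = {
    "top_mad": "pone.0191758.s001",
    "random": "pone.0191758.s002",
}
_FIXTURE_SUFFIXES = (".xlsx", ".tsv", ".csv")


@dataclass(frozen=True)
class SurrogateProfile:
    """Generating distribution for a surrogate gene panel.

    ``ln mu_g ~ Normal(log_mean_loc, log_mean_scale^2)`` and
    ``ln k_g ~ Normal(log_disp_loc, log_disp_scale^2)``.
    """

    n_genes: int = 100
    n_samples: int = 55
    log_mean_loc: float = 4.0
    log_mean_scale: float = 2.0
    log_disp_loc: float = 0.0
    log_disp_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if self.log_mean_scale <= 0 or self.log_disp_scale <= 0:
            raise ValueError("scales must be positive")


def generate_surrogate_panel(
    profile: SurrogateProfile,
) -> tuple[CountMatrix, NBPanelParams]:
    """Draw per-gene (mu, k), simulate NB counts, and return both."""
    rng = np.random.default_rng(profile.seed)
    mu = rng.lognormal(profile.log_mean_loc, profile.log_mean_scale,
                       size=profile.n_genes)
    k = rng.lognormal(profile.log_disp_loc, profile.log_disp_scale,
                      size=profile.n_genes)
    p = k / (k + mu)
    counts = rng.negative_binomial(
        k[:, None], p[:, None], size=(profile.n_genes, profile.n_samples)
    )
    gene_ids = tuple(f"gene_{i + 1:04d}" for i in range(profile.n_genes))
    sample_ids = tuple(f"sample_{i + 1:02d}" for i in range(profile.n_samples))
    matrix = CountMatrix(counts, gene_ids, sample_ids)
    truth = NBPanelParams(
        {g: NBParams(mu=float(m), k=float(kk)) for g, m, kk in zip(gene_ids, mu, k)}
    )
    return matrix, truth


def load_supplementary_fixture(
    name: str, fixtures_dir: str | Path = "fixtures"
) -> CountMatrix:
    """Load one of the optional real-data fixture matrices.

    ``name`` is ``top_mad`` (s001) or ``random`` (s002). The file is looked
    up in ``fixtures_dir`` as .xlsx, .tsv or .csv. Fixtures are optional
    inputs: when absent, run the pipeline with the surrogate source
    (``--surrogate``) instead.
    """
    if name not in FIXTURE_FILES:
        raise ValueError(f"unknown fixture {name!r}; choose from {set(FIXTURE_FILES)}")
    stem = FIXTURE_FILES[name]
    fixtures_dir = Path(fixtures_dir)
    for suffix in _FIXTURE_SUFFIXES:
        path = fixtures_dir / (stem + suffix)
        if path.exists():
            matrix = load_count_matrix(path)
            if matrix.n_genes != 100 or matrix.n_samples != 55:
                raise ValueError(
                    f"{path.name}: expected 100 genes x 55 samples, got "
                    f"{matrix.n_genes} x {matrix.n_samples}"
                )
            return matrix
    raise FileNotFoundError(
        f"fixture {stem}.(xlsx|tsv|csv) not found under {fixtures_dir}/; "
        "these files are optional — run with --surrogate to use synthetic "
        "data instead"
    )
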