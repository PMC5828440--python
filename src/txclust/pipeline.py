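"""Study orchestration: scenarios -> simulation -> transform -> cluster -> score.

Seed policy
-----------
A single master seed drives everything. All scenarios share the same
simulation base seed so that, e.g., the K = 1 batches of the two top-MAD
categories are bit-identical (their designs coincide when there is no
cluster structure). Clustering seeds are derived per (scenario, transform,
replicate) from the master seed via ``SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    CountMatrix,
    GenePanel,
    select_random_filtered,
    select_top_mad,
)
from .metrics import evaluate
from .mixture import COV_MODELS, DEFAULT_K_RANGE, ClusteringResult, FitError, select_model
from .nb import NBPanelParams, estimate_panel_params
from .normality import NormalitySummary, summarize_normality
from .simulate import CATEGORIES, build_design, simulate_batch
from .synthetic import SurrogateProfile, generate_surrogate_panel, load_supplementary_fixture
from .transforms import TRANSFORM_NAMES, get_transform

PANEL_SIZE = 100
METRIC_NAMES = ("ari", "cer", "ci")


@dataclass(frozen=True)
class StudyConfig:
    """Flat configuration of one simulation-study run."""

    source: str = "surrogate"              # "surrogate" | "fixture"
    fixtures_dir: str = "fixtures"
    surrogate_n_genes: int = 400
    categories: tuple[str, ...] = CATEGORIES
    K_set: tuple[int, ...] = (1, 2, 3)
    transforms: tuple[str, ...] = TRANSFORM_NAMES
    n_datasets: int = 100
    seed: int = 0
    K_range: tuple[int, ...] = DEFAULT_K_RANGE
    models: tuple[str, ...] = COV_MODELS
    n_init: int = 10
    blom_axis: str = "per_sample"
    log_pseudocount: float = 1.0
    shift_mode: str = "multiplicative"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.categories or not self.K_set or not self.transforms:
            raise ValueError("categories, K_set and transforms must be nonempty")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        unknown = set(self.transforms) - set(TRANSFORM_NAMES)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in fields}
        for key in ("categories", "K_set", "transforms", "K_range", "models"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregated normality and clustering metrics for one scenario cell."""

    category: str
    K: int
    transform: str
    normality: NormalitySummary
    metric_means: dict[str, float]
    metric_ses: dict[str, float]
    n_datasets: int
    n_failures: int = 0


def _transform_options(config: StudyConfig, name: str) -> dict:
    if name == "log":
        return {"pseudocount": config.log_pseudocount}
    if name == "blom":
        return {"axis": config.blom_axis}
    return {}


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0])


def _clustering_features(values: np.ndarray) -> np.ndarray:
    """Samples-as-rows feature matrix with constant genes dropped.

    Constant features are uninformative and make every diagonal-covariance
    fit singular, so they are removed before clustering.
    """
    X = values.T
    keep = X.var(axis=0) > 0
    if keep.sum() < 2:
        raise FitError("fewer than 2 non-constant genes; nothing to cluster")
    return X[:, keep]


def _source_params(config: StudyConfig) -> dict[str, NBPanelParams]:
    """NB parameter panels for the gene selections the config needs."""
    needed = {
        "top_mad" if c.startswith("T") else "random" for c in config.categories
    }
    matrices: dict[str, CountMatrix] = {}
    panels: dict[str, GenePanel] = {}
    if config.source == "surrogate":
        profile = SurrogateProfile(
            n_genes=config.surrogate_n_genes, n_samples=55, seed=config.seed
        )
        parent, _ = generate_surrogate_panel(profile)
        if "top_mad" in needed:
            matrices["top_mad"] = parent
            panels["top_mad"] = select_top_mad(parent, PANEL_SIZE)
        if "random" in needed:
            matrices["random"] = parent
            panels["random"] = select_random_filtered(
                parent, PANEL_SIZE, seed=config.seed
            )
    elif config.source == "fixture":
        for name in needed:
            matrices[name] = load_supplementary_fixture(name, config.fixtures_dir)
            panels[name] = GenePanel(matrices[name].gene_ids, name)
    else:
        raise ValueError(f"unknown source {config.source!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero gene warnings handled downstream
        return {
            name: estimate_panel_params(matrices[name], panels[name])
            for name in needed
        }


def run_simulation_study(config: StudyConfig) -> list[ScenarioSummary]:
    """Run the full scenario grid and return one summary per cell.

    K = 1 cells carry normality summaries only (there is no multi-cluster
    truth to score); K >= 2 cells additionally carry mean (SE) ARI, CER and
    CI across replicates. Results are written to ``config.output_dir`` when
    set.
    """
    params_by_selection = _source_params(config)
    summaries: list[ScenarioSummary] = []
    log_lines: list[str] = []
    for scen_idx, (category, K) in enumerate(
        (c, k) for c in config.categories for k in config.K_set
    ):
        selection = "top_mad" if category.startswith("T") else "random"
        params = params_by_selection[selection]
        design = build_design(
            category, K, n_datasets=config.n_datasets,
            base_seed=config.seed, shift_mode=config.shift_mode,
        )
        t0 = time.perf_counter()
        batch = simulate_batch(params, design)
        for tf_idx, tf_name in enumerate(config.transforms):
            transform = get_transform(tf_name, **_transform_options(config, tf_name))
            transformed = [transform(ds.counts) for ds in batch]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm = summarize_normality(transformed, category=category, K=K)
            metric_values: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
            n_failures = 0
            if K >= 2:
                for d, (ds, tm) in enumerate(zip(batch, transformed)):
                    cseed = _derived_seed(config.seed, scen_idx, tf_idx, d)
                    try:
                        result = select_model(
                            _clustering_features(tm.values),
                            K_range=config.K_range,
                            models=config.models,
                            seed=cseed,
                            n_init=config.n_init,
                        )
                    except FitError:
                        n_failures += 1
                        continue
                    scores = evaluate(ds.true_labels, result.labels)
                    metric_values["ari"].append(scores.ari)
                    metric_values["cer"].append(scores.cer)
                    metric_values["ci"].append(scores.ci)
            means = {
                m: float(np.mean(v)) if v else float("nan")
                for m, v in metric_values.items()
            }
            ses = {
                m: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1
                else float("nan")
                for m, v in metric_values.items()
            }
            summaries.append(
                ScenarioSummary(
                    category=category, K=K, transform=tf_name, normality=norm,
                    metric_means=means, metric_ses=ses,
                    n_datasets=config.n_datasets, n_failures=n_failures,
                )
            )
        log_lines.append(
            f"{category} K={K}: {config.n_datasets} datasets, "
            f"{time.perf_counter() - t0:.1f}s"
        )
    if config.output_dir is not None:
        write_report(summaries, config.output_dir, config=config,
                     log_lines=log_lines)
    return summaries


def cluster_real_data(
    matrix: CountMatrix,
    transforms=TRANSFORM_NAMES,
    seed: int = 0,
    K_range=DEFAULT_K_RANGE,
    models=COV_MODELS,
    n_init: int = 10,
    blom_axis: str = "per_sample",
) -> dict[str, ClusteringResult | Exception]:
    """Transform and cluster one real count matrix, per transform.

    Errors in one transform are captured and returned in its slot rather
    than aborting the others.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    results: dict[str, ClusteringResult | Exception] = {}
    for tf_idx, name in enumerate(transforms):
        options = {"axis": blom_axis} if name == "blom" else {}
        try:
            tm = get_transform(name, **options)(matrix)
            results[name] = select_model(
                _clustering_features(tm.values),
                K_range=K_range,
                models=models,
                seed=_derived_seed(seed, tf_idx),
                n_init=n_init,
            )
        except Exception as exc:  # noqa: BLE001 - per-transform isolation
            results[name] = exc
    return results


def summaries_to_tables(
    summaries: list[ScenarioSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format normality and clustering-metric tables."""
    norm_rows, metric_rows = [], []
    for s in summaries:
        norm_rows.append(
            {
                "transform": s.transform, "category": s.category, "K": s.K,
                "mean_sk": s.normality.mean_skewness,
                "se_sk": s.normality.se_skewness,
                "mean_kt": s.normality.mean_kurtosis,
                "se_kt": s.normality.se_kurtosis,
                "n_datasets": s.normality.n_datasets,
            }
        )
        if s.K >= 2:
            for m in METRIC_NAMES:
                metric_rows.append(
                    {
                        "transform": s.transform, "category": s.category,
                        "K": s.K, "metric": m,
                        "mean": s.metric_means[m], "se": s.metric_ses[m],
                        "n_failures": s.n_failures,
                    }
                )
    return pd.DataFrame(norm_rows), pd.DataFrame(metric_rows)


def write_report(
    summaries: list[ScenarioSummary],
    outdir: str | Path,
    config: StudyConfig | None = None,
    real_results: dict[str, ClusteringResult | Exception] | None = None,
    sample_ids=None,
    log_lines=None,
) -> list[Path]:
    """Write the normality table, metrics table, assignments and manifest."""
    if not summaries and not real_results:
        raise ValueError("nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    norm_df, metric_df = summaries_to_tables(summaries)
    paths = []
    p = outdir / "normality.tsv"
    norm_df.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "metrics.tsv"
    metric_df.to_csv(p, sep="\t", index=False)
    paths.append(p)
    assign_rows = []
    if real_results:
        for name, res in real_results.items():
            if isinstance(res, Exception):
                continue
            ids = sample_ids or [f"sample_{i + 1:02d}" for i in range(len(res.labels))]
            for sid, lab in zip(ids, res.labels):
                assign_rows.append(
                    {"transform": name, "sample_id": sid, "cluster": int(lab),
                     "chosen_K": res.chosen_K, "chosen_model": res.chosen_model}
                )
    p = outdir / "assignments.tsv"
    pd.DataFrame(assign_rows,
                 columns=["transform", "sample_id", "cluster", "chosen_K",
                          "chosen_model"]).to_csv(p, sep="\t", index=False)
    paths.append(p)
    manifest = {
        "package": "txclust",
        "version": __version__,
        "config": config.to_dict() if config is not None else None,
        "log": list(log_lines or []),
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    paths.append(p)
    return paths


def replay_manifest(manifest_path: str | Path, outdir: str | Path
                    ) -> list[ScenarioSummary]:
    """Re-run a study from its manifest; outputs land in ``outdir``."""
    manifest = json.loads(Path(manifest_path).read_text())
    if manifest.get("config") is None:
        raise ValueError("manifest carries no config; cannot replay")
    config = StudyConfig.from_dict({**manifest["config"], "output_dir": str(outdir)})
    return run_simulation_study(config)
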