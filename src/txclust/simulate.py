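"""Clustered negative-binomial count simulation.

Twelve scenario designs (4 parent categories x K in {1,2,3}) generate
counts from per-gene NB parameters, with cluster structure induced by
multiplying the (mean, dispersion) of a random subset of "up-expressed"
genes in the non-baseline clusters.

Seed policy: replicate ``d`` of a batch uses ``base_seed + d``; up-gene
assignment uses ``base_seed - 1`` so the same genes are shifted in the
K = 2 and K = 3 runs that share a base seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .features import CountMatrix, GenePanel
from .nb import DISPERSION_CAP, NBPanelParams, NBParams

N_SAMPLES = 55

CATEGORIES = ("TE", "RE", "TX", "RX")

#: Cluster sizes by (balance, K). Equal designs split 55 as evenly as
#: possible; unequal designs put 5 samples in the first cluster.
_CLUSTER_SIZES = {
    ("equal", 1): (55,),
    ("equal", 2): (28, 27),
    ("equal", 3): (18, 18, 19),
    ("unequal", 1): (55,),
    ("unequal", 2): (5, 50),
    ("unequal", 3): (5, 17, 33),
}

_UP_FRACTIONS = {1: (0.0,), 2: (0.0, 0.10), 3: (0.0, 0.10, 0.20)}

#: (dmu1, dmu2, dk1, dk2): fold-change shifts for the second and third
#: clusters' up-expressed genes.
DEFAULT_SHIFTS = (math.exp(3.375), math.exp(5.5), 1.01, 1.03)


@dataclass(frozen=True)
class SimulationDesign:
    """One simulation scenario: parent category, K, sizes, shifts, seeds."""

    category: str
    K: int
    cluster_sizes: tuple[int, ...]
    up_fractions: tuple[float, ...]
    shifts: tuple[float, float, float, float] = DEFAULT_SHIFTS
    shift_mode: str = "multiplicative"
    n_datasets: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.K not in (1, 2, 3):
            raise ValueError("K must be 1, 2, or 3")
        if len(self.cluster_sizes) != self.K:
            raise ValueError("one size per cluster required")
        if sum(self.cluster_sizes) != N_SAMPLES:
            raise ValueError(f"cluster sizes must sum to {N_SAMPLES}")
        if self.up_fractions[0] != 0.0:
            raise ValueError("the baseline cluster has no up-expressed genes")
        if self.shift_mode not in ("multiplicative", "additive"):
            raise ValueError("shift_mode must be multiplicative or additive")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated count matrix with its ground truth."""

    counts: CountMatrix
    true_labels: np.ndarray  # cluster index per sample, 1-based
    up_genes: dict[int, frozenset[str]]  # cluster index -> shifted gene ids
    seed: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.true_labels, dtype=np.int64)
        labels.setflags(write=False)
        object.__setattr__(self, "true_labels", labels)


def build_design(
    category: str,
    K: int,
    n_datasets: int = 100,
    base_seed: int = 0,
    shift_mode: str = "multiplicative",
) -> SimulationDesign:
    """Populate a scenario design from the study's size and shift tables."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if K not in (1, 2, 3):
        raise ValueError("K must be 1, 2, or 3")
    balance = "equal" if category in ("TE", "RE") else "unequal"
    return SimulationDesign(
        category=category,
        K=K,
        cluster_sizes=_CLUSTER_SIZES[(balance, K)],
        up_fractions=_UP_FRACTIONS[K],
        n_datasets=n_datasets,
        base_seed=base_seed,
        shift_mode=shift_mode,
    )


def assign_up_genes(
    panel: GenePanel, design: SimulationDesign, seed: int | None = None
) -> dict[int, frozenset[str]]:
    """Choose disjoint up-expressed gene sets for the shifted clusters.

    A single seeded permutation of the panel supplies both sets: cluster 2
    takes the first 10% and cluster 3 the next 20%, so cluster 2's set is
    identical across K = 2 and K = 3 for a shared seed.
    """
    if seed is None:
        seed = design.base_seed - 1
    n_genes = len(panel)
    counts = []
    for frac in design.up_fractions[1:]:
        raw = frac * n_genes
        n_up = round(raw)
        if abs(raw - n_up) > 1e-9:
            raise ValueError(f"up fraction {frac} is not integral for {n_genes} genes")
        counts.append(n_up)
    if sum(counts) > n_genes:
        raise ValueError("requested up-gene sets exceed the panel size")
    rng = np.random.default_rng(seed & (2**64 - 1))  # two's complement if < 0
    perm = rng.permutation(n_genes)
    sets: dict[int, frozenset[str]] = {}
    start = 0
    for cluster, n_up in enumerate(counts, start=2):
        sets[cluster] = frozenset(panel.gene_ids[perm[i]]
                                  for i in range(start, start + n_up))
        start += n_up
    return sets


def _shift_params(p: NBParams, dmu: float, dk: float, mode: str) -> NBParams:
    if mode == "multiplicative":
        mu, k = p.mu * dmu, p.k * dk
    else:
        mu, k = p.mu + dmu, p.k + dk
    k = min(k, DISPERSION_CAP)
    return NBParams(mu=mu, k=k, converged=p.converged, boundary=k == DISPERSION_CAP)


def apply_effect_shifts(
    params: NBPanelParams,
    design: SimulationDesign,
    up_genes: dict[int, frozenset[str]],
) -> list[NBPanelParams]:
    """Return per-cluster parameter panels (index 0 = baseline, unshifted).

    Up genes in cluster 2 get (dmu1, dk1); up genes in cluster 3 get
    (dmu2, dk2). All other genes keep their fitted parameters.
    """
    dmu1, dmu2, dk1, dk2 = design.shifts
    cluster_shift = {2: (dmu1, dk1), 3: (dmu2, dk2)}
    out = [params]
    for cluster in range(2, design.K + 1):
        dmu, dk = cluster_shift[cluster]
        up = up_genes.get(cluster, frozenset())
        shifted = {
            g: _shift_params(p, dmu, dk, design.shift_mode) if g in up else p
            for g, p in params.params.items()
        }
        out.append(NBPanelParams(shifted, selection_mode=params.selection_mode))
    return out


def simulate_dataset(
    params: NBPanelParams,
    design: SimulationDesign,
    up_genes: dict[int, frozenset[str]],
    seed: int,
) -> SimulatedDataset:
    """Draw one clustered NB count matrix (genes x 55 samples).

    Every entry is an independent NB draw with the sample's
    cluster-specific (mu, k); samples are laid out in label-blocked column
    order.
    """
    per_cluster = apply_effect_shifts(params, design, up_genes)
    rng = np.random.default_rng(seed)
    gene_ids = params.gene_ids
    blocks = []
    labels = []
    for cluster_idx, size in enumerate(design.cluster_sizes):
        mu, k = per_cluster[cluster_idx].arrays()
        p = k / (k + mu)
        block = rng.negative_binomial(k[:, None], p[:, None],
                                      size=(len(gene_ids), size))
        blocks.append(block)
        labels.extend([cluster_idx + 1] * size)
    counts = np.concatenate(blocks, axis=1)
    sample_ids = tuple(f"sample_{i + 1:02d}" for i in range(counts.shape[1]))
    return SimulatedDataset(
        counts=CountMatrix(counts, gene_ids, sample_ids),
        true_labels=np.array(labels),
        up_genes=dict(up_genes),
        seed=seed,
    )


def simulate_batch(
    params: NBPanelParams, design: SimulationDesign
) -> list[SimulatedDataset]:
    """Simulate ``design.n_datasets`` replicates with seeds base_seed + d."""
    panel = GenePanel(params.gene_ids, params.selection_mode or "top_mad")
    up_genes = assign_up_genes(panel, design)
    return [
        simulate_dataset(params, design, up_genes, design.base_seed + d)
        for d in range(design.n_datasets)
    ]
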