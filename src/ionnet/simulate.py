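"""Synthetic data generators for every pipeline stage.

These emulate the statistical structure the analysis assumes rather than any
particular deposited dataset: log-normal protein intensities with bait-specific
spiked enrichment, intensity-dependent (left-censored, MNAR) missingness,
IgG control pulldowns drawn from background, correlated cardiomyocyte
subpopulation expression, per-gene LD-block GWAS p-value tables with planted
signals, and two-channel binary cluster images with a known proximal fraction.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BaitDesign, IntensityMatrix, ProteinAnnotations

__all__ = [
    "SynthSpec",
    "SpikeTruth",
    "generate_apms",
    "generate_expression",
    "generate_ecg_gwas",
    "generate_cluster_images",
]


@dataclass
class SpikeTruth:
    """Ground truth of the simulated interactome."""

    interactors: dict[str, set[str]]  # bait -> spiked protein ids
    effect_sizes: dict[tuple[str, str], float]  # (bait, protein) -> log2 effect
    shared_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shared: dict[str, set[str]] = {}
        for bait, prots in self.interactors.items():
            for p in prots:
                shared.setdefault(p, set()).add(bait)
        self.shared_map = shared

    def all_spiked(self) -> set[str]:
        return set(self.shared_map)


@dataclass
class SynthSpec:
    """Parameters of the AP-MS simulation.

    Intensities are generated on log2 scale: per-protein base abundances are
    drawn N(background_mean_log2, protein_sd_log2^2) and replicate measurements
    add N(0, background_sd_log2^2) noise.  True interactors gain
    ``effect_size_log2`` in their bait's replicates only.  Missingness is
    logistic left-censoring in log2 intensity, calibrated so the realized
    total missing fraction matches ``missing_total_fraction``.
    """

    n_proteins: int = 2000
    n_baits: int = 6
    replicates_per_bait: int = 4
    igg_replicates: int = 4
    families: Mapping[str, str] | None = None  # bait -> family label
    n_true_per_bait: int | Mapping[str, int] = 20
    n_shared: int = 0  # extra interactors spiked into two baits each
    effect_size_log2: float = 4.0
    background_mean_log2: float = 25.0
    background_sd_log2: float = 1.0  # replicate noise sd
    protein_sd_log2: float = 2.0  # spread of per-protein base abundance
    missing_total_fraction: float = 0.25
    mnar_steepness: float = 1.0
    proteome_samples: int = 3
    proteome_missing_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_total_fraction < 1:
            raise ValueError("missing_total_fraction must lie in [0, 1)")
        if not 0 <= self.proteome_missing_fraction < 1:
            raise ValueError("proteome_missing_fraction must lie in [0, 1)")
        for name in ("n_proteins", "n_baits", "replicates_per_bait"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        n_true = self.n_true_per_bait
        counts = n_true.values() if isinstance(n_true, Mapping) else [n_true]
        if any(c < 0 for c in counts):
            raise ValueError("n_true_per_bait must be non-negative")
        if max(counts) > self.n_proteins:
            raise ValueError("n_true_per_bait exceeds n_proteins")
        if self.n_proteins <= self.n_baits:
            raise ValueError("n_proteins must exceed n_baits")

    def bait_names(self) -> list[str]:
        return [f"bait{i + 1}" for i in range(self.n_baits)]

    def n_true_for(self, bait: str) -> int:
        if isinstance(self.n_true_per_bait, Mapping):
            return int(self.n_true_per_bait.get(bait, 0))
        return int(self.n_true_per_bait)


def _censor_midpoint(x: np.ndarray, steepness: float, target: float) -> float:
    """Bisect the logistic midpoint so mean missing probability hits target."""
    if target <= 0:
        return -np.inf

    def frac(x0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(steepness * (x - x0)))))

    lo, hi = x.min() - 50.0, x.max() + 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _apply_mnar(
    log2_values: np.ndarray,
    fraction: float,
    steepness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return values with logistic left-censored missingness (NaN) applied."""
    if fraction <= 0:
        return log2_values
    x0 = _censor_midpoint(log2_values.ravel(), steepness, fraction)
    p_missing = 1.0 / (1.0 + np.exp(steepness * (log2_values - x0)))
    out = log2_values.copy()
    out[rng.random(log2_values.shape) < p_missing] = np.nan
    return out


def generate_apms(
    spec: SynthSpec,
) -> tuple[IntensityMatrix, BaitDesign, ProteinAnnotations, SpikeTruth, IntensityMatrix]:
    """Simulate a parallel AP-MS screen.

    Returns ``(pulldowns, design, annotations, truth, proteome)``.  The
    pulldown matrix contains all bait replicate columns plus IgG controls; the
    deep-proteome matrix shares the protein space and has its own (much lower)
    missingness.  Bait proteins themselves are included as spiked entries of
    their own pulldown, mirroring a bait being among the most abundant
    proteins in its precipitate.  Matrices are returned on the raw (2**x)
    scale with missing values as NaN, ready for ingestion.
    """
    rng = np.random.default_rng(spec.rng_seed)
    baits = spec.bait_names()
    n_reps = spec.replicates_per_bait
    # the first n_baits protein slots are the bait proteins themselves, named
    # after their bait so downstream calling can flag them
    proteins = baits + [
        f"P{i + 1:05d}" for i in range(spec.n_proteins - spec.n_baits)
    ]

    base = rng.normal(spec.background_mean_log2, spec.protein_sd_log2, spec.n_proteins)

    # choose spiked proteins: bait i's own "bait protein" is proteins[i]; the
    # remaining true interactors are drawn without replacement from the rest
    interactors: dict[str, set[str]] = {}
    effects: dict[tuple[str, str], float] = {}
    pool = rng.permutation(np.arange(spec.n_baits, spec.n_proteins))
    cursor = 0
    for i, bait in enumerate(baits):
        n_true = spec.n_true_for(bait)
        chosen = {proteins[i]}  # the bait protein itself
        take = max(0, n_true - 1)
        chosen |= {proteins[j] for j in pool[cursor : cursor + take]}
        cursor += take
        interactors[bait] = chosen
        for p in chosen:
            effects[(bait, p)] = spec.effect_size_log2
    for _ in range(spec.n_shared):
        p = proteins[pool[cursor]]
        cursor += 1
        b1, b2 = rng.choice(spec.n_baits, size=2, replace=False)
        for b in (baits[b1], baits[b2]):
            interactors[b].add(p)
            effects[(b, p)] = spec.effect_size_log2
    truth = SpikeTruth(interactors, effects)

    sample_ids = [f"{b}_r{r + 1}" for b in baits for r in range(n_reps)]
    igg_ids = [f"IgG_r{r + 1}" for r in range(spec.igg_replicates)]
    n_cols = len(sample_ids) + len(igg_ids)
    log2_vals = base[:, None] + rng.normal(
        0.0, spec.background_sd_log2, (spec.n_proteins, n_cols)
    )
    pidx = {p: i for i, p in enumerate(proteins)}
    for bi, bait in enumerate(baits):
        cols = slice(bi * n_reps, (bi + 1) * n_reps)
        for p in interactors[bait]:
            log2_vals[pidx[p], cols] += effects[(bait, p)]

    log2_vals = _apply_mnar(
        log2_vals, spec.missing_total_fraction, spec.mnar_steepness, rng
    )
    pulldowns = IntensityMatrix(
        pd.DataFrame(
            np.exp2(log2_vals), index=proteins, columns=sample_ids + igg_ids
        )
    )

    prot_ids = [f"prot_r{r + 1}" for r in range(spec.proteome_samples)]
    prot_vals = base[:, None] + rng.normal(
        0.0, spec.background_sd_log2, (spec.n_proteins, spec.proteome_samples)
    )
    prot_vals = _apply_mnar(
        prot_vals, spec.proteome_missing_fraction, spec.mnar_steepness, rng
    )
    proteome = IntensityMatrix(
        pd.DataFrame(np.exp2(prot_vals), index=proteins, columns=prot_ids)
    )

    if spec.families is not None:
        family_map = {b: spec.families.get(b, b) for b in baits}
    else:
        family_map = {b: b for b in baits}
    design = BaitDesign(
        baits,
        {b: sample_ids[i * n_reps : (i + 1) * n_reps] for i, b in enumerate(baits)},
        family_map,
        igg_ids,
    )

    # peptide counts scale with abundance; spiked entries get a boost in their
    # own bait so specificity ranking has signal to work with
    coverage = pd.Series(
        np.clip(rng.normal(35, 15, spec.n_proteins), 1, 95), index=proteins
    )
    counts = np.maximum(
        0, rng.poisson(5.0, (spec.n_proteins, spec.n_baits))
    ).astype(int)
    for bi, bait in enumerate(baits):
        for p in interactors[bait]:
            counts[pidx[p], bi] += rng.poisson(15.0)
    annotations = ProteinAnnotations(
        coverage, pd.DataFrame(counts, index=proteins, columns=baits)
    )
    return pulldowns, design, annotations, truth, proteome


def generate_expression(
    genes: Sequence[str],
    cell_types: Sequence[str],
    cm_subpop_corr: float,
    seed: int,
    cm_columns: Sequence[str] | None = None,
    zero_fraction: float = 0.02,
    cm_mean: float = 5.0,
    other_mean: float = 2.0,
    sd: float = 1.0,
) -> pd.DataFrame:
    """Gene x cell-type mean-expression matrix with correlated CM columns.

    Cardiomyocyte (CM) subpopulation columns share a latent factor so their
    pairwise Pearson correlation equals ``cm_subpop_corr``; a ``zero_fraction``
    of genes is set to zero in all CM columns (not CM-expressed).
    """
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if not 0 <= cm_subpop_corr <= 1:
        raise ValueError("cm_subpop_corr must lie in [0, 1]")
    if cm_columns is None:
        cm_columns = list(cell_types)[:2]
    cm_columns = list(cm_columns)
    unknown = set(cm_columns) - set(cell_types)
    if unknown:
        raise ValueError(f"cm_columns not in cell_types: {sorted(unknown)}")
    if len(cm_columns) < 2:
        raise ValueError("need at least 2 cardiomyocyte subpopulation columns")

    rng = np.random.default_rng(seed)
    n = len(genes)
    r = cm_subpop_corr
    latent = rng.standard_normal(n)
    data = {}
    for ct in cell_types:
        if ct in cm_columns:
            eps = rng.standard_normal(n)
            vals = cm_mean + sd * (np.sqrt(r) * latent + np.sqrt(1 - r) * eps)
        else:
            vals = other_mean + sd * rng.standard_normal(n)
        data[ct] = np.clip(vals, 0.0, None)
    expr = pd.DataFrame(data, index=list(genes))
    if zero_fraction > 0:
        zero_mask = rng.random(n) < zero_fraction
        expr.loc[zero_mask, cm_columns] = 0.0
    expr.attrs["cm_columns"] = cm_columns
    return expr


def generate_ecg_gwas(
    genes: Sequence[str],
    variants_per_block: int,
    n_timepoints: int = 500,
    signal_genes: set[str] | frozenset[str] = frozenset(),
    signal_minp: float = 1e-9,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-gene variant x timepoint p-value tables.

    Null genes carry Uniform(0, 1) entries.  Each signal gene has exactly one
    planted entry equal to ``signal_minp``, guaranteed below all its other
    entries (the rest are rescaled into (signal_minp, 1]).
    """
    signal_genes = set(signal_genes)
    unknown = signal_genes - set(genes)
    if unknown:
        raise ValueError(f"signal genes not in gene list: {sorted(unknown)}")
    if not 0 < signal_minp < 1:
        raise ValueError("signal_minp must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    cols = [f"t{j + 1}" for j in range(n_timepoints)]
    for gene in genes:
        if variants_per_block == 0:
            tables[gene] = pd.DataFrame(columns=cols, dtype=float)
            continue
        rows = [f"{gene}_v{i + 1}" for i in range(variants_per_block)]
        p = rng.random((variants_per_block, n_timepoints))
        if gene in signal_genes:
            p = signal_minp + p * (1.0 - signal_minp)  # strictly above the plant
            vi = rng.integers(variants_per_block)
            ti = rng.integers(n_timepoints)
            p[vi, ti] = signal_minp
        tables[gene] = pd.DataFrame(p, index=rows, columns=cols)
    return tables


def _disc_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def _stamp(image: np.ndarray, cy: int, cx: int, radius: int) -> None:
    mask = _disc_mask(radius)
    image[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] |= mask


def generate_cluster_images(
    shape: tuple[int, int] = (256, 256),
    n_clusters_a: int = 20,
    n_clusters_b: int = 20,
    target_proximal_fraction: float = 0.3,
    pixel_nm: float = 20.0,
    seed: int = 0,
    radius_range: tuple[int, int] = (2, 5),
    max_attempts: int = 20000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two binary channels of disc-shaped clusters with known proximity truth.

    ``round(target * n_clusters_a)`` A-clusters are placed overlapping a
    B-cluster by one pixel (edge gap < 1 px, i.e. < ``pixel_nm`` nm); the rest
    keep an edge gap of at least 3 px from every B-cluster.  A-clusters (and
    B-clusters) are mutually separated so connected-component labeling
    recovers the construction exactly.  Returns (A, B, realized fraction).
    """
    if not 0 <= target_proximal_fraction <= 1:
        raise ValueError("target_proximal_fraction must lie in [0, 1]")
    if n_clusters_a < 1 or n_clusters_b < 1:
        raise ValueError("need at least one cluster per channel")
    rng = np.random.default_rng(seed)
    h, w = shape
    img_a = np.zeros(shape, dtype=bool)
    img_b = np.zeros(shape, dtype=bool)
    rmax = radius_range[1]

    def sample_center() -> tuple[int, int, int]:
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        margin = rmax + 4
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        return cy, cx, r

    def far_from(centers: list[tuple[int, int, int]], cy, cx, r, gap) -> bool:
        return all(
            np.hypot(cy - y, cx - x) >= r + rr + gap for y, x, rr in centers
        )

    b_centers: list[tuple[int, int, int]] = []
    attempts = 0
    while len(b_centers) < n_clusters_b:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("cannot place B clusters at requested density")
        cy, cx, r = sample_center()
        # keep B clusters well apart so an adjacent A touches only its partner
        if far_from(b_centers, cy, cx, r, gap=2 * rmax + 8):
            b_centers.append((cy, cx, r))
            _stamp(img_b, cy, cx, r)

    n_prox = round(target_proximal_fraction * n_clusters_a)
    a_centers: list[tuple[int, int, int]] = []
    # proximal A-clusters: overlap a distinct B-cluster by one pixel
    for i in range(n_prox):
        by, bx, br = b_centers[i % len(b_centers)]
        placed = False
        for _ in range(max_attempts):
            r = int(rng.integers(radius_range[0], radius_range[1] + 1))
            theta = rng.uniform(0, 2 * np.pi)
            d = br + r - 1  # one-pixel overlap
            cy = int(round(by + d * np.sin(theta)))
            cx = int(round(bx + d * np.cos(theta)))
            if not (rmax < cy < h - rmax and rmax < cx < w - rmax):
                continue
            if not far_from(a_centers, cy, cx, r, gap=3):
                continue
            # require the rasterized discs to share >=1 pixel so the measured
            # edge-to-edge pixel distance is exactly 0 (< 1 px rule)
            candidate = np.zeros(shape, dtype=bool)
            _stamp(candidate, cy, cx, r)
            if not (candidate & img_b).any():
                continue
            a_centers.append((cy, cx, r))
            img_a |= candidate
            placed = True
            break
        if not placed:
            raise RuntimeError("cannot place proximal A cluster")
    # distal A-clusters: edge gap >= 3 px from every B cluster
    while len(a_centers) < n_clusters_a:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("cannot place distal A clusters at requested density")
        cy, cx, r = sample_center()
        if far_from(b_centers, cy, cx, r, gap=3) and far_from(a_centers, cy, cx, r, gap=3):
            a_centers.append((cy, cx, r))
            _stamp(img_a, cy, cx, r)

    realized = n_prox / n_clusters_a
    return img_a, img_b, realized
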