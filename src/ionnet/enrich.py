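"""Interactor calling from parallel pulldowns.

The stage normalizes raw intensities, builds a per-protein control
distribution from the other pulldowns run in parallel (complementary
medians), falls back to IgG controls, scaled deep-proteome values and
left-shifted random imputation where data are missing, and calls significant
bait-specific enrichment with an s0-moderated two-sample statistic under a
permutation-based FDR.

Statistic
---------
For a protein with bait-side values x and control-side values y,

    d = (mean(x) - mean(y)) / (se_pooled + s0)

where se_pooled is the pooled two-sample standard error and s0 is a
stabilization constant that makes the significance boundary depend on the
fold change as well as the p-value.  The reported p-value is the classical
two-sided pooled t-test p; s0 enters only the cutoff geometry.  The FDR at a
threshold c on |d| is estimated by permuting the bait/control column labels
jointly across proteins; with at most 8 columns in total, all distinct label
assignments are enumerated exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BaitDesign,
    IntensityMatrix,
    PipelineConfig,
    ProteinAnnotations,
    log2_transform,
)

__all__ = [
    "quantile_normalize",
    "pulldown_presence",
    "eligibility_threshold",
    "complementary_median",
    "scale_proteome",
    "build_control_matrix",
    "ControlModel",
    "s0_statistic",
    "permutation_fdr_call",
    "SignificanceCall",
    "call_interactors",
]

PROVENANCE_LABELS = {
    0: "complementary_median",
    1: "igg",
    2: "proteome_scaled",
    3: "random_imputed",
}


# ---------------------------------------------------------------------------
# normalization


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize the samples of a raw-scale matrix.

    Every column is mapped onto a common reference distribution (the
    row-means of the column-sorted matrix).  Missing entries stay missing;
    for columns with missing values the reference is interpolated onto the
    column's observed quantiles.  Tied values within a column receive the
    mean of the reference values their positions span.
    """
    if matrix.log_scale:
        raise ValueError("quantile_normalize expects raw-scale values")
    X = matrix.values.astype(float)
    n, p = X.shape
    n_obs = np.sum(~np.isnan(X), axis=0)
    if np.any(n_obs == 0):
        bad = [matrix.sample_ids[j] for j in np.where(n_obs == 0)[0]]
        raise ValueError(f"all-missing sample columns: {bad}")
    if p == 1:
        return IntensityMatrix(matrix.data.copy(), log_scale=False)

    # reference distribution of length n: per-column sorted observed values
    # interpolated onto a common quantile grid, averaged across columns
    grid = np.linspace(0.0, 1.0, n)
    ref_cols = np.empty((n, p))
    for j in range(p):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        if col.size == 1:
            ref_cols[:, j] = col[0]
        else:
            ref_cols[:, j] = np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    ref = ref_cols.mean(axis=1)

    out = np.full_like(X, np.nan)
    for j in range(p):
        obs = ~np.isnan(X[:, j])
        vals = X[obs, j]
        m = vals.size
        if m == 1:
            target = np.array([np.median(ref)])
        else:
            ref_q = np.interp(np.linspace(0.0, 1.0, m), grid, ref)
            order = np.argsort(vals, kind="stable")
            target = np.empty(m)
            target[order] = ref_q
            # ties: average the reference values the tied group occupies
            sorted_vals = vals[order]
            k = 0
            while k < m:
                k2 = k
                while k2 + 1 < m and sorted_vals[k2 + 1] == sorted_vals[k]:
                    k2 += 1
                if k2 > k:
                    target[order[k : k2 + 1]] = ref_q[k : k2 + 1].mean()
                k = k2 + 1
        out[obs, j] = target
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.protein_ids, columns=matrix.sample_ids),
        log_scale=False,
    )


# ---------------------------------------------------------------------------
# presence / eligibility


def eligibility_threshold(design: BaitDesign) -> tuple[int, int]:
    """(total bait pulldown samples, strict lower bound for eligibility).

    A protein is eligible for complementary-median control construction when
    it is observed in strictly more than half of all bait pulldown samples:
    e.g. 16 baits x 4 replicates give 64 samples and a bound of 32.
    """
    total = len(design.pulldown_samples)
    return total, total // 2


def pulldown_presence(matrix: IntensityMatrix, design: BaitDesign) -> pd.DataFrame:
    """Per-protein observation count across bait pulldowns and eligibility.

    IgG control columns are excluded from the count.  Eligibility is the
    strict more-than-half rule.
    """
    samples = design.pulldown_samples
    missing = [s for s in samples if s not in matrix.data.columns]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    total, bound = eligibility_threshold(design)
    counts = matrix.data[samples].notna().sum(axis=1)
    return pd.DataFrame(
        {"n_observed": counts.astype(int), "eligible": counts > bound}
    )


# ---------------------------------------------------------------------------
# control construction


def complementary_median(
    matrix: IntensityMatrix,
    design: BaitDesign,
    bait: str,
    protein: str,
) -> float:
    """Median of a protein across all out-of-family pulldown replicates.

    Baits in the target bait's family are excluded entirely, so shared true
    interactors of related channels do not mask each other.  Returns NaN when
    the exclusion leaves no observed values.
    """
    if bait not in design.baits:
        raise KeyError(f"unknown bait: {bait!r}")
    cols = [
        s for b in design.out_of_family_baits(bait) for s in design.replicate_map[b]
    ]
    if not cols:
        return float("nan")
    vals = matrix.data.loc[protein, cols].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(np.median(vals)) if vals.size else float("nan")


def _slot_medians(
    matrix: IntensityMatrix, design: BaitDesign, bait: str
) -> np.ndarray:
    """Per-replicate-slot complementary medians, shape (n_proteins, n_reps).

    Slot r takes the median over out-of-family baits of their r-th replicate
    value, giving a control vector with replicate-to-replicate spread rather
    than four identical copies of one grand median.
    """
    n_reps = len(design.replicate_map[bait])
    others = design.out_of_family_baits(bait)
    out = np.full((len(matrix.protein_ids), n_reps), np.nan)
    if not others:
        return out
    for r in range(n_reps):
        cols = [
            design.replicate_map[b][r]
            for b in others
            if len(design.replicate_map[b]) > r
        ]
        if cols:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[:, r] = np.nanmedian(matrix.data[cols].to_numpy(), axis=1)
    return out


def scale_proteome(
    proteome: IntensityMatrix,
    pulldown: IntensityMatrix,
    min_shared: int = 20,
    iqr_zero_policy: str = "error",
) -> IntensityMatrix:
    """Affine-match the deep proteome onto the pulldown intensity scale.

    Both inputs must be log2-scale.  The map is fitted on the shared proteins
    so that the scaled proteome's median equals the pulldown median and its
    IQR equals the pulldown IQR, then applied to all proteome values.
    """
    if not (proteome.log_scale and pulldown.log_scale):
        raise ValueError("scale_proteome expects log2-scale matrices")
    shared = proteome.data.index.intersection(pulldown.data.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared proteins (< {min_shared}); cannot anchor scaling"
        )
    pv = proteome.data.loc[shared].to_numpy().ravel()
    dv = pulldown.data.loc[shared].to_numpy().ravel()
    pv, dv = pv[~np.isnan(pv)], dv[~np.isnan(dv)]
    med_p, med_d = np.median(pv), np.median(dv)
    iqr_p = np.subtract(*np.percentile(pv, [75, 25]))
    iqr_d = np.subtract(*np.percentile(dv, [75, 25]))
    if iqr_p == 0:
        if iqr_zero_policy == "shift":
            slope = 1.0
        else:
            raise ValueError("proteome IQR is zero; cannot fit affine scaling")
    else:
        slope = iqr_d / iqr_p
    scaled = (proteome.data - med_p) * slope + med_d
    return IntensityMatrix(scaled, log_scale=True)


@dataclass
class ControlModel:
    """Control-side values for one bait: (n_proteins, n_reps) with provenance.

    ``provenance`` holds integer codes per value (see PROVENANCE_LABELS);
    ``eligibility`` records which proteins passed the more-than-half rule.
    """

    protein_ids: list[str]
    values: np.ndarray
    provenance: np.ndarray
    eligibility: pd.Series

    def provenance_labels(self) -> list[str]:
        """Comma-joined distinct provenance per protein, in cascade order."""
        out = []
        for row in self.provenance:
            codes = sorted(set(int(c) for c in row if c >= 0))
            out.append(",".join(PROVENANCE_LABELS[c] for c in codes))
        return out


def build_control_matrix(
    matrix: IntensityMatrix,
    design: BaitDesign,
    bait: str,
    config: PipelineConfig,
    proteome: IntensityMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> ControlModel:
    """Cascade of control values for every protein of one bait.

    Per protein (and per replicate slot within it):

    1. complementary slot medians across out-of-family pulldowns, for
       proteins passing the more-than-half eligibility rule;
    2. otherwise the observed IgG control values;
    3. otherwise the protein's median in the scaled deep proteome;
    4. otherwise a random draw from a left-shifted normal
       N(mean - downshift*sd, (width*sd)^2), with mean/sd taken over all
       observed pulldown values (log2 scale).

    ``matrix`` must be normalized and log2-scale; ``proteome`` (optional)
    must already be scaled onto the pulldown scale.
    """
    if not matrix.log_scale:
        raise ValueError("control construction expects a log2-scale matrix")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_reps = len(design.replicate_map[bait])
    proteins = matrix.protein_ids
    n = len(proteins)
    values = np.full((n, n_reps), np.nan)
    prov = np.full((n, n_reps), -1, dtype=int)

    presence = pulldown_presence(matrix, design)
    eligible = presence["eligible"].to_numpy()

    sm = _slot_medians(matrix, design, bait)
    fill = eligible[:, None] & ~np.isnan(sm)
    values[fill] = sm[fill]
    prov[fill] = 0

    if design.igg_samples:
        igg = matrix.data[design.igg_samples].to_numpy()
        for r in range(n_reps):
            col = igg[:, r % igg.shape[1]]
            fill = np.isnan(values[:, r]) & ~np.isnan(col)
            values[fill, r] = col[fill]
            prov[fill, r] = 1

    if proteome is not None:
        if not proteome.log_scale:
            raise ValueError("proteome must be log2-scale (already scaled)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pmed = np.nanmedian(
                proteome.data.reindex(proteins).to_numpy(), axis=1
            )
        for r in range(n_reps):
            fill = np.isnan(values[:, r]) & ~np.isnan(pmed)
            values[fill, r] = pmed[fill]
            prov[fill, r] = 2

    pooled = matrix.data[design.pulldown_samples].to_numpy()
    pooled = pooled[~np.isnan(pooled)]
    mu = pooled.mean() - config.imputation_downshift * pooled.std(ddof=1)
    sd = config.imputation_width * pooled.std(ddof=1)
    fill = np.isnan(values)
    if fill.any():
        values[fill] = rng.normal(mu, sd, size=int(fill.sum()))
        prov[fill] = 3

    return ControlModel(proteins, values, prov, presence["eligible"])


# ---------------------------------------------------------------------------
# statistic


def _d_matrix(
    bait_vals: np.ndarray, ctrl_vals: np.ndarray, s0: float
) -> np.ndarray:
    """Vectorized s0-moderated statistic, one value per row."""
    n1, n2 = bait_vals.shape[1], ctrl_vals.shape[1]
    m1, m2 = bait_vals.mean(axis=1), ctrl_vals.mean(axis=1)
    v1 = bait_vals.var(axis=1, ddof=1)
    v2 = ctrl_vals.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / (se + s0)


def s0_statistic(
    bait_values: Sequence[float], control_values: Sequence[float], s0: float
) -> tuple[float, float]:
    """(d, p) for one protein: moderated statistic and classical t-test p.

    With s0 = 0, d is exactly the pooled two-sample t statistic.  Identical
    groups give d = 0 and p = 1.
    """
    x = np.asarray(bait_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values on each side")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    d = float(_d_matrix(x[None, :], y[None, :], s0)[0])
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    return d, p


def _t_pvalues(bait_vals: np.ndarray, ctrl_vals: np.ndarray) -> np.ndarray:
    """Two-sided pooled t-test p-values per row, degenerate rows -> 1."""
    n1, n2 = bait_vals.shape[1], ctrl_vals.shape[1]
    t = _d_matrix(bait_vals, ctrl_vals, 0.0)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    diff = bait_vals.mean(axis=1) - ctrl_vals.mean(axis=1)
    degenerate = ~np.isfinite(t)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    return np.clip(p, np.finfo(float).tiny, 1.0)


# ---------------------------------------------------------------------------
# permutation FDR


@dataclass
class SignificanceCall:
    """Outcome of the permutation-FDR thresholding for one bait."""

    d: np.ndarray
    threshold: float  # on |d|; inf when nothing can be called
    est_fdr: float  # estimated FDR at the threshold
    significant: np.ndarray  # boolean per protein
    exact: bool  # True when all label assignments were enumerated
    n_assignments: int


def _label_assignments(
    n1: int, n2: int, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Index sets of the bait side under each permutation, (k, n1)."""
    total = n1 + n2
    n_exact = math.comb(total, n1)
    if total <= 8 or n_exact <= n_permutations:
        idx = np.array(list(combinations(range(total), n1)), dtype=int)
        return idx, True
    picks = np.empty((n_permutations, n1), dtype=int)
    for i in range(n_permutations):
        picks[i] = rng.permutation(total)[:n1]
    return picks, False


def permutation_fdr_call(
    bait_vals: np.ndarray,
    ctrl_vals: np.ndarray,
    s0: float,
    fdr_target: float,
    n_permutations: int = 250,
    rng: np.random.Generator | None = None,
) -> SignificanceCall:
    """Call significant proteins at a permutation-estimated FDR.

    The bait/control column labels are permuted jointly for all proteins
    (the same relabeling per permutation, preserving protein-wise
    correlation).  For a candidate threshold c on |d|,

        FDR(c) = mean over permutations of #{|d_perm| >= c} / #{|d_obs| >= c}

    capped at 1; the significant set is ``|d| >= c*`` for the smallest
    candidate c* with FDR(c*) <= fdr_target.  With at most 8 columns in
    total (or fewer distinct assignments than ``n_permutations``) all
    assignments are enumerated exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n1, n2 = bait_vals.shape[1], ctrl_vals.shape[1]
    pool = np.hstack([bait_vals, ctrl_vals])
    total = n1 + n2
    d_obs = _d_matrix(bait_vals, ctrl_vals, s0)

    picks, exact = _label_assignments(n1, n2, n_permutations, rng)
    k = picks.shape[0]
    all_idx = np.arange(total)
    perm_abs = np.empty((k, pool.shape[0]))
    for i in range(k):
        bait_idx = picks[i]
        ctrl_idx = np.setdiff1d(all_idx, bait_idx, assume_unique=True)
        perm_abs[i] = np.abs(_d_matrix(pool[:, bait_idx], pool[:, ctrl_idx], s0))

    abs_obs = np.abs(d_obs)
    perm_sorted = np.sort(perm_abs.ravel())
    obs_sorted = np.sort(abs_obs)
    candidates = np.unique(abs_obs)
    n_obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, candidates, side="left")
    n_perm_ge = perm_sorted.size - np.searchsorted(perm_sorted, candidates, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.minimum(1.0, (n_perm_ge / k) / n_obs_ge)
    ok = np.where(fdr <= fdr_target)[0]
    if ok.size == 0:
        return SignificanceCall(
            d_obs, float("inf"), float("nan"), np.zeros(pool.shape[0], bool), exact, k
        )
    c_star = float(candidates[ok[0]])
    return SignificanceCall(
        d_obs, c_star, float(fdr[ok[0]]), abs_obs >= c_star, exact, k
    )


# ---------------------------------------------------------------------------
# full pipeline


def _impute_left_shifted(
    block: np.ndarray, config: PipelineConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-column left-shifted normal imputation of remaining NaNs."""
    out = block.copy()
    for j in range(block.shape[1]):
        col = out[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            continue
        mu = obs.mean() - config.imputation_downshift * obs.std(ddof=1)
        sd = config.imputation_width * obs.std(ddof=1)
        miss = np.isnan(col)
        col[miss] = rng.normal(mu, sd, size=int(miss.sum()))
    return out


def call_interactors(
    matrix: IntensityMatrix,
    design: BaitDesign,
    config: PipelineConfig,
    proteome: IntensityMatrix | None = None,
    annotations: ProteinAnnotations | None = None,
) -> dict[str, pd.DataFrame]:
    """Full per-bait interactor calling pipeline on a raw intensity matrix.

    Steps: quantile-normalize pulldowns and proteome separately; log2; filter
    proteins observed in at least ``min_valid_replicates`` of the bait's
    replicates; build the control cascade; compute the s0-moderated statistic
    and permutation FDR with per-bait (fdr, s0) overrides.  Returns one result
    table per bait; the bait protein itself (if present in the matrix under
    the bait's name) is always reported and flagged.
    """
    norm = quantile_normalize(matrix)
    logm = log2_transform(norm)
    scaled_proteome = None
    if proteome is not None:
        pl = log2_transform(quantile_normalize(proteome))
        scaled_proteome = scale_proteome(
            pl, logm, iqr_zero_policy=config.iqr_zero_policy
        )

    results: dict[str, pd.DataFrame] = {}
    proteins = np.array(logm.protein_ids)
    for bi, bait in enumerate(design.baits):
        rng = np.random.default_rng([config.rng_seed % (2**31), bi])
        fdr_target, s0 = config.cutoffs_for(bait)
        reps = design.replicate_map[bait]
        bait_block = logm.data[reps].to_numpy()
        n_valid = (~np.isnan(bait_block)).sum(axis=1)
        tested = n_valid >= config.min_valid_replicates

        control = build_control_matrix(
            logm, design, bait, config, proteome=scaled_proteome, rng=rng
        )
        bait_imp = _impute_left_shifted(bait_block, config, rng)

        x = bait_imp[tested]
        y = control.values[tested]
        call = permutation_fdr_call(
            x, y, s0, fdr_target, config.n_permutations, rng
        )
        p = _t_pvalues(x, y)
        enrich = x.mean(axis=1) - y.mean(axis=1)

        prov = np.array(control.provenance_labels())
        df = pd.DataFrame(
            {
                "protein": proteins[tested],
                "log2_enrichment": enrich,
                "d_stat": call.d,
                "p_value": p,
                "neg_log10_p": -np.log10(p),
                "significant": call.significant,
                "n_valid_bait_replicates": n_valid[tested],
                "control_provenance": prov[tested],
                "is_bait": proteins[tested] == bait,
            }
        ).set_index("protein")
        # the bait itself is always reported, even if it failed the filter
        if bait in proteins and bait not in df.index:
            idx = int(np.where(proteins == bait)[0][0])
            df.loc[bait] = {
                "log2_enrichment": np.nan,
                "d_stat": np.nan,
                "p_value": np.nan,
                "neg_log10_p": np.nan,
                "significant": False,
                "n_valid_bait_replicates": int(n_valid[idx]),
                "control_provenance": prov[idx],
                "is_bait": True,
            }
        df.attrs["bait"] = bait
        df.attrs["fdr_target"] = fdr_target
        df.attrs["s0"] = s0
        df.attrs["d_threshold"] = call.threshold
        df.attrs["exact_permutations"] = call.exact
        df.attrs["n_assignments"] = call.n_assignments
        df.attrs["config_hash"] = config.config_hash()
        df.attrs["rng_seed"] = config.rng_seed
        results[bait] = df
    return results


def significant_sets(results: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Per-bait significant interactor sets (bait's own entry excluded)."""
    return {
        bait: set(df.index[df["significant"] & ~df["is_bait"]])
        for bait, df in results.items()
    }
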