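"""CVR maps, robust-range handling, ROI summaries, and group statistics.

Cerebrovascular reactivity is the relative CBF change induced by the
vasodilator,

    CVR = (CBF_post - CBF_pre) / CBF_pre * 100   [%],

computed voxelwise on a shared grid.  Outlier voxels outside the within-mask
1st-99th percentile band are excluded from summary statistics (the "robust
range").  Group comparisons use paired t tests with a normality check and a
Pearson correlation with a Fisher-z confidence interval; voxelwise family-
wise error control uses a max-statistic sign-flip permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import ImageVolume, ValidationError, require

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CvrMap:
    """Voxelwise CVR (%) with its robust-range exclusion mask."""

    values: ImageVolume
    robust_bounds: tuple[float, float]
    excluded_mask: np.ndarray  # True where a voxel is excluded
    technique: str = ""

    def robust_values(self) -> np.ndarray:
        """In-mask CVR values inside the robust range."""
        keep = self.values.brain_mask & ~self.excluded_mask
        return self.values.values[keep]

    def robust_mean(self) -> float:
        vals = self.robust_values()
        return float(vals.mean()) if vals.size else float("nan")


def robust_range_mask(
    values: np.ndarray,
    mask: np.ndarray,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> np.ndarray:
    """Mark voxels strictly outside the within-mask percentile band.

    Percentiles use linear interpolation between order statistics; ties at
    the bounds are kept (strict inequality excludes).  A constant map
    excludes nothing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    inside = values[mask]
    lo, hi = np.percentile(inside, [lo_pct, hi_pct])
    excluded = np.zeros(values.shape, dtype=bool)
    excluded[mask] = (inside < lo) | (inside > hi)
    return excluded


def compute_cvr_map(
    cbf_pre: ImageVolume,
    cbf_post: ImageVolume,
    technique: str = "",
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> CvrMap:
    """Voxelwise CVR (%) from pre/post CBF maps on a shared grid.

    Voxels with non-positive baseline CBF are excluded before the robust
    percentile bounds are computed (the ratio is undefined there).
    """
    require(cbf_pre.shape == cbf_post.shape, "CBF grids must match")
    require(bool(np.array_equal(cbf_pre.brain_mask, cbf_post.brain_mask)),
            "CBF masks must match")
    mask = cbf_pre.brain_mask
    pre = cbf_pre.values
    valid = mask & (pre > 0)
    cvr = np.zeros(pre.shape)
    cvr[valid] = (cbf_post.values[valid] - pre[valid]) / pre[valid] * 100.0

    excluded = ~valid & mask
    if valid.any():
        tail_excl = robust_range_mask(cvr, valid, lo_pct, hi_pct)
        lo, hi = np.percentile(cvr[valid], [lo_pct, hi_pct])
        excluded = excluded | tail_excl
    else:
        lo = hi = float("nan")

    vol = cbf_pre.like(cvr, units="%")
    return CvrMap(values=vol, robust_bounds=(float(lo), float(hi)),
                  excluded_mask=excluded, technique=technique)


# --------------------------------------------------------------- ROI summary
def roi_summaries(
    source: CvrMap | ImageVolume,
    rois: dict[str, np.ndarray],
    subject_id: str = "",
    technique: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """Per-ROI means over non-excluded voxels.

    ``rois`` maps roi_id -> boolean mask on the image grid.  Empty ROIs are
    flagged with a missing value rather than dropped.
    """
    if isinstance(source, CvrMap):
        vol = source.values
        keep = vol.brain_mask & ~source.excluded_mask
        technique = technique or source.technique
    else:
        vol = source
        keep = vol.brain_mask
    rows = []
    for roi_id, roi_mask in rois.items():
        roi_mask = np.asarray(roi_mask, dtype=bool)
        require(roi_mask.shape == vol.shape, f"ROI {roi_id!r} shape mismatch")
        sel = roi_mask & keep
        rows.append({
            "roi_id": roi_id,
            "subject_id": subject_id,
            "technique": technique,
            "condition": condition,
            "n_voxels": int(sel.sum()),
            "mean": float(vol.values[sel].mean()) if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------- paired ROI test
@dataclass
class PairedTestResult:
    t: float
    p: float
    df: int
    ks_normality_p: float
    pearson_r: float
    pearson_ci: tuple[float, float]
    n: int


def paired_roi_test(a: np.ndarray, b: np.ndarray,
                    ci_level: float = 0.95) -> PairedTestResult:
    """Two-tailed paired t test plus normality check and correlation.

    The Kolmogorov-Smirnov statistic tests the paired differences against a
    normal distribution fitted to them; the Pearson r between ``a`` and
    ``b`` gets a Fisher-z confidence interval.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    require(a.size == b.size, "paired samples must have equal length")
    require(a.size >= 3, "need at least 3 pairs")
    n = a.size
    diff = a - b

    if np.allclose(diff, 0.0):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_rel(a, b)
        t_stat, p_val = float(t_stat), float(p_val)

    sd = diff.std(ddof=1)
    if sd > 0:
        ks = stats.kstest(diff, "norm", args=(diff.mean(), sd))
        ks_p = float(ks.pvalue)
    else:
        ks_p = 1.0

    if a.std() > 0 and b.std() > 0:
        r = float(stats.pearsonr(a, b).statistic)
    else:
        r = np.nan
    if np.isfinite(r) and abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = stats.norm.ppf(0.5 + ci_level / 2.0)
        ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    else:
        ci = (np.nan, np.nan)

    return PairedTestResult(t=t_stat, p=p_val, df=n - 1, ks_normality_p=ks_p,
                            pearson_r=r, pearson_ci=ci, n=n)


# ------------------------------------------------- permutation FWE correction
def _smooth_within_mask(vol: np.ndarray, mask: np.ndarray,
                        sigma_vox: np.ndarray) -> np.ndarray:
    """Gaussian smoothing renormalized to the mask (no bleed from outside)."""
    data = np.where(mask, vol, 0.0)
    num = ndimage.gaussian_filter(data, sigma=sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    out = np.zeros_like(vol)
    out[mask] = num[mask] / np.where(den[mask] > 1e-12, den[mask], 1.0)
    return out


def permutation_fwe_map(
    difference_maps: list[ImageVolume],
    n_perm: int = 1000,
    seed: int = 0,
    smoothing_fwhm_mm: float = 3.0,
) -> ImageVolume:
    """FWE-corrected p map for a one-sample test across subjects.

    Subject difference maps are smoothed (Gaussian, ``smoothing_fwhm_mm``),
    a voxelwise one-sample t map is formed, and its null distribution is
    built by random sign flips of whole subjects.  The corrected p at a
    voxel is the rank of its observed |t| within the null distribution of
    the spatial max |t| (plus the identity permutation), which controls the
    family-wise error rate exactly under exchangeability of signs.
    """
    require(len(difference_maps) >= 6, "need at least 6 subjects")
    require(n_perm >= 100, "need at least 100 permutations")
    shapes = {v.shape for v in difference_maps}
    require(len(shapes) == 1, "subject maps must share one grid")
    mask = difference_maps[0].brain_mask
    voxel = np.asarray(difference_maps[0].voxel_size)
    sigma_vox = smoothing_fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / voxel

    if smoothing_fwhm_mm > 0:
        stack = np.stack([
            _smooth_within_mask(v.values, mask, sigma_vox)[mask]
            for v in difference_maps
        ])  # (n_subj, n_vox)
    else:
        stack = np.stack([v.values[mask] for v in difference_maps])
    n_subj, n_vox = stack.shape

    def t_map(signs: np.ndarray) -> np.ndarray:
        flipped = stack * signs[:, None]
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        return mean / np.where(sd > 0, sd, np.inf) * np.sqrt(n_subj)

    t_obs = np.abs(t_map(np.ones(n_subj)))

    rng = np.random.default_rng(seed)
    exceed = np.ones(n_vox)  # identity permutation counts once
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        max_t = np.abs(t_map(signs)).max()
        exceed += (max_t >= t_obs).astype(float)
    p_corr = exceed / (n_perm + 1)

    out = np.ones(mask.shape)
    out[mask] = p_corr
    return difference_maps[0].like(out, units="p")
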