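"""Quantitative evaluation of estimated R2* maps and paired statistics.

NRMSE and a *global* (single-window) SSIM over a region of interest — the
whole liver for map quality, parenchyma only for the representative mean R2*
— plus Bland-Altman agreement limits and the Wilcoxon signed-rank test for
paired method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_model import ParameterMaps

__all__ = [
    "nrmse",
    "ssim_global",
    "ssim_windowed",
    "roi_mean_r2star",
    "AgreementResult",
    "bland_altman",
    "wilcoxon_signed_rank",
]


def _region_values(ref, est, region):
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("ref and est shapes differ")
    if region is None:
        return ref.ravel(), est.ravel()
    region = np.asarray(region, dtype=bool)
    if region.shape != ref.shape:
        raise ValueError("region shape differs from the maps")
    if not region.any():
        raise ValueError("region is empty")
    return ref[region], est[region]


def nrmse(ref, est, region=None) -> float:
    """l2 norm of (ref - est) over the region divided by the l2 norm of ref.

    Returned as a fraction (multiply by 100 for the % convention used in
    summaries).
    """
    r, e = _region_values(ref, est, region)
    denom = np.linalg.norm(r)
    if denom == 0:
        raise ValueError("reference is zero over the region")
    return float(np.linalg.norm(r - e) / denom)


def ssim_global(ref, est, region=None, k1: float = 0.01, k2: float = 0.03) -> float:
    """Single-window SSIM from region-wide means, variances and covariance.

        SSIM = (2 mu_x mu_y + C1)(2 cov + C2) /
               ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2))

    with C1 = (k1 L)^2, C2 = (k2 L)^2 and L = max(ref) - min(ref) over the
    region (population variances, ddof = 0).
    """
    r, e = _region_values(ref, est, region)
    if r.size < 2:
        raise ValueError("region must contain at least 2 pixels")
    L = float(r.max() - r.min())
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    mx, my = r.mean(), e.mean()
    vx, vy = r.var(), e.var()
    cov = ((r - mx) * (e - my)).mean()
    return float(
        (2 * mx * my + c1) * (2 * cov + c2)
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def ssim_windowed(ref, est, region=None, **kwargs) -> float:
    """Sliding-window SSIM (scikit-image), averaged over the region.

    Offered as a variant; the global single-window form is the default
    elsewhere in the package.
    """
    from skimage.metrics import structural_similarity

    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    rng_ = float(ref.max() - ref.min())
    _, smap = structural_similarity(
        ref, est, data_range=rng_ if rng_ > 0 else 1.0, full=True, **kwargs
    )
    if region is None:
        return float(smap.mean())
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    return float(smap[region].mean())


def roi_mean_r2star(maps: ParameterMaps, parenchyma_mask) -> float:
    """Arithmetic mean R2* over the parenchyma ROI (vessels excluded)."""
    mask = np.asarray(parenchyma_mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError("mask shape differs from the maps")
    if not mask.any():
        raise ValueError("parenchyma mask is empty")
    return float(maps.r2star[mask].mean())


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of paired differences a - b."""

    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    differences: np.ndarray

    @property
    def limits(self) -> tuple[float, float]:
        return (self.lower_limit, self.upper_limit)


def bland_altman(a, b) -> AgreementResult:
    """Mean difference and ±1.96 SD limits of agreement (sd with ddof = 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, d)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ranks of tied |differences| are averaged.
    The null distribution is exact (enumeration) for n <= 12 non-zero pairs
    and a normal approximation with continuity correction beyond that.
    Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    method = "exact" if d.size <= 12 else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)
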