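"""Map- and curve-level comparison metrics.

nRMSE is the root-mean-square error over a mask normalized by the reference
range (max - min within the mask) — the normalizer is a reported convention
pinned here, since Table-style numbers depend on it. SSIM wraps the standard
Gaussian-weighted structural similarity (sigma = 1.5, population covariance),
with the data range taken from the reference inside the mask and the score
averaged over masked voxels. Agreement between two estimators is summarized
by Bland-Altman limits (mean difference +/- 1.96 SD) and Lin's concordance
correlation coefficient

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),

with population (1/n) moments, Lin's original convention. Tissue-wise method
comparison uses per-subject summary values (median per tissue per subject)
paired across subjects in a two-sided Wilcoxon signed-rank test, exact for
small samples; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "nrmse",
    "ssim",
    "lin_ccc",
    "bland_altman",
    "AgreementReport",
    "wilcoxon_paired",
    "tissue_compare",
    "curve_fit_error",
    "plot_bland_altman",
    "plot_tissue_boxes",
]


def _masked(est, ref, mask):
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref shapes differ")
    if mask is None:
        mask = np.ones(ref.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ref.shape:
        raise ValueError("mask shape differs from maps")
    return est, ref, mask


def nrmse(est, ref, mask=None) -> float:
    """RMSE over the mask divided by the reference range within the mask.

    Invariant under adding the same constant to both maps; zero iff the maps
    agree on the mask.
    """
    est, ref, mask = _masked(est, ref, mask)
    d = est[mask] - ref[mask]
    rmse = float(np.sqrt(np.mean(d * d)))
    rng = float(ref[mask].max() - ref[mask].min())
    if rng == 0:
        return 0.0 if rmse == 0 else np.inf
    return rmse / rng


def ssim(est, ref, mask=None, data_range: Optional[float] = None) -> float:
    """Mean structural similarity over the mask.

    Gaussian-weighted windows (sigma 1.5), population covariance; data range
    from the reference within the mask unless given. 1 iff the maps are
    identical within the mask.
    """
    est, ref, mask = _masked(est, ref, mask)
    if data_range is None:
        data_range = float(ref[mask].max() - ref[mask].min())
        if data_range == 0:
            return 1.0 if np.allclose(est[mask], ref[mask]) else -1.0
    _, smap = structural_similarity(
        ref, est, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, full=True)
    return float(smap[mask].mean())


def lin_ccc(est, ref) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(est, dtype=float).ravel()
    y = np.asarray(ref, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("est and ref must be equal-length with n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * cov / denom)


@dataclass
class AgreementReport:
    """Bland-Altman limits of agreement plus Lin's CCC."""

    mean_diff: float
    loa_low: float
    loa_high: float
    ccc: float

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise ValueError("limits must bracket the mean difference")


def bland_altman(est, ref) -> AgreementReport:
    """mdiff = mean(est - ref); limits mdiff +/- 1.96 SD(est - ref)."""
    x = np.asarray(est, dtype=float).ravel()
    y = np.asarray(ref, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("est and ref lengths differ")
    d = x - y
    mdiff = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return AgreementReport(
        mean_diff=mdiff,
        loa_low=mdiff - 1.96 * sd,
        loa_high=mdiff + 1.96 * sd,
        ccc=lin_ccc(x, y),
    )


def wilcoxon_paired(a, b, alternative: str = "two-sided"):
    """Paired Wilcoxon signed-rank test; exact null for small n.

    Identical samples (all differences zero) return the null-center statistic
    n(n+1)/4 with p = 1 rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs >= 2 pairs of equal length")
    d = a - b
    if np.all(d == 0):
        n = d.size
        return n * (n + 1) / 4.0, 1.0
    res = stats.wilcoxon(a, b, alternative=alternative,
                         zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def tissue_compare(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Compare two methods tissue by tissue across subjects.

    Inputs are per-subject summary tables (rows = subjects, columns =
    tissues, entries = one summary value, e.g. the median of a parameter in
    that tissue), pairing by subject. Returns per-tissue medians of both
    methods, the signed-rank statistic and its p-value; tissues with fewer
    than 2 complete pairs are flagged with NaN p.
    """
    if list(summaries_a.columns) != list(summaries_b.columns):
        raise ValueError("tissue columns differ between methods")
    rows = []
    for tissue in summaries_a.columns:
        a = summaries_a[tissue].to_numpy(dtype=float)
        b = summaries_b[tissue].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            rows.append({"tissue": tissue, "median_a": np.nan,
                         "median_b": np.nan, "statistic": np.nan,
                         "pvalue": np.nan, "n_pairs": int(ok.sum())})
            continue
        stat, p = wilcoxon_paired(a[ok], b[ok], alternative=alternative)
        rows.append({
            "tissue": tissue,
            "median_a": float(np.median(a[ok])),
            "median_b": float(np.median(b[ok])),
            "statistic": stat,
            "pvalue": p,
            "n_pairs": int(ok.sum()),
        })
    return pd.DataFrame(rows).set_index("tissue")


def curve_fit_error(
    observed: np.ndarray,
    fitted: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-slice nRMSE and SSIM between observed and fitted dynamic series.

    ``observed`` / ``fitted`` are (x, y, z, t); metrics are computed for
    every 2D slice over its (x, y, t) stack (SSIM averaged over frames) and
    the last row aggregates mean and SD across slices.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.ndim != 4:
        raise ValueError("observed and fitted must be equal-shape 4D stacks")
    nz, nt = observed.shape[2], observed.shape[3]
    if mask is None:
        mask = np.ones(observed.shape[:3], dtype=bool)
    rows = []
    for z in range(nz):
        m2 = mask[:, :, z]
        if not m2.any():
            rows.append({"slice": z, "nrmse": np.nan, "ssim": np.nan})
            continue
        m3 = np.broadcast_to(m2[..., None], (m2.shape + (nt,)))
        nr = nrmse(fitted[:, :, z, :], observed[:, :, z, :], m3)
        rng = float(observed[:, :, z, :][m3].max()
                    - observed[:, :, z, :][m3].min())
        svals = [
            ssim(fitted[:, :, z, t], observed[:, :, z, t], m2,
                 data_range=rng if rng > 0 else None)
            for t in range(nt)
        ]
        rows.append({"slice": z, "nrmse": nr, "ssim": float(np.mean(svals))})
    df = pd.DataFrame(rows).set_index("slice")
    agg = pd.DataFrame({
        "nrmse": [df["nrmse"].mean(), df["nrmse"].std(ddof=1)],
        "ssim": [df["ssim"].mean(), df["ssim"].std(ddof=1)],
    }, index=["mean", "sd"])
    return pd.concat([df, agg])


def plot_bland_altman(est, ref, out_path=None, ax=None, label=""):
    """Bland-Altman scatter with the mean-difference and 1.96-SD lines."""
    import matplotlib
    if out_path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(est, dtype=float).ravel()
    y = np.asarray(ref, dtype=float).ravel()
    rep = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.scatter((x + y) / 2, x - y, s=4, alpha=0.4)
    ax.axhline(rep.mean_diff, color="gray")
    ax.axhline(rep.loa_low, color="gray", linestyle="--")
    ax.axhline(rep.loa_high, color="gray", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference")
    ax.set_title(f"{label} CCC = {rep.ccc:.3f}".strip())
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return rep, ax


def plot_tissue_boxes(values_by_method, out_path=None, ax=None,
                      ylabel=""):
    """Side-by-side box plots per tissue for several methods.

    ``values_by_method`` maps method name -> {tissue -> 1D values}.
    """
    import matplotlib
    if out_path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(values_by_method)
    tissues = list(next(iter(values_by_method.values())))
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(tissues) + 1, 3))
    width = 0.8 / len(methods)
    for mi, method in enumerate(methods):
        data = [np.asarray(values_by_method[method][t]).ravel()
                for t in tissues]
        pos = np.arange(len(tissues)) + (mi - (len(methods) - 1) / 2) * width
        ax.boxplot(data, positions=pos, widths=width * 0.9,
                   showfliers=False)
    ax.set_xticks(np.arange(len(tissues)))
    ax.set_xticklabels(tissues)
    ax.set_ylabel(ylabel)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
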