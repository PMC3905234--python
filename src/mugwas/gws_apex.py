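"""Study-specific genome-wide significance from quantile-rank curves.

For each chromosome the ascending s-values are plotted against the
expected -log10 uniform quantiles and smoothed by local quadratic
regression (tricube weights).  The *projected* curve truncates as many
of the highest values as needed for the fit to be monotone nondecreasing
with non-positive second derivative; its highest point is the
chromosome's apex.  The whole-genome apex -- the study-specific
genome-wide-significance cutoff -- is the median apex among the
``n_select`` autosomes whose s-values deviate least (maximum norm) from
their projection.  The *estimated* curve for plotting replaces top
values by the whole-genome apex until its own apex is at or below that
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QRCurve",
    "ApexEstimate",
    "expected_quantiles",
    "loess_quadratic",
    "project_curve",
    "wg_apex",
    "estimated_curve",
    "call_study_gws",
    "genome_curves",
]

SEX_CHROMS = {"X", "Y", "XY", "MT", "M", "23", "24", "25", "26",
              "chrX", "chrY", "chrM", "chrMT"}


@dataclass
class QRCurve:
    """A quantile-rank curve: sorted s-values, expected quantiles, fit."""

    s_sorted: np.ndarray          # full ascending input
    expected: np.ndarray          # -log10 uniform quantiles, same length
    fitted: np.ndarray            # loess fit over retained points
    n_truncated: int              # top values removed (projection) / replaced
    apex: float
    deviation: float              # max |s - fitted| over retained points
    degenerate: bool = False

    @property
    def retained(self) -> int:
        return len(self.fitted)


@dataclass
class ApexEstimate:
    """Per-chromosome apices and the whole-genome cutoff."""

    per_chromosome: pd.DataFrame  # chrom, apex, deviation, n_truncated, selected
    wg_apex: float
    selected: list = field(default_factory=list)


def expected_quantiles(n: int) -> np.ndarray:
    """Expected -log10 uniform order statistics, ascending: -log10((n-i+0.5)/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(1, n + 1)
    return -np.log10((n - i + 0.5) / n)


def loess_quadratic(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                    chunk: int = 512, max_exact: int = 1000) -> np.ndarray:
    """Local quadratic regression with tricube weights at each data point.

    ``x`` must be sorted ascending.  The neighbourhood of each point is
    the ``ceil(span * n)`` nearest points (contiguous in x); weights are
    tricube in normalized distance.  Linear in ``y``.  Above
    ``max_exact`` points the fit is evaluated at an evenly rank-spaced
    subgrid (always including both endpoints) and linearly interpolated,
    as in classical loess implementations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n > max_exact:
        grid = np.unique(np.round(np.linspace(0, n - 1, max_exact)).astype(int))
        fit_grid = _loess_at(x, y, x[grid], span)
        return np.interp(x, x[grid], fit_grid)
    return _loess_at(x, y, x, span)


def _loess_at(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
              span: float, chunk: int = 512) -> np.ndarray:
    n = x.size
    m = x_eval.size
    k = int(np.ceil(span * n))
    k = max(4, min(n, k))
    # left edge of each nearest-k window (two-pointer over sorted x)
    left = np.empty(m, dtype=np.int64)
    l = 0
    for i in range(m):
        e = x_eval[i]
        while l + k < n and x[l + k] - e < e - x[l]:
            l += 1
        left[i] = l
    fitted = np.empty(m)
    offsets = np.arange(k)
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        idx = left[start:stop, None] + offsets[None, :]
        xw = x[idx]
        yw = y[idx]
        xc = x_eval[start:stop, None]
        d = np.abs(xw - xc)
        dmax = d.max(axis=1, keepdims=True)
        dmax[dmax == 0] = 1.0
        w = (1.0 - (d / dmax) ** 3) ** 3
        np.clip(w, 0.0, None, out=w)
        t = (xw - xc) / dmax
        # normal equations for y ~ a0 + a1 t + a2 t^2
        pw = np.stack([np.ones_like(t), t, t * t], axis=2)   # m x k x 3
        A = np.einsum("mk,mki,mkj->mij", w, pw, pw)
        b = np.einsum("mk,mk,mki->mi", w, yw, pw)
        A += 1e-12 * np.eye(3)
        coef = np.linalg.solve(A, b[..., None])[..., 0]
        fitted[start:stop] = coef[:, 0]
    return fitted


def _violations(x: np.ndarray, f: np.ndarray, tol: float,
                concavity_rel: float, apex_fraction: float) -> bool:
    """True if the fit fails monotone nondecrease or apex-region concavity.

    Monotonicity is checked over the whole curve at tolerance ``tol``
    scaled by the mean slope.  Concavity (non-increasing slope of the
    fit) is enforced over the top ``apex_fraction`` of points (at least
    five), at tolerance ``concavity_rel`` times the mean slope: removing
    top values can only repair upward curvature near the apex, while
    small mid-curve curvature reflects the genuine discreteness of
    s-values and does not affect the apex.
    """
    if f.size < 3:
        return False
    df = np.diff(f)
    scale = max(1e-12, (f[-1] - f[0]) / (x[-1] - x[0]))
    if np.any(df < -tol * max(1.0, scale)):
        return True
    slopes = df / np.diff(x)
    top = max(5, int(apex_fraction * (f.size - 2)))
    # absolute floor keeps numerically flat fits (scale ~ 0) from looping
    return bool(np.any(np.diff(slopes)[-top:] > concavity_rel * scale + tol))


def project_curve(s_values: np.ndarray, span: float = 0.3, tol: float = 1e-9,
                  min_points: int = 20, concavity_rel: float = 0.05,
                  apex_fraction: float = 0.1) -> QRCurve:
    """Projected QR curve: truncate top values until monotone + concave.

    Below ``min_points`` values the curve is degenerate with apex equal
    to the maximum s.
    """
    s_sorted = np.sort(np.asarray(s_values, dtype=np.float64))
    n = s_sorted.size
    expected = expected_quantiles(n) if n else np.empty(0)
    if n < min_points:
        apex = float(s_sorted[-1]) if n else 0.0
        return QRCurve(s_sorted, expected, s_sorted.copy(), 0, apex,
                       0.0, degenerate=True)
    m = n
    floor = max(4, min_points // 2)
    while True:
        fitted = loess_quadratic(expected[:m], s_sorted[:m], span=span)
        if not _violations(expected[:m], fitted, tol, concavity_rel,
                           apex_fraction):
            break
        if m <= floor:
            warnings.warn("projection still violates shape constraints at the "
                          "truncation floor; keeping the floor fit")
            break
        m -= 1
    deviation = float(np.max(np.abs(s_sorted[:m] - fitted)))
    # the apex is the projection evaluated at the full panel's top expected
    # quantile: truncation removes values from the fit, not rank range
    if m == n:
        apex = float(fitted[-1])
    else:
        apex = float(_loess_at(expected[:m], s_sorted[:m],
                               expected[-1:], span)[0])
    return QRCurve(
        s_sorted=s_sorted,
        expected=expected,
        fitted=fitted,
        n_truncated=n - m,
        apex=apex,
        deviation=deviation,
    )


def wg_apex(curves: dict, n_select: int = 10, winsorized_mean: bool = False) -> ApexEstimate:
    """Whole-genome apex: median apex of the lowest-deviation autosomes.

    ``curves`` maps chromosome name to its projected ``QRCurve``.  Sex
    chromosomes are never included.  With fewer than ``n_select``
    autosomes all are used (with a warning).  ``winsorized_mean``
    switches the median for a 25%-winsorized mean of the selected apices.
    """
    rows = []
    for chrom, curve in curves.items():
        rows.append({
            "chrom": chrom,
            "apex": curve.apex,
            "deviation": curve.deviation,
            "n_truncated": curve.n_truncated,
            "autosome": str(chrom) not in SEX_CHROMS,
        })
    table = pd.DataFrame(rows)
    autosomes = table[table["autosome"]].copy()
    if autosomes.empty:
        raise ValueError("need at least one autosome curve")
    if len(autosomes) < n_select:
        warnings.warn(
            f"only {len(autosomes)} autosomes available, using all "
            f"(n_select={n_select})"
        )
        n_select = len(autosomes)
    sel = autosomes.nsmallest(n_select, "deviation", keep="first")
    apices = sel["apex"].to_numpy()
    if winsorized_mean:
        from scipy.stats.mstats import winsorize
        value = float(np.mean(winsorize(apices, limits=0.25)))
    else:
        value = float(np.median(apices))
    table["selected"] = table["chrom"].isin(sel["chrom"])
    return ApexEstimate(per_chromosome=table, wg_apex=value,
                        selected=sel["chrom"].tolist())


def estimated_curve(s_values: np.ndarray, wg_apex_value: float,
                    span: float = 0.3) -> QRCurve:
    """Estimated QR curve: replace top values by the WG apex until the
    curve's own apex is at or below that level.  Nothing is removed, so
    the fit spans all points; used for plotting (the solid curve)."""
    if not np.isfinite(wg_apex_value):
        raise ValueError("wg_apex must be finite")
    s_sorted = np.sort(np.asarray(s_values, dtype=np.float64))
    n = s_sorted.size
    expected = expected_quantiles(n)
    y = s_sorted.copy()
    replaceable = np.flatnonzero(s_sorted > wg_apex_value)
    n_replaced = 0
    fitted = loess_quadratic(expected, y, span=span)
    if replaceable.size:
        for j in replaceable[::-1]:
            if fitted.max() <= wg_apex_value:
                break
            y[j] = wg_apex_value
            n_replaced += 1
            fitted = loess_quadratic(expected, y, span=span)
        if fitted.max() > wg_apex_value + 1e-9 and n_replaced == replaceable.size:
            warnings.warn("estimated curve apex still above WG apex after "
                          "replacing all values above it")
    deviation = float(np.max(np.abs(y - fitted))) if n else 0.0
    return QRCurve(
        s_sorted=s_sorted,
        expected=expected,
        fitted=fitted,
        n_truncated=n_replaced,
        apex=float(fitted.max()) if n else 0.0,
        deviation=deviation,
    )


def call_study_gws(results: pd.DataFrame, apex: ApexEstimate,
                   exclude_flagged: bool = True):
    """Significant loci (s > WG apex) merged into regions.

    Loci whose best windows share at least one SNP merge into one region;
    the best locus per region is reported.  With ``exclude_flagged`` the
    reliability flags (single-SNP-driven, low information content,
    unannotated) remove loci from the reported list -- they still fed the
    curves.
    Returns (significant loci DataFrame, regions DataFrame).
    """
    sig = results[results["s"] > apex.wg_apex].copy()
    if exclude_flagged:
        for col in ("single_snp_driven", "low_mu_ic", "unannotated"):
            if col in sig.columns:
                sig = sig[~sig[col].astype(bool)]
    sig = sig.sort_values(["chrom", "window_lo"], kind="stable")
    regions = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        current = None
        for _, row in sub.iterrows():
            lo, hi = int(row["window_lo"]), int(row["window_hi"])
            if current is not None and lo <= current["window_hi"]:
                current["window_hi"] = max(current["window_hi"], hi)
                current["n_loci"] += 1
                if row["s"] > current["s"]:
                    for key in ("s", "rsid", "pos", "best_width", "polarity"):
                        current[key] = row[key]
            else:
                if current is not None:
                    regions.append(current)
                current = {
                    "chrom": chrom, "window_lo": lo, "window_hi": hi,
                    "s": row["s"], "rsid": row["rsid"], "pos": row["pos"],
                    "best_width": row["best_width"], "polarity": row["polarity"],
                    "n_loci": 1,
                }
        if current is not None:
            regions.append(current)
    region_df = pd.DataFrame(
        regions, columns=["chrom", "window_lo", "window_hi", "s", "rsid",
                          "pos", "best_width", "polarity", "n_loci"])
    return sig.reset_index(drop=True), region_df


def genome_curves(results: pd.DataFrame, span: float = 0.3,
                  min_points: int = 20) -> dict:
    """Projected QR curve per chromosome from a scan table."""
    return {
        chrom: project_curve(sub["s"].to_numpy(), span=span, min_points=min_points)
        for chrom, sub in results.groupby("chrom", sort=False)
    }
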