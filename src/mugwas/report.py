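"""Plot rendering: QR plots, per-width region plots, profile heatmaps.

All renderers are pure functions of the tables they receive -- no
statistic is recomputed here.  Conventions: observed points against
expected quantiles, dashed projected curve, solid estimated curve, solid
horizontal line at the whole-genome apex, grey points for low-reliability
loci; region plots draw black dots for the single-SNP s and one line per
width 2-6 with increasingly solid dashes; profiles use an
orange/yellow/green genotype palette.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .gws_apex import QRCurve, expected_quantiles

__all__ = ["render_qr", "render_region", "render_profile"]

_WIDTH_STYLES = {2: (0, (1, 3)), 3: (0, (1, 1)), 4: (0, (4, 2)),
                 5: (0, (6, 1)), 6: "solid"}

_GENO_COLORS = {0: "#e69f00", 1: "#f0e442", 2: "#009e73", -1: "#ffffff"}


def render_qr(results, projection: QRCurve, estimate: QRCurve | None = None,
              wg_apex: float | None = None, labels: dict | None = None,
              ax=None):
    """Quantile-rank plot of a scan table.

    ``results`` needs an ``s`` column and optionally reliability flag
    columns (flagged loci are greyed).  ``projection`` is drawn dashed
    over its retained points, ``estimate`` solid, and ``wg_apex`` as a
    solid horizontal line.  ``labels`` maps rsID to text drawn at the
    locus position above the cutoff.
    """
    if len(results) == 0:
        raise ValueError("empty results table")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    s = results["s"].to_numpy()
    order = np.argsort(s)
    exp = expected_quantiles(len(s))
    flagged = np.zeros(len(s), dtype=bool)
    for col in ("single_snp_driven", "low_mu_ic", "unannotated"):
        if col in results.columns:
            flagged |= results[col].to_numpy().astype(bool)
    flagged = flagged[order]
    ax.scatter(exp[~flagged], s[order][~flagged], s=8, c="#1f3f77", zorder=3)
    ax.scatter(exp[flagged], s[order][flagged], s=8, c="#aaaaaa", zorder=2)
    lim = max(exp.max(), s.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="#999999", lw=0.8, zorder=1)
    m = projection.retained
    ax.plot(projection.expected[:m], projection.fitted, "--", color="#2060c0",
            lw=1.5, label="projection", zorder=4)
    if estimate is not None:
        ax.plot(estimate.expected[: estimate.retained], estimate.fitted,
                color="#2060c0", lw=1.5, label="estimate", zorder=4)
    if wg_apex is not None:
        ax.axhline(wg_apex, color="#c03020", lw=1.2, label="WG apex")
    if labels and "rsid" in results.columns:
        rank_of = {r: k for k, r in enumerate(results["rsid"].to_numpy()[order])}
        for rsid, text in labels.items():
            if rsid in rank_of:
                k = rank_of[rsid]
                ax.annotate(text, (exp[k], s[order][k]), fontsize=7,
                            xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed s")
    ax.legend(loc="upper left", fontsize=8)
    return ax.figure


def render_region(results, chrom, lo_pos=None, hi_pos=None,
                  annotation=None, ax=None):
    """Per-width significance profile across a chromosome region.

    Dots: single-SNP s (width 1).  Lines: per-width best s, dash density
    increasing with width (2 dotted ... 6 solid).  Low-reliability
    stretches are drawn red.  An annotation track of gene intervals is
    added underneath when provided.
    """
    sub = results[results["chrom"].astype(str) == str(chrom)]
    if lo_pos is not None:
        sub = sub[sub["pos"] >= lo_pos]
    if hi_pos is not None:
        sub = sub[sub["pos"] <= hi_pos]
    if sub.empty:
        raise ValueError("region contains no SNPs")
    sub = sub.sort_values("pos")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    pos = sub["pos"].to_numpy() / 1e6
    if "s_w1" in sub.columns:
        ax.plot(pos, sub["s_w1"], "k.", ms=4, label="width 1")
    for w, style in _WIDTH_STYLES.items():
        col = f"s_w{w}"
        if col in sub.columns and sub[col].notna().any():
            ax.plot(pos, sub[col], linestyle=style, color="#1f3f77", lw=1.1,
                    label=f"width {w}")
    flagged = np.zeros(len(sub), dtype=bool)
    for col in ("single_snp_driven", "low_mu_ic"):
        if col in sub.columns:
            flagged |= sub[col].to_numpy().astype(bool)
    if flagged.any() and "s" in sub.columns:
        ax.plot(pos[flagged], sub["s"].to_numpy()[flagged], "r.", ms=5,
                label="low reliability")
    if annotation is not None:
        genes = annotation[annotation["chrom"].astype(str) == str(chrom)]
        y0 = -0.06 * max(1.0, float(np.nanmax(sub.filter(like="s_w").to_numpy())))
        for _, iv in genes.iterrows():
            ax.plot([iv["start"] / 1e6, iv["end"] / 1e6], [y0, y0],
                    color="#444444", lw=4, solid_capstyle="butt")
    ax.set_xlabel(f"chromosome {chrom} position (Mb)")
    ax.set_ylabel("s")
    ax.legend(fontsize=7, ncol=3)
    return ax.figure


def render_profile(profile, ax=None):
    """Heatmap of an allelotype profile matrix.

    Orange: homozygous major, yellow: heterozygous, green: homozygous
    minor, white: missing; rows already ordered by population and
    mu-score.
    """
    from matplotlib.colors import ListedColormap

    geno = profile.matrix.drop(columns="group").to_numpy().astype(int)
    img = np.zeros(geno.shape)
    lut = {-1: 0, 0: 1, 1: 2, 2: 3}
    for g, v in lut.items():
        img[geno == g] = v
    cmap = ListedColormap(["#ffffff", _GENO_COLORS[0], _GENO_COLORS[1],
                           _GENO_COLORS[2]])
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(img, aspect="auto", cmap=cmap, interpolation="nearest",
              vmin=0, vmax=3)
    groups = profile.matrix["group"].to_numpy()
    bounds = np.flatnonzero(groups[1:] != groups[:-1]) + 1
    for b in bounds:
        ax.axhline(b - 0.5, color="black", lw=1.0)
    ax.set_xticks(range(geno.shape[1]))
    ax.set_xticklabels(profile.matrix.columns[1:], rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("subjects (by population, then mu-score)")
    return ax.figure
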