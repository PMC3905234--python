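"""Genome scan: best wide-locus result per center SNP.

For every center SNP, diplotypes of widths 1-6 (windows truncated at
chromosome ends, even widths placed left-heavy) are tested with every
polarity whose first component is +1; the most significant s-value per
center is kept together with its width, polarity and information
content, plus the per-width maxima for plotting.  Reliability flags mark
loci driven by a single SNP, loci with low mu-score information content
and loci outside annotated gene intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mucore
from .io_qc import GenotypeStudy

__all__ = [
    "scan_chromosome",
    "scan_study",
    "single_snp_scan",
    "flag_single_snp_driven",
    "restrict_to_annotated",
    "LOW_MU_IC_DEFAULT",
]

LOW_MU_IC_DEFAULT = 0.2


def _window_bounds(center: int, width: int, n: int) -> tuple[int, int]:
    """[lo, hi] inclusive SNP indices; even widths sit left-heavy."""
    lo = max(0, center - (width - 1) // 2)
    hi = min(n - 1, center + width // 2)
    return lo, hi


def _polarities(w: int):
    """All sign vectors of length w with first component fixed +1."""
    if w == 1:
        yield np.ones(1, dtype=np.int8)
        return
    for rest in itertools.product((1, -1), repeat=w - 1):
        yield np.array((1,) + rest, dtype=np.int8)


def _s_from_z(z: float) -> float:
    from scipy.special import log_ndtr

    return float(-(np.log(2.0) + log_ndtr(-abs(z))) / np.log(10.0))


def scan_chromosome(
    study: GenotypeStudy,
    chrom,
    groups: tuple = ("case-severe", "case-mild"),
    widths=range(1, 7),
    stratify_by: str | None = None,
    sex_rule: bool = False,
) -> pd.DataFrame:
    """Scan one chromosome; one row per center SNP.

    ``groups`` names the (case, reference) subject groups.  With
    ``stratify_by='sex'`` the test is stratified; with ``sex_rule`` the
    Bonferroni-adjusted better single-sex result replaces the stratified
    one when more significant.
    """
    idx = study.snp_indices(chrom)
    if idx.size == 0:
        raise ValueError(f"no SNPs on chromosome {chrom}")
    in_groups = study.subjects["group"].isin(groups).to_numpy()
    case = (study.subjects["group"] == groups[0]).to_numpy()[in_groups]
    sex = study.subjects["sex"].to_numpy()[in_groups]
    geno = study.genotypes[in_groups][:, idx]
    strata = sex if (stratify_by == "sex" or sex_rule) else None
    n_local = idx.size
    rows = []
    for c in range(n_local):
        best = dict(s=-1.0, width=0, polarity="", z=0.0, direction=0,
                    engine=None, pol=None, lo=0, hi=0)
        per_width = {w: np.nan for w in widths}
        seen: dict = {}
        for w in widths:
            lo, hi = _window_bounds(c, w, n_local)
            if (lo, hi) in seen:
                per_width[w] = seen[(lo, hi)]
                continue
            window = geno[:, lo : hi + 1]
            w_eff = hi - lo + 1
            engine = mucore.WindowEngine(window, case, strata)
            best_w = -1.0
            for pol in _polarities(w_eff):
                z, T, T_k, var_k = engine.stats(pol)
                if sex_rule:
                    s_strat = _s_from_z(z)
                    z_k = np.where(var_k > 0, T_k / np.sqrt(np.where(var_k > 0, var_k, 1.0)), 0.0)
                    s_k = [_s_from_z(zk) for zk in z_k]
                    s_here, _ = mucore.select_sex_specific(
                        s_strat,
                        max([s for s, lab in zip(s_k, engine.stratum_labels) if lab == "M"],
                            default=0.0),
                        max([s for s, lab in zip(s_k, engine.stratum_labels) if lab == "F"],
                            default=0.0),
                    )
                else:
                    s_here = _s_from_z(z)
                if s_here > best_w:
                    best_w = s_here
                if s_here > best["s"]:
                    best = dict(s=s_here, width=w, polarity="".join(
                                    "+" if p > 0 else "-" for p in pol),
                                z=z, direction=int(np.sign(T)),
                                engine=engine, pol=pol, lo=lo, hi=hi)
            per_width[w] = best_w
            seen[(lo, hi)] = best_w
        best["mu_ic"] = best["engine"].mu_ic(best["pol"]) if best["engine"] is not None else np.nan
        rows.append({
            "chrom": chrom,
            "pos": int(study.snp_map["pos"].iloc[idx[c]]),
            "rsid": study.snp_map["rsid"].iloc[idx[c]],
            "center_index": int(idx[c]),
            "s": best["s"],
            "best_width": best["width"],
            "polarity": best["polarity"],
            "mu_ic": best["mu_ic"],
            "direction": best["direction"],
            "window_lo": int(idx[best["lo"]]),
            "window_hi": int(idx[best["hi"]]),
            **{f"s_w{w}": per_width[w] for w in widths},
        })
    df = pd.DataFrame(rows)
    df["low_mu_ic"] = df["mu_ic"] < LOW_MU_IC_DEFAULT
    df["single_snp_driven"] = False
    df["unannotated"] = False
    return df


def scan_study(
    study: GenotypeStudy,
    groups: tuple = ("case-severe", "case-mild"),
    widths=range(1, 7),
    stratify_by: str | None = None,
    sex_rule: bool = False,
    flag_drivers: bool = True,
) -> pd.DataFrame:
    """Scan all chromosomes; optionally add the single-SNP-driver flag."""
    parts = [
        scan_chromosome(study, chrom, groups, widths, stratify_by, sex_rule)
        for chrom in study.chromosomes()
    ]
    df = pd.concat(parts, ignore_index=True)
    if flag_drivers:
        df["single_snp_driven"] = flag_single_snp_driven(df, study, groups)
    return df


def single_snp_scan(study: GenotypeStudy, groups=("case-severe", "case-mild")) -> pd.DataFrame:
    """Vectorized width-1 scan (tie-corrected rank test per SNP).

    Count-based fast path exactly matching ``mucore.u_test`` on single
    SNPs: missing subjects stay in the permutation set with score 0.
    """
    from scipy import stats

    in_groups = study.subjects["group"].isin(groups).to_numpy()
    case = (study.subjects["group"] == groups[0]).to_numpy()[in_groups]
    g = study.genotypes[in_groups]
    N = g.shape[0]
    n1 = int(case.sum())
    n2 = N - n1
    counts = np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)])       # 3 x S
    case_counts = np.stack([(g[case] == k).sum(axis=0) for k in (0, 1, 2)])
    # score of genotype k: #called-below - #called-above; missing scores 0
    below = np.cumsum(counts, axis=0) - counts
    above = counts[::-1].cumsum(axis=0)[::-1] - counts
    score = (below - above).astype(np.float64)
    T = (case_counts * score).sum(axis=0)
    ss = (counts * score**2).sum(axis=0)
    var = n1 * n2 * ss / (N * (N - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, T / np.sqrt(var), 0.0)
    s = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
    s = np.where(var > 0, s, 0.0)
    out = study.snp_map[["chrom", "pos", "rsid"]].copy()
    out["s"] = s
    out["z"] = z
    out["maf"] = study.maf()
    return out


def flag_single_snp_driven(
    results: pd.DataFrame,
    study: GenotypeStudy,
    groups: tuple = ("case-severe", "case-mild"),
    drop_fraction: float = 0.5,
    univariate_margin: float = 0.5,
) -> np.ndarray:
    """Leave-one-out flag for wide loci carried by one SNP.

    For each best window of width >= 2: remove one member SNP at a time
    and re-test; the locus is flagged when some removal costs more than
    ``drop_fraction`` of s AND that SNP alone scores within
    ``univariate_margin`` of the full window.
    """
    in_groups = study.subjects["group"].isin(groups).to_numpy()
    case = (study.subjects["group"] == groups[0]).to_numpy()[in_groups]
    geno = study.genotypes[in_groups]
    flags = np.zeros(len(results), dtype=bool)
    for i, row in results.iterrows():
        if row["best_width"] < 2 or row["s"] <= 0:
            continue
        lo, hi = int(row["window_lo"]), int(row["window_hi"])
        pol = np.array([1 if ch == "+" else -1 for ch in row["polarity"]], dtype=np.int8)
        cols = np.arange(lo, hi + 1)
        for k in range(len(cols)):
            keep = np.delete(cols, k)
            sub_pol = np.delete(pol, k)
            sub_pol = sub_pol * sub_pol[0]          # renormalize leading sign
            res = mucore.u_test(mucore.mu_scores(geno[:, keep], sub_pol), case)
            drop = row["s"] - res.s
            if drop <= drop_fraction * row["s"]:
                continue
            uni = mucore.u_test(mucore.mu_scores(geno[:, [cols[k]]]), case)
            if uni.s >= row["s"] - univariate_margin:
                flags[i] = True
                break
    return flags


def restrict_to_annotated(results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Flag loci whose center SNP lies in no annotated interval.

    ``annotation`` is BED-style: chrom, start, end (0-based half-open),
    optional name.  Flagged loci stay in the table (and in any
    quantile-rank curve built from it); reported gene lists downstream
    exclude them.
    """
    if not {"chrom", "start", "end"}.issubset(annotation.columns):
        raise ValueError("annotation must have chrom/start/end columns")
    out = results.copy()
    covered = np.zeros(len(out), dtype=bool)
    for chrom, sub in annotation.groupby("chrom"):
        here = (out["chrom"].astype(str) == str(chrom)).to_numpy()
        if not here.any():
            continue
        pos0 = out.loc[here, "pos"].to_numpy() - 1     # 0-based coordinate
        hit = np.zeros(pos0.size, dtype=bool)
        for _, iv in sub.iterrows():
            hit |= (pos0 >= iv["start"]) & (pos0 < iv["end"])
        covered[np.flatnonzero(here)] = hit
    out["unannotated"] = ~covered
    return out
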