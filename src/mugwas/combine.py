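"""Evidence combination across independent stages and allelotype profiles.

Stage s-values are combined by Fisher's method: with two independent
p-values, X = -2(ln p1 + ln p2) = 2 ln(10) (s1 + s2) follows a
chi-square with 4 degrees of freedom under the joint null, whose
survival function has the closed form exp(-X/2)(1 + X/2); the combined
value on the -log10 scale is therefore s_F = (s1 + s2) - log10(1 + X/2),
evaluated in log space so it is stable for arbitrarily large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mucore

__all__ = ["fisher_combine", "cross_stage", "allelotype_profile",
           "ProfileMatrix", "map_to_genes"]

_LN10 = np.log(10.0)


def fisher_combine(s1, s2):
    """Fisher chi-square (4 df) combination of two stage s-values.

    Accepts scalars or arrays of s = -log10 p; returns s_F on the same
    scale.  s_F >= max(s1, s2) whenever both exceed the chi-square-4
    crossover (about 0.61).
    """
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("stage s-values must be non-negative")
    half_x = _LN10 * (s1 + s2)
    s_f = (s1 + s2) - np.log1p(half_x) / _LN10
    if s_f.ndim == 0:
        return float(s_f)
    return s_f


def map_to_genes(results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Best locus s-value per annotated gene.

    ``annotation`` is BED-style (chrom, start, end 0-based half-open,
    name).  A locus belongs to a gene when its center SNP position falls
    inside the interval.  Returns one row per gene with its best s and
    the center rsID attaining it.
    """
    rows = []
    for _, iv in annotation.iterrows():
        here = results[(results["chrom"].astype(str) == str(iv["chrom"]))
                       & (results["pos"] - 1 >= iv["start"])
                       & (results["pos"] - 1 < iv["end"])]
        if here.empty:
            continue
        best = here.loc[here["s"].idxmax()]
        rows.append({"gene": iv["name"], "chrom": iv["chrom"],
                     "s": float(best["s"]), "rsid": best["rsid"]})
    df = pd.DataFrame(rows, columns=["gene", "chrom", "s", "rsid"])
    # a gene name may map to several intervals; keep its best
    if not df.empty:
        df = df.sort_values("s", ascending=False).drop_duplicates("gene")
    return df.reset_index(drop=True)


def cross_stage(results_1: pd.DataFrame, results_2: pd.DataFrame,
                annotation: pd.DataFrame, top_k: int = 100) -> pd.DataFrame:
    """Cross-stage gene table with ranks, top-k flags and Fisher s_F.

    Each stage's loci map to genes via the annotation; genes get their
    within-stage rank (1 = most significant), flags for top-20/50/100
    membership, and s_F where both stages observed the gene.
    """
    g1 = map_to_genes(results_1, annotation).rename(columns={"s": "s_1", "rsid": "rsid_1"})
    g2 = map_to_genes(results_2, annotation).rename(columns={"s": "s_2", "rsid": "rsid_2"})
    if g1.empty or g2.empty or not set(g1["gene"]) & set(g2["gene"]):
        import warnings
        warnings.warn("no genes shared between stages")
    g1["rank_1"] = g1["s_1"].rank(ascending=False, method="min").astype(int)
    g2["rank_2"] = g2["s_2"].rank(ascending=False, method="min").astype(int)
    merged = pd.merge(g1.drop(columns="chrom"), g2.drop(columns="chrom"),
                      on="gene", how="outer")
    both = merged["s_1"].notna() & merged["s_2"].notna()
    merged["s_f"] = np.nan
    merged.loc[both, "s_f"] = fisher_combine(merged.loc[both, "s_1"].to_numpy(),
                                             merged.loc[both, "s_2"].to_numpy())
    for k in (20, 50, 100):
        merged[f"top{k}_both"] = (merged["rank_1"] <= k) & (merged["rank_2"] <= k)
    merged["replicated"] = (merged["rank_1"] <= top_k) & (merged["rank_2"] <= top_k)
    return merged.sort_values("s_f", ascending=False, na_position="last") \
        .reset_index(drop=True)


def clear_replicated_driver_flags(results_1: pd.DataFrame, results_2: pd.DataFrame,
                                  top_k: int = 100):
    """Clear the single-SNP-driven flag for center SNPs in both stages' top-k.

    A locus carried by one SNP is normally excluded, except when the same
    center SNP ranks in the top-k of both independent stages.
    """
    def top_set(df):
        return set(df.nlargest(top_k, "s")["rsid"])

    shared = top_set(results_1) & top_set(results_2)
    out = []
    for df in (results_1, results_2):
        d = df.copy()
        d.loc[d["rsid"].isin(shared), "single_snp_driven"] = False
        out.append(d)
    return tuple(out)


@dataclass
class ProfileMatrix:
    """Genotype category matrix for an allelotype (diplotype) profile.

    ``matrix`` rows are subjects grouped by population (severe cases,
    controls, mild cases) and sorted within population by diplotype
    mu-score (descending; ties by subject id); columns are the region
    SNPs with genotype categories 0/1/2 (missing -1).  ``summary`` holds
    the per-population mean mu-score.
    """

    matrix: pd.DataFrame
    mu_scores: pd.Series
    summary: pd.DataFrame
    consensus: list


_POP_ORDER = ["case-severe", "control", "case-mild"]


def allelotype_profile(study, region_rsids, consensus_rsids=None,
                       polarity=None, auto_consensus: bool = False) -> ProfileMatrix:
    """Polarized-diplotype mu-score profile over a pooled sample.

    Mu-scores are computed from the consensus SNP subset with the given
    polarity over all subjects (cases of both severities plus any
    unrelated controls); subjects with missing consensus genotypes stay
    in, compared on their available components.  With ``auto_consensus``
    the subset of region SNPs maximizing the severe-vs-mild mean
    mu-score separation is chosen (exploratory).
    """
    rsid_to_col = {r: j for j, r in enumerate(study.snp_map["rsid"])}
    missing = [r for r in region_rsids if r not in rsid_to_col]
    if missing:
        raise ValueError(f"region SNPs not in study: {missing}")
    region_cols = [rsid_to_col[r] for r in region_rsids]
    groups = study.subjects["group"].to_numpy()

    def scores_for(subset_rsids, pol):
        cols = [rsid_to_col[r] for r in subset_rsids]
        window = study.genotypes[:, cols]
        return mucore.mu_scores(window, pol).scores

    if auto_consensus:
        import itertools
        best, best_sep = None, -np.inf
        for r in range(1, len(region_rsids) + 1):
            for sub in itertools.combinations(region_rsids, r):
                for pol in itertools.product((1, -1), repeat=len(sub) - 1):
                    p = np.array((1,) + pol, dtype=np.int8)
                    sc = scores_for(sub, p)
                    sev = sc[groups == "case-severe"].mean()
                    mild = sc[groups == "case-mild"].mean()
                    if sev - mild > best_sep:
                        best_sep, best = sev - mild, (list(sub), p)
        consensus_rsids, polarity = best
    elif consensus_rsids is None:
        consensus_rsids = list(region_rsids)
    if not set(consensus_rsids) <= set(region_rsids):
        raise ValueError("consensus SNPs must be a subset of the region SNPs")
    if polarity is None:
        polarity = np.ones(len(consensus_rsids), dtype=np.int8)

    sc = scores_for(consensus_rsids, np.asarray(polarity))
    subj = study.subjects.copy()
    subj["mu_score"] = sc
    subj["_pop"] = pd.Categorical(subj["group"], categories=_POP_ORDER, ordered=True)
    subj = subj.sort_values(["_pop", "mu_score", "id"],
                            ascending=[True, False, True], kind="stable")
    order = subj.index.to_numpy()
    matrix = pd.DataFrame(
        study.genotypes[np.ix_(order, region_cols)],
        index=subj["id"].to_numpy(),
        columns=list(region_rsids),
    )
    matrix.insert(0, "group", subj["group"].to_numpy())
    summary = subj.groupby("group", observed=True)["mu_score"] \
        .agg(["mean", "count"]).reindex([p for p in _POP_ORDER
                                         if p in set(groups)])
    return ProfileMatrix(
        matrix=matrix,
        mu_scores=pd.Series(sc, index=study.subjects["id"].to_numpy(), name="mu_score"),
        summary=summary.reset_index(),
        consensus=list(consensus_rsids),
    )
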