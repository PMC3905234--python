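"""Permutation null of the single-SNP rank test as a function of MAF.

With discrete genotype data the attainable p-values of a rank/u-test are
bounded: the rarer the minor allele, the coarser the permutation
distribution and the smaller the most extreme attainable significance.
This module quantifies that *MAF-significance correlation* by estimating
extreme tail quantiles (default 1 - 1e-5) of the permutation
distribution of s = -log10 p for two equal groups of n subjects whose
pooled genotype counts are fixed at rounded Hardy-Weinberg expectations.

Label permutation is performed by its exact distributional equivalent:
the genotype counts falling into group 1 follow a multivariate
hypergeometric distribution, which is cheap to sample in bulk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SimCell", "hwe_counts", "permutation_quantile", "maf_grid",
           "maf_s_correlation"]


@dataclass
class SimCell:
    """One (MAF, group size) permutation experiment."""

    maf: float
    n_per_group: int
    n_perm: int = 2_500_000
    q: float = 1e-5
    seed: int = 0
    quantile_s: float | None = None

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def hwe_counts(maf: float, n_total: int) -> tuple[int, int, int]:
    """Genotype counts (n0, n1, n2) at rounded HWE expectations."""
    n2 = int(round(n_total * maf * maf))
    n1 = int(round(n_total * 2 * maf * (1 - maf)))
    n0 = n_total - n1 - n2
    return n0, n1, n2


def _s_for_counts(k1: np.ndarray, k2: np.ndarray, n0: int, n1: int, n2: int,
                  n: int) -> np.ndarray:
    """s-values of the tie-corrected rank test for group-1 genotype counts.

    ``k1``/``k2`` count group-1 subjects with genotype 1 and 2; the test
    statistic is the linear mu-score sum, identical to the two-sided
    tie-corrected Wilcoxon normal approximation (no continuity
    correction)."""
    N = n0 + n1 + n2
    score = np.array([
        -(n1 + n2),          # genotype 0: below none, above n1+n2
        n0 - n2,             # genotype 1
        n0 + n1,             # genotype 2
    ], dtype=np.float64)
    ss = n0 * score[0] ** 2 + n1 * score[1] ** 2 + n2 * score[2] ** 2
    var = n * (N - n) * ss / (N * (N - 1))
    if var <= 0:
        return np.zeros(np.shape(k1))
    k0 = n - k1 - k2
    T = k0 * score[0] + k1 * score[1] + k2 * score[2]
    z = np.abs(T) / np.sqrt(var)
    return -(np.log(2.0) + stats.norm.logsf(z)) / np.log(10.0)


def _tail_order_statistic(s: np.ndarray, q: float) -> float:
    """Empirical 1-q quantile as a plain order statistic (no smoothing)."""
    m = s.size
    idx = min(m - 1, max(0, int(np.ceil((1.0 - q) * m)) - 1))
    return float(np.partition(s, idx)[idx])


def permutation_quantile(cell: SimCell, return_draws: bool = False):
    """Estimate the 1-q permutation quantile of s for one cell.

    Pooled genotype counts are fixed at rounded HWE expectations for 2n
    subjects; each permutation draws the group-1 genotype counts from the
    multivariate hypergeometric distribution.  Returns the cell with
    ``quantile_s`` filled in (and the draws when requested).
    """
    n = cell.n_per_group
    N = 2 * n
    n0, n1, n2 = hwe_counts(cell.maf, N)
    if cell.n_perm * cell.q < 10:
        warnings.warn("n_perm * q < 10: tail quantile estimate is unstable")
    if n1 + n2 == 0 or n0 + n1 == 0:
        out = replace(cell, quantile_s=0.0)
        return (out, np.zeros(0)) if return_draws else out
    rng = np.random.default_rng(cell.seed)
    k2 = rng.hypergeometric(n2, N - n2, n, size=cell.n_perm) if n2 else \
        np.zeros(cell.n_perm, dtype=np.int64)
    k1 = rng.hypergeometric(n1, N - n2 - n1, n - k2) if n1 else \
        np.zeros(cell.n_perm, dtype=np.int64)
    codes = k1 * (n2 + 1) + k2
    uniq, inverse = np.unique(codes, return_inverse=True)
    u1, u2 = uniq // (n2 + 1), uniq % (n2 + 1)
    s_uniq = _s_for_counts(u1, u2, n0, n1, n2, n)
    s = s_uniq[inverse]
    out = replace(cell, quantile_s=_tail_order_statistic(s, cell.q))
    return (out, s) if return_draws else out


def permutation_quantile_labels(cell: SimCell) -> SimCell:
    """Reference implementation by direct label shuffling (slow; used to
    validate the hypergeometric shortcut)."""
    n = cell.n_per_group
    N = 2 * n
    n0, n1, n2 = hwe_counts(cell.maf, N)
    geno = np.repeat([0, 1, 2], [n0, n1, n2])
    rng = np.random.default_rng(cell.seed)
    k1 = np.empty(cell.n_perm, dtype=np.int64)
    k2 = np.empty(cell.n_perm, dtype=np.int64)
    for b in range(cell.n_perm):
        pick = rng.choice(N, size=n, replace=False)
        g = geno[pick]
        k1[b] = (g == 1).sum()
        k2[b] = (g == 2).sum()
    s = _s_for_counts(k1, k2, n0, n1, n2, n)
    return replace(cell, quantile_s=_tail_order_statistic(s, cell.q))


def maf_grid(mafs, ns, n_perm: int = 2_500_000, q: float = 1e-5,
             seed: int = 0) -> pd.DataFrame:
    """Quantile table over a (MAF x group size) grid with Monte-Carlo CIs.

    Each cell gets an independent child seed of ``seed``.  The CI is the
    binomial-based interval on the tail order statistic.
    """
    children = np.random.SeedSequence(seed).spawn(len(mafs) * len(ns))
    rows = []
    k = 0
    for maf in mafs:
        for n in ns:
            cell = SimCell(maf=maf, n_per_group=n, n_perm=n_perm, q=q,
                           seed=children[k].generate_state(1)[0] % (2**31))
            k += 1
            cell, s = permutation_quantile(cell, return_draws=True)
            lo_r, hi_r = stats.binom.interval(0.95, n_perm, 1 - q)
            s_part = np.sort(s)
            ci_lo = float(s_part[int(max(0, lo_r - 1))])
            ci_hi = float(s_part[int(min(n_perm - 1, hi_r))])
            rows.append({"maf": maf, "n_per_group": n, "n_perm": n_perm,
                         "q": q, "quantile_s": cell.quantile_s,
                         "ci_lo": ci_lo, "ci_hi": ci_hi})
    return pd.DataFrame(rows)


def maf_s_correlation(s_values: np.ndarray, mafs: np.ndarray,
                      n_bins: int = 5):
    """Spearman correlation of per-SNP s with MAF plus a binned summary."""
    s_values = np.asarray(s_values, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    ok = np.isfinite(s_values) & np.isfinite(mafs)
    s_values, mafs = s_values[ok], mafs[ok]
    if s_values.size < 10:
        raise ValueError("need at least 10 loci")
    if np.ptp(s_values) == 0 or np.ptp(mafs) == 0:
        rho = np.nan
    else:
        rho = float(stats.spearmanr(mafs, s_values).statistic)
    edges = np.quantile(mafs, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-12
    which = np.clip(np.digitize(mafs, edges) - 1, 0, n_bins - 1)
    summary = pd.DataFrame({
        "maf_bin_lo": edges[:-1],
        "maf_bin_hi": edges[1:],
        "n": np.bincount(which, minlength=n_bins),
        "mean_s": [s_values[which == b].mean() if (which == b).any() else np.nan
                   for b in range(n_bins)],
        "max_s": [s_values[which == b].max() if (which == b).any() else np.nan
                  for b in range(n_bins)],
    })
    return rho, summary
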