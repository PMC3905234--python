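"""u-statistic scores over partially ordered multi-SNP genotype vectors.

A *diplotype* is the unphased genotype vector at 1-6 neighbouring SNPs,
each component coded as minor-allele count (0/1/2).  After *polarization*
(choosing, per SNP, which allele counts as "risk"), subjects are compared
componentwise: subject i dominates subject j if i's polarized vector is
>= j's at every component both have called, and strictly greater at one.
The mu-score of a subject is the number of subjects it dominates minus
the number dominating it; the two-group test is the linear u-statistic of
mu-scores with its exact permutation variance and a normal approximation.
For a single SNP this reduces exactly to the tie-corrected Wilcoxon
rank-sum test (no continuity correction).

Only a monotonicity assumption is made -- additional risk alleles within
the locus do not decrease risk -- so no additivity or independence across
SNPs is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MuScores",
    "TestResult",
    "polarize",
    "mu_scores",
    "u_test",
    "stratified_u_test",
    "select_sex_specific",
    "MAX_WIDTH",
]

MAX_WIDTH = 6

_LOG10 = np.log(10.0)


@dataclass
class MuScores:
    """Per-subject mu-scores and the information content of the scoring.

    ``mu_ic`` is the fraction of subject pairs that are ordered (comparable
    and unequal); low values mark loci where the partial order carries
    little information.
    """

    scores: np.ndarray            # int64, one per subject; sums to 0
    mu_ic: float                  # n_pairs_ordered / n_pairs_total
    n_pairs_ordered: int
    n_pairs_total: int


@dataclass
class TestResult:
    """Two-group u-test outcome on the -log10 p scale (``s``)."""

    s: float                      # -log10 two-sided p
    z: float                      # standardized linear statistic
    direction: int                # +1 cases score high, -1 low, 0 degenerate
    n_cases: int
    n_controls: int
    degenerate: bool = False


def polarize(window: np.ndarray, polarity: np.ndarray) -> np.ndarray:
    """Apply a per-SNP risk orientation to a subjects x w genotype window.

    Components with polarity -1 are mapped g -> 2 - g; missing entries
    (negative) are preserved.
    """
    window = np.asarray(window)
    polarity = np.asarray(polarity)
    if polarity.shape[-1] != window.shape[-1]:
        raise ValueError("polarity length must equal window width")
    if not np.all(np.abs(polarity) == 1):
        raise ValueError("polarity entries must be +1 or -1")
    out = window.copy()
    flip = polarity < 0
    miss = window < 0
    out[:, flip] = 2 - out[:, flip]
    out[miss] = window[miss]
    return out


def _compress(window: np.ndarray):
    """Collapse subjects to unique diplotype patterns.

    Returns (patterns u x w, inverse n, counts u).  Integer genotype
    windows (values in {0,1,2}, missing < 0) are encoded base-4 so the
    unique pass runs on a 1-d integer vector; arbitrary float windows
    (NaN missing) fall back to row-wise unique.
    """
    window = np.asarray(window)
    n, w = window.shape
    if np.issubdtype(window.dtype, np.integer) and w <= 9:
        vals = np.where(window < 0, 3, window).astype(np.int64)
        codes = vals @ (4 ** np.arange(w, dtype=np.int64))
        uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
        digits = (uniq[:, None] // (4 ** np.arange(w, dtype=np.int64))) % 4
        patterns = np.where(digits == 3, -1, digits).astype(np.float64)
        patterns[patterns < 0] = np.nan
    else:
        arr = np.asarray(window, dtype=np.float64)
        patterns, inverse, counts = np.unique(
            arr, axis=0, return_inverse=True, return_counts=True
        )
        inverse = inverse.ravel()
    return patterns, inverse, counts


def _domination(patterns: np.ndarray) -> np.ndarray:
    """Boolean u x u matrix D with D[a, b] = pattern a dominates pattern b.

    Comparison restricted to components non-missing (non-NaN) in both; a
    pair with no shared component is incomparable.
    """
    valid = ~np.isnan(patterns)
    P = patterns[:, None, :]
    Q = patterns[None, :, :]
    both = valid[:, None, :] & valid[None, :, :]
    with np.errstate(invalid="ignore"):
        ge = np.where(both, P >= Q, True).all(axis=2)
        gt = np.where(both, P > Q, False).any(axis=2)
    return ge & gt


def mu_scores(window: np.ndarray, polarity: np.ndarray | None = None) -> MuScores:
    """Compute mu-scores for a subjects x w (polarized) genotype window.

    ``score_i = #{j dominated by i} - #{j dominating i}`` under the
    componentwise partial order over shared non-missing components.  The
    implementation collapses subjects to unique patterns first; it is
    exactly equivalent to the O(n^2) pairwise definition.
    """
    window = np.asarray(window)
    if window.ndim == 1:
        window = window[:, None]
    n = window.shape[0]
    if n < 2:
        raise ValueError("mu_scores needs at least two subjects")
    if polarity is not None:
        window = polarize(window, polarity)
    patterns, inverse, counts = _compress(window)
    dom = _domination(patterns).astype(np.int64)
    counts = counts.astype(np.int64)
    pattern_scores = dom @ counts - counts @ dom
    ordered = int(counts @ dom @ counts)
    total = n * (n - 1) // 2
    return MuScores(
        scores=pattern_scores[inverse],
        mu_ic=ordered / total,
        n_pairs_ordered=ordered,
        n_pairs_total=total,
    )


def _test_from_scores(scores: np.ndarray, case_mask: np.ndarray) -> tuple[float, float, float]:
    """Return (T, Var, z) for the linear statistic T = sum of case scores."""
    n1 = int(case_mask.sum())
    n2 = scores.size - n1
    N = scores.size
    T = float(scores[case_mask].sum())
    ss = float(np.square(scores, dtype=np.float64).sum())
    var = n1 * n2 * ss / (N * (N - 1)) if N > 1 else 0.0
    z = T / np.sqrt(var) if var > 0 else 0.0
    return T, var, z


def _s_from_z(z: float) -> float:
    # two-sided normal p on the -log10 scale, stable for large |z|
    log_p = np.log(2.0) + stats.norm.logsf(abs(z))
    return float(-log_p / _LOG10)


def u_test(mu: MuScores, groups: np.ndarray) -> TestResult:
    """Two-group test of mu-scores.

    ``groups`` is a boolean case indicator.  T = sum of case scores; under
    the permutation null E[T] = 0 and Var(T) = n1*n2/(N(N-1)) * sum(score^2);
    the two-sided p comes from the normal approximation (no continuity
    correction) and is reported as s = -log10 p.
    """
    case = np.asarray(groups, dtype=bool)
    if case.size != mu.scores.size:
        raise ValueError("groups length must match number of subjects")
    n1 = int(case.sum())
    n2 = case.size - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    T, var, z = _test_from_scores(mu.scores, case)
    if var <= 0:
        return TestResult(s=0.0, z=0.0, direction=0, n_cases=n1, n_controls=n2,
                          degenerate=True)
    return TestResult(
        s=_s_from_z(z),
        z=float(z),
        direction=int(np.sign(T)) if T != 0 else 0,
        n_cases=n1,
        n_controls=n2,
    )


def stratified_u_test(
    window: np.ndarray,
    groups: np.ndarray,
    strata: np.ndarray,
    polarity: np.ndarray | None = None,
) -> TestResult:
    """Stratified u-test: mu-scores within each stratum, T and Var summed.

    Strata with only one group present contribute no information and are
    skipped; if no stratum is informative the result is degenerate.
    """
    window = np.asarray(window)
    if window.ndim == 1:
        window = window[:, None]
    case = np.asarray(groups, dtype=bool)
    strata = np.asarray(strata)
    T_tot = 0.0
    var_tot = 0.0
    n1_tot = n2_tot = 0
    for lab in np.unique(strata):
        idx = strata == lab
        sub_case = case[idx]
        n1 = int(sub_case.sum())
        n2 = int(idx.sum()) - n1
        if n1 == 0 or n2 == 0 or idx.sum() < 2:
            continue
        mu = mu_scores(window[idx], polarity)
        T, var, _ = _test_from_scores(mu.scores, sub_case)
        T_tot += T
        var_tot += var
        n1_tot += n1
        n2_tot += n2
    if var_tot <= 0 or n1_tot == 0 or n2_tot == 0:
        return TestResult(s=0.0, z=0.0, direction=0, n_cases=n1_tot,
                          n_controls=n2_tot, degenerate=True)
    z = T_tot / np.sqrt(var_tot)
    return TestResult(
        s=_s_from_z(z),
        z=float(z),
        direction=int(np.sign(T_tot)) if T_tot != 0 else 0,
        n_cases=n1_tot,
        n_controls=n2_tot,
    )


class WindowEngine:
    """Shared pattern comparisons for all polarities of one genotype window.

    Subjects are collapsed to unique diplotype patterns once; the strict
    componentwise comparison matrix of each column is reused across
    polarities (flipping a column's polarity transposes its comparison
    matrix).  Produces exactly the same statistics as ``mu_scores`` +
    ``u_test`` / ``stratified_u_test``; exists because the genome scan
    evaluates up to 2^(w-1) polarities per window.
    """

    def __init__(self, window: np.ndarray, case: np.ndarray,
                 strata: np.ndarray | None = None):
        window = np.asarray(window)
        if window.ndim == 1:
            window = window[:, None]
        self.w = window.shape[1]
        case = np.asarray(case, dtype=bool)
        patterns, inverse, _ = _compress(window)
        u = len(patterns)
        if strata is None:
            strata_idx = np.zeros(len(case), dtype=np.int64)
            n_strata = 1
            self.stratum_labels = ["all"]
        else:
            labels, strata_idx = np.unique(np.asarray(strata), return_inverse=True)
            n_strata = len(labels)
            self.stratum_labels = list(labels)
        # per-stratum pattern counts, overall and for cases
        flat = strata_idx * u + inverse
        self.counts = np.bincount(flat, minlength=n_strata * u) \
            .reshape(n_strata, u).astype(np.float64)
        self.case_counts = np.bincount(flat[case], minlength=n_strata * u) \
            .reshape(n_strata, u).astype(np.float64)
        self.n1 = self.case_counts.sum(axis=1)
        self.n = self.counts.sum(axis=1)
        valid = ~np.isnan(patterns)
        self._gt = []
        for k in range(self.w):
            col = patterns[:, k]
            both = valid[:, k][:, None] & valid[:, k][None, :]
            with np.errstate(invalid="ignore"):
                self._gt.append((col[:, None] > col[None, :]) & both)

    def _domination(self, polarity: np.ndarray) -> np.ndarray:
        ge = None
        gt = None
        for k in range(self.w):
            Gk = self._gt[k] if polarity[k] > 0 else self._gt[k].T
            Lk = self._gt[k].T if polarity[k] > 0 else self._gt[k]
            ge = ~Lk if ge is None else ge & ~Lk
            gt = Gk if gt is None else gt | Gk
        return ge & gt

    def stats(self, polarity: np.ndarray):
        """(z, T, per-stratum (T_k, var_k)) for one polarity; z pools strata."""
        D = self._domination(polarity)
        M = (D.T.astype(np.float64) - D)
        S = self.counts @ M                      # per-stratum pattern scores
        T_k = (self.case_counts * S).sum(axis=1)
        ss_k = (self.counts * S * S).sum(axis=1)
        n2 = self.n - self.n1
        with np.errstate(invalid="ignore", divide="ignore"):
            var_k = np.where(self.n > 1,
                             self.n1 * n2 * ss_k / (self.n * (self.n - 1)), 0.0)
        informative = (self.n1 > 0) & (n2 > 0)
        T = T_k[informative].sum()
        var = var_k[informative].sum()
        z = T / np.sqrt(var) if var > 0 else 0.0
        return float(z), float(T), T_k, var_k

    def mu_ic(self, polarity: np.ndarray) -> float:
        """Pooled fraction of ordered subject pairs under this polarity."""
        D = self._domination(polarity)
        tot = self.counts.sum(axis=0)
        n = int(tot.sum())
        ordered = float(tot @ D @ tot)
        return ordered / (n * (n - 1) / 2)


_LOG10_2 = float(np.log10(2.0))


def select_sex_specific(s_strat: float, s_male: float, s_female: float) -> tuple[float, str]:
    """Pick between the sex-stratified and the better single-sex result.

    The single-sex value is Bonferroni-adjusted for the two sexes
    (s - log10 2) and reported only when it strictly beats the stratified
    analysis; ties keep the stratified result.
    """
    if min(s_strat, s_male, s_female) < 0:
        raise ValueError("s-values must be non-negative")
    if s_male >= s_female:
        s_adj, label = s_male - _LOG10_2, "male"
    else:
        s_adj, label = s_female - _LOG10_2, "female"
    if s_adj > s_strat:
        return s_adj, label
    return s_strat, "stratified"
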