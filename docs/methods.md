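# Methods

## The model

`mugwas` tests case/control (or severe-case vs mild-case) association on
*wide loci*: unphased genotype vectors over 1–6 neighbouring SNPs
("diplotypes"), each component coded as minor-allele count 0/1/2. The
only substantive assumption is monotonicity — that additional risk
alleles within the locus do not decrease risk, to an unknown extent — so
no additivity or independence across SNPs is imposed, and epistatic
(thresholded) joint effects that are invisible marginally remain
detectable.

After choosing a per-SNP *polarity* (which allele counts as risk; the
first component is fixed to +1 since a global flip is equivalent),
subjects are partially ordered componentwise over the components both
members of a pair have called. The **μ-score** of a subject is the
number of subjects it dominates minus the number dominating it; the
fraction of ordered pairs (**μIC**) measures how informative the
ordering is. The two-group test uses the linear statistic
T = Σ_cases score_i, whose permutation moments are exact:

    E[T] = 0,   Var(T) = n1 n2 / (N (N − 1)) · Σ_i score_i²

with z = T/√Var referred to the normal law, two-sided, and reported as
s = −log10 p. For a single SNP the μ-scores are affine in midranks, so
the test is *exactly* the tie-corrected Wilcoxon rank-sum normal
approximation without continuity correction; the test suite pins this
equivalence to 1e-10 relative precision, and pins the pattern-compressed
implementation to the O(n²) pairwise definition exactly.

Subjects with missing components are compared on shared non-missing
components; a pair with nothing shared is incomparable. A subject
incomparable to everyone scores 0 but stays in the permutation set —
this keeps the fast count-based single-SNP path and the general engine
numerically identical.

### Genome scan

For each center SNP, windows of widths 1–6 (even widths left-heavy,
truncated at chromosome ends) are evaluated under all 2^(w−1)
polarities; the best s per center is kept with its width, polarity and
μIC, plus per-width maxima for region plots. Since s is monotone in
|z|, only the best polarity per width is converted to a p-value.
Reliability flags:

- **single-SNP-driven** — leave-one-out: if removing one member SNP
  costs more than half of s *and* that SNP alone comes within 0.5 of
  the window's s, the wide locus is just a univariate hit in disguise.
  Both thresholds (0.5/0.5) are package defaults; the exception that a
  flag is cleared when the same center SNP is in both stages' top-k
  lives in `combine.clear_replicated_driver_flags`.
- **low μIC** — below 0.2 (configurable) the partial order carries too
  little information for the locus to be trusted.
- **unannotated** — the center SNP falls in no supplied gene/LD-block
  interval (BED, 0-based half-open).

Flagged loci stay in every quantile-rank curve (they are genuine test
results); only reported gene lists and region calls exclude them.

## Study-specific genome-wide significance

A scan over overlapping diplotypes makes fixed genome-wide thresholds
doubly wrong: discreteness of genotype data bends the null
quantile-quantile curve *below* the diagonal at low MAF (see below),
while multiple dependent tests per center lift the curve *above* it.
The package therefore estimates significance from the data:

1. **Projected QR curve per chromosome.** Sorted s-values are plotted
   against expected uniform quantiles e_i = −log10((n−i+0.5)/n) and
   smoothed with a local quadratic (tricube-weighted, k-nearest-
   neighbour span, default 0.3). As many of the highest values are
   truncated as needed for the fit to be monotone nondecreasing with
   non-positive curvature near its top; the **apex** is the resulting
   fit evaluated at the *full* panel's top expected quantile (the rank
   range is not shrunk by truncation — only the values are removed).
2. **Whole-genome apex.** Per-chromosome deviation is the maximum
   absolute residual over retained points; the 10 lowest-deviation
   autosomes (sex chromosomes never enter) are selected and the median
   of their apices is the study-specific genome-wide-significance
   cutoff. A 25%-winsorized-mean alternative sits behind a flag.
3. **Estimated curve** (for plotting): the highest raw values are
   replaced by the WG apex, one at a time, until the refitted curve's
   own apex is at or below that level.
4. **Calls.** Loci with s above the cutoff, minus flagged ones, merged
   into regions whenever their best windows share a SNP.

### Numerical choices

- The loess is a plain local weighted least-squares quadratic (gaussian
  family, no robustness iterations), evaluated at every point up to
  1000 points and on an evenly rank-spaced 1000-point subgrid with
  linear interpolation above that, as classical loess implementations
  do. It is exactly linear in the response, reproduces linear and
  quadratic data to numerical precision, and is cross-checked against
  R's `loess(degree=2)` in the test suite.
- The shape check behind truncation: monotonicity over the whole curve
  (tolerance 1e-9 scaled by the mean slope) and concavity
  (non-increasing slope) over the top decile of points at a tolerance
  of 0.05 times the mean slope. A strictly global, strictly zero-
  tolerance concavity requirement is inoperable on finite data: the
  empirical QR curve of a few thousand discrete s-values has plateaus
  and kinks in its interior that no amount of top-truncation can
  remove, while the apex region — the only part truncation can repair,
  and the only part that feeds the cutoff — is exactly where upward
  curvature signals inflated top values. If the floor of the truncation
  loop is reached the floor fit is kept with a warning.
- Expected quantiles use the symmetric (i − 0.5)/n convention, avoiding
  infinities at the top rank. A rank-based x-axis was evaluated and
  rejected: the strong convexity of s against rank makes the boundary
  fit collapse.
- On pure-null panels of independent loci the extrapolated apex is
  approximately unbiased for the diagonal endpoint −log10(0.5/n); the
  deviation-based selection of chromosomes then biases the median
  cutoff *down* by roughly 0.2 (chromosomes whose top order statistics
  happen to run high also have large maximum residuals and are
  excluded). This conservatism is inherent in the published selection
  rule, which was designed to keep signal-bearing chromosomes out of
  the null estimate; consequently a handful of null loci per genome
  exceed the cutoff (the acceptance suite measures both effects and
  documents where they land).

## MAF–significance correlation

With two groups of n subjects and pooled genotype counts fixed at
rounded Hardy–Weinberg expectations, label permutation is equivalent to
drawing the group-1 genotype counts from a multivariate hypergeometric
distribution — the implementation samples counts in bulk, deduplicates,
and evaluates s only on distinct count pairs, making 2.5 million
permutations per cell a few seconds' work. The 1−10⁻⁵ quantile is the
plain empirical order statistic. At high MAF the normal approximation
without continuity correction attains s slightly above 5 at this
quantile; as MAF falls the attainable tail contracts — the
MAF–significance correlation that motivates study-specific rather than
fixed cutoffs. These quantiles are sensitive to the exact test variant
(sidedness, continuity correction, count rounding) at the 0.1–0.3
level in s; the package pins one variant (two-sided, no continuity
correction, fixed counts) and states it here so the numbers are
reproducible.

## Fisher combination across stages

Two independent stages' s-values combine via X = 2 ln(10) (s₁+s₂),
which is χ² with 4 degrees of freedom under the joint null; the closed
form of its survival function gives

    s_F = (s₁ + s₂) − log10(1 + X/2)

evaluated in log space (stable for arbitrarily large inputs, checked
against the χ²₄ survival function to 1e-10 relative). Stage evidence is
combined at the gene level, each stage contributing its best locus s
within the gene's annotation interval; within-gene multiplicity is
already absorbed by the apex criterion and is not re-penalized.

## The synthetic-data generator

`synthdata` emulates the structure the method assumes, not any real
cohort: autosomal panels organised in LD blocks built by copying a
small pool of founder haplotypes (no recombination within a block — the
simplest mechanism producing block LD), Hardy–Weinberg genotypes by
random founder pairing, founder frequencies from a flat Dirichlet with
per-SNP allele assignment greedily matching a target MAF drawn from the
configured range, missingness completely at random, and two severity
groups filled by case/case sampling from a logistic penetrance. Planted
wide loci carry a hard epistatic threshold: no effect below k risk
alleles, log-odds linear in the excess above it. Sex is independent of
genotype unless a locus declares a sex-specific effect; stages share
the founder pool (same panel, same LD) and draw independent subjects.

Defaults (500 per group, 8 chromosomes × 50 SNPs, blocks of 3–8 SNPs
from 8 founders, MAF 0.02–0.5, 1% missingness, 85% male, odds
multiplier 3 above a 2-copy threshold for planted loci) are of the
order of a single sex-skewed genotyping-study stage at desk scale.
What the generator does *not* model: realistic recombination maps and
demography, imputation uncertainty, batch effects, population
stratification, relatedness. Passing tests therefore show the
machinery's statistical behaviour under its own assumptions, not
robustness to the artifacts of real cohorts.

Two test-specific configurations are deliberate choices, not defaults:
the null-apex calibration uses independent loci (block size 1) with MAF
0.1–0.5, because the theoretical diagonal endpoint it is compared to
presumes independent, granularity-free tests — under LD or very low MAF
the apex is *genuinely* lower, which is the method's point, not an
estimator error; and the permutation-quantile table fixes genotype
counts at HWE expectations to isolate permutation variability.

## Problem sizes used in the automated checks

Calibration runs 20 null genomes of 20 chromosomes × 5,000 loci with
500 subjects per group (single-SNP scans); recovery and specificity run
50 planted and 50 null genomes of 8 chromosomes × 40 SNPs under the
full width-1–6 scan with flags and annotation; the permutation table
runs the full 2.5 × 10⁶ permutations per cell. These sizes keep each
property estimable with reasonable Monte-Carlo error while the whole
suite remains a desk-scale run.

## Known limitations

- The normal approximation to the permutation null is anti-conservative
  in the extreme tail for very rare variants; the QC MAF filter (2%)
  and the μIC flag bound the exposure, and the granularity ceiling is
  surfaced by `mafsim` rather than hidden.
- The study-specific cutoff is a heuristic, deliberately so: it offers
  consistency and unbiasedness arguments, not an error-rate guarantee,
  and under a pure null a few loci per genome will exceed it.
- Covariate adjustment (including principal-component ancestry
  correction) is out of scope; the wide-locus design reduces, but does
  not remove, sensitivity to stratification.
- Exact permutation p-values for wide loci are not computed; the
  normal approximation is used throughout.
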