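# mugwas

Wide-locus case/control GWAS with u-statistic μ-scores, study-specific
genome-wide significance from quantile-rank (QR) curve apices,
permutation quantification of the MAF–significance correlation, and
Fisher combination across independent study stages.

## Who this is for

Statistical geneticists analysing common-disease case/control (or
severe-vs-mild case/case) genotype panels in which risk is carried by
*combinations* of neighbouring common variants — epistatic wide loci
that single-SNP scans with fixed genome-wide thresholds systematically
miss. The package is a library first (`import mugwas`), with a thin
`mugwas` command-line front end and runnable scripts in `examples/`.

## The statistic

A **diplotype** is the unphased genotype vector at 1–6 neighbouring
SNPs, each coded 0/1/2 in minor-allele dose. After polarizing each SNP
(choosing its risk allele), subjects are partially ordered
componentwise; subject *i*'s **μ-score** is

    score_i = #{j : i dominates j} − #{j : j dominates i}

The two-group test uses T = Σ_cases score_i with its exact permutation
variance Var(T) = n₁n₂/(N(N−1)) Σ score_i², z = T/√Var, and reports
s = −log₁₀ p (two-sided normal). For a single SNP this is exactly the
tie-corrected Wilcoxon rank-sum test. The only modelling assumption is
that extra risk alleles within the locus do not decrease risk — no
additivity, no independence.

Because discrete genotypes bound the attainable p-values (more tightly
the rarer the allele — the **MAF–significance correlation**), and
overlapping diplotypes multiply dependent tests, fixed thresholds are
replaced by a **study-specific cutoff**: per chromosome, the sorted
s-values against expected uniform quantiles are loess-projected after
truncating top values until the fit is monotone and concave near its
apex; the whole-genome cutoff is the median apex of the ten
lowest-deviation autosomes. Two stages combine per gene by Fisher's
method, s_F = (s₁+s₂) − log₁₀(1 + ln10·(s₁+s₂)), the closed-form χ²₄
tail.

## Worked example

```sh
python examples/01_wide_locus_scan.py
```

generates a 1000-subject study with a planted 4-SNP epistatic locus
(odds ×3 above a 2-copy threshold) at chromosome 1, SNP indices 18–21,
scans all widths and polarities, and prints:

```
top 5 loci (s = -log10 p of the best diplotype at each center):
chrom     rsid  center_index         s  best_width polarity    mu_ic
    1 rs000021            20 11.657824           2       ++ 0.574947
    1 rs000022            21 10.568581           4     ++++ 0.555213
    1 rs000023            22 10.273481           3      +++ 0.552947
    1 rs000019            18  9.713028           6   +++-++ 0.356200
    1 rs000024            23  9.514539           1        + 0.433742
```

Every top center sits inside or beside the planted locus; `s` is the
best −log₁₀ p over widths 1–6 and polarities at that center,
`best_width`/`polarity` identify the winning diplotype, and `mu_ic` is
the fraction of subject pairs the partial order actually ranks
(low values flag unreliable loci). `examples/02_*` continues to the
study-specific cutoff and region calls, `03_*` tabulates the
permutation-null tail quantiles per MAF, `04_*` the Fisher stage
combination, `05_*` an allelotype severity profile against unrelated
controls.

The same pipeline is scriptable from a shell:

```sh
mugwas synth --out study/ --planted --seed 7
mugwas qc   --in study/study --out qced/
mugwas scan --in qced/filtered --annotation study/study.genes.bed --out scan.tsv
mugwas gws  --scan scan.tsv --out gws/
```

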