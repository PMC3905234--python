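"""Quantify the MAF-significance correlation of the rank test.

For discrete genotype data the extreme tail of the permutation null
contracts with minor allele frequency: rare variants simply cannot
reach the significance common ones can. This reproduces the tail
quantile table at reduced permutation count (2.5e5 instead of 2.5e6;
pass --full for the full-size run) -- the 1-1e-5 quantile of s sits
slightly above 5 at MAF 0.40 and falls as MAF or sample size shrink.
"""

import sys

from mugwas.mafsim import maf_grid

n_perm = 2_500_000 if "--full" in sys.argv else 250_000
table = maf_grid(mafs=[0.05, 0.20, 0.40], ns=[300, 1000],
                 n_perm=n_perm, q=1e-5, seed=1)
table["q"] = table["q"].map("{:.0e}".format)
print(f"permutation-null 1-1e-5 quantiles of s ({n_perm:,} permutations/cell):")
print(table.round(3).to_string(index=False))
print("\nthe rare-variant cells sit well below the common-variant ones, and "
      "at MAF 0.05 the attainable tail grows with the per-group n; "
      "ci_lo/ci_hi bound the Monte-Carlo error of the order statistic.")
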