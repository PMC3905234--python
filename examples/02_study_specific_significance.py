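"""Estimate a study-specific genome-wide-significance cutoff.

Scans a planted-signal study, fits a projected quantile-rank curve per
chromosome, takes the median apex of the lowest-deviation autosomes as
the whole-genome cutoff, and reports the significant regions. The
printed cutoff is the s-value a locus must exceed to be called in THIS
study -- it adapts to panel size, MAF spectrum and the multiplicity of
overlapping diplotypes instead of using a fixed genome-wide threshold.
"""

import warnings

from mugwas.gws_apex import call_study_gws, genome_curves, wg_apex
from mugwas.scan import restrict_to_annotated, scan_study
from mugwas.synthdata import (PlantedLocus, SynthConfig, generate_study,
                              make_annotation)

cfg = SynthConfig(
    n_subjects_per_group=500,
    n_chromosomes=8,
    snps_per_chromosome=40,
    planted_loci=[PlantedLocus(0, (18, 19, 20, 21), (1, 1, 1, 1))],
    seed=3,
)
study, truth = generate_study(cfg)
results = scan_study(study, flag_drivers=True)
results = restrict_to_annotated(results, make_annotation(cfg))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    curves = genome_curves(results)
    apex = wg_apex(curves, n_select=10)

print("per-chromosome projected QR apices:")
print(apex.per_chromosome.round(3).to_string(index=False))
print(f"\nstudy-specific GWS cutoff (WG apex): {apex.wg_apex:.3f}")

sig, regions = call_study_gws(results, apex)
print(f"\n{len(regions)} significant region(s) above the cutoff:")
if len(regions):
    print(regions.round(3).to_string(index=False))
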