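"""Synthetic case/case genotype studies with LD-block structure.

Emulates the design the scan assumes: autosomal SNP panels organised in
linkage-disequilibrium blocks built from a small pool of founder
haplotypes, Hardy-Weinberg genotypes from random haplotype pairing, a
minor-allele-frequency spectrum reaching down to rare variants,
missingness completely at random, two severity groups (severe vs mild
cases), sex strata, and optionally several independent stages and a set
of unrelated controls.  Risk loci are *planted* as contiguous multi-SNP
wide loci with a monotone, optionally epistatic (thresholded) penetrance
in the polarized risk-allele count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeStudy

__all__ = ["PlantedLocus", "SynthConfig", "generate_haplotype_blocks",
           "generate_study", "make_annotation", "write_study"]

_SNP_SPACING_BP = 5000
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class PlantedLocus:
    """A contiguous wide locus carrying risk for the severe phenotype.

    ``risk_orientation`` gives the per-SNP sign (+1: minor allele is the
    risk allele).  The polarized risk count r is the sum over SNPs of the
    risk-allele dose; penetrance is flat below ``threshold`` copies and
    rises by log(effect_size) per additional copy above it (monotone,
    epistatic when threshold > 0).  ``sex_specific`` restricts the effect
    to 'M' or 'F' carriers.
    """

    chromosome: int
    snp_indices: tuple
    risk_orientation: tuple
    effect_size: float = 3.0
    threshold: int = 2
    sex_specific: str | None = None

    def __post_init__(self):
        idx = np.asarray(self.snp_indices)
        if not 1 <= len(idx) <= 6:
            raise ValueError("planted locus width must be 1..6")
        if len(idx) > 1 and not np.all(np.diff(idx) == 1):
            raise ValueError("planted locus SNP indices must be contiguous")
        if len(self.risk_orientation) != len(idx):
            raise ValueError("risk_orientation length mismatch")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be a positive odds multiplier")

    def risk_count(self, geno_chrom: np.ndarray) -> np.ndarray:
        """Polarized risk-allele count per subject (missing counted 0)."""
        idx = list(self.snp_indices)
        g = geno_chrom[:, idx].astype(np.int64)
        orient = np.asarray(self.risk_orientation)
        pol = np.where(orient[None, :] > 0, g, 2 - g)
        pol[g < 0] = 0
        return pol.sum(axis=1)


@dataclass
class SynthConfig:
    """Generator parameters; the defaults set the reference study design."""

    n_subjects_per_group: int = 500
    n_chromosomes: int = 8
    snps_per_chromosome: int = 50
    block_size_range: tuple = (3, 8)
    founder_haplotypes_per_block: int = 8
    maf_range: tuple = (0.02, 0.5)
    missing_rate: float = 0.01
    planted_loci: list = field(default_factory=list)
    sex_ratio: float = 0.85          # fraction male, matching a male-skewed design
    stages: int = 1
    n_controls: int = 0              # optional unrelated controls per stage
    base_rate: float = 0.5           # P(severe) with zero planted risk
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.block_size_range[0] < 1 or self.block_size_range[0] > self.block_size_range[1]:
            raise ValueError("invalid block_size_range")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.founder_haplotypes_per_block < 1:
            raise ValueError("need at least one founder haplotype per block")
        n_snps = self.n_chromosomes * self.snps_per_chromosome
        for locus in self.planted_loci:
            if locus.chromosome >= self.n_chromosomes:
                raise ValueError(f"planted locus on chromosome {locus.chromosome} "
                                 f"outside panel of {self.n_chromosomes}")
            if max(locus.snp_indices) >= self.snps_per_chromosome:
                raise ValueError("planted locus SNP indices outside chromosome")


@dataclass
class HaplotypeBlock:
    chromosome: int
    snp_offset: int                  # first SNP index within the chromosome
    haplotypes: np.ndarray           # founders x block_size, 0/1 minor-allele
    freqs: np.ndarray                # founder haplotype frequencies
    target_maf: np.ndarray


def _assign_alleles(freqs: np.ndarray, target: float, rng) -> np.ndarray:
    """Pick a founder subset whose total frequency approximates ``target``.

    Greedy subset selection over a random founder order; guarantees the
    SNP is polymorphic in the founder pool.
    """
    order = rng.permutation(len(freqs))
    carrier = np.zeros(len(freqs), dtype=np.int8)
    total = 0.0
    for f in order:
        if abs(total + freqs[f] - target) < abs(total - target):
            carrier[f] = 1
            total += freqs[f]
    if carrier.sum() == 0:
        carrier[np.argmin(np.abs(freqs - target))] = 1
    if carrier.sum() == len(freqs):
        carrier[np.argmax(freqs)] = 0
    return carrier


def generate_haplotype_blocks(cfg: SynthConfig) -> list:
    """Founder haplotype pools for every LD block of every chromosome."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    lo, hi = cfg.block_size_range
    blocks = []
    for chrom in range(cfg.n_chromosomes):
        offset = 0
        while offset < cfg.snps_per_chromosome:
            size = min(int(rng.integers(lo, hi + 1)), cfg.snps_per_chromosome - offset)
            h = cfg.founder_haplotypes_per_block
            freqs = rng.dirichlet(np.ones(h))
            freqs = np.sort(freqs)[::-1]
            target = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=size)
            haps = np.stack(
                [_assign_alleles(freqs, t, rng) for t in target], axis=1
            )  # founders x size
            if h == 1:
                haps = np.zeros((1, size), dtype=np.int8)
            blocks.append(HaplotypeBlock(chrom, offset, haps.astype(np.int8),
                                         freqs, target))
            offset += size
    return blocks


def _draw_genotypes(blocks, n, rng) -> np.ndarray:
    """Random pairing of founder haplotypes per block (HWE within block)."""
    chroms = max(b.chromosome for b in blocks) + 1
    per_chrom = {}
    for b in blocks:
        per_chrom.setdefault(b.chromosome, []).append(b)
    cols = []
    for chrom in range(chroms):
        for b in sorted(per_chrom[chrom], key=lambda b: b.snp_offset):
            cumf = np.cumsum(b.freqs)
            cumf[-1] = 1.0
            pick = np.searchsorted(cumf, rng.random((2, n)), side="right")
            cols.append(b.haplotypes[pick[0]] + b.haplotypes[pick[1]])
    return np.concatenate(cols, axis=1).astype(np.int8)


def _severe_probability(cfg: SynthConfig, geno: np.ndarray, sex: np.ndarray) -> np.ndarray:
    logit = np.full(geno.shape[0], np.log(cfg.base_rate / (1 - cfg.base_rate)))
    for locus in cfg.planted_loci:
        start = locus.chromosome * cfg.snps_per_chromosome
        sub = geno[:, start : start + cfg.snps_per_chromosome]
        r = locus.risk_count(sub)
        excess = np.maximum(0, r - locus.threshold)
        eff = excess * np.log(locus.effect_size)
        if locus.sex_specific is not None:
            eff = np.where(sex == locus.sex_specific, eff, 0.0)
        logit = logit + eff
    return 1.0 / (1.0 + np.exp(-logit))


def _sample_stage(cfg, blocks, rng, stage):
    """Draw subjects for one stage by case/case sampling to fixed group sizes."""
    n_target = cfg.n_subjects_per_group
    got = {"case-severe": [], "case-mild": []}
    sexes = {"case-severe": [], "case-mild": []}
    have = {"case-severe": 0, "case-mild": 0}
    # with planted risk the severe fraction can drift from 1/2; over-draw more
    batch = max(int(2.3 * n_target) if not cfg.planted_loci else 4 * n_target, 200)
    guard = 0
    while min(have.values()) < n_target:
        guard += 1
        if guard > 200:
            raise RuntimeError("phenotype sampling did not fill both groups; "
                               "penetrance is too extreme")
        g = _draw_genotypes(blocks, batch, rng)
        sex = np.where(rng.random(batch) < cfg.sex_ratio, "M", "F")
        p = _severe_probability(cfg, g, sex)
        severe = rng.random(batch) < p
        for label, mask in (("case-severe", severe), ("case-mild", ~severe)):
            need = n_target - have[label]
            if need > 0:
                take = np.flatnonzero(mask)[:need]
                got[label].append(g[take])
                sexes[label].append(sex[take])
                have[label] += take.size
    rows, labels, sex_all = [], [], []
    for label in ("case-severe", "case-mild"):
        rows.append(np.concatenate(got[label], axis=0)[:n_target])
        labels += [label] * n_target
        sex_all.append(np.concatenate(sexes[label])[:n_target])
    if cfg.n_controls > 0:
        g = _draw_genotypes(blocks, cfg.n_controls, rng)
        sex = np.where(rng.random(cfg.n_controls) < cfg.sex_ratio, "M", "F")
        rows.append(g)
        labels += ["control"] * cfg.n_controls
        sex_all.append(sex)
    geno = np.concatenate(rows, axis=0)
    sex_all = np.concatenate(sex_all)
    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno[miss] = MISSING
    subjects = pd.DataFrame({
        "id": [f"S{stage}_{i:05d}" for i in range(len(labels))],
        "group": labels,
        "sex": sex_all,
        "stage": stage,
    })
    return geno, subjects


def _snp_map(cfg: SynthConfig) -> pd.DataFrame:
    recs = []
    k = 0
    for chrom in range(cfg.n_chromosomes):
        for j in range(cfg.snps_per_chromosome):
            a_mn, a_mj = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
            recs.append((str(chrom + 1), (j + 1) * _SNP_SPACING_BP,
                         f"rs{k + 1:06d}", a_mn, a_mj))
            k += 1
    return pd.DataFrame(recs, columns=["chrom", "pos", "rsid", "a_minor", "a_major"])


def generate_study(cfg: SynthConfig):
    """Generate a study and its truth table.

    Returns (GenotypeStudy, truth DataFrame).  With several stages, all
    stages share the founder haplotype pool (same panel and LD structure)
    but draw independent subjects; the stage is recorded per subject.
    Deterministic given ``cfg.seed``.
    """
    blocks = generate_haplotype_blocks(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    genos, subs = [], []
    for stage in range(1, cfg.stages + 1):
        g, s = _sample_stage(cfg, blocks, rng, stage)
        genos.append(g)
        subs.append(s)
    geno = np.concatenate(genos, axis=0)
    subjects = pd.concat(subs, ignore_index=True)
    snp_map = _snp_map(cfg)
    # harmonize coding with the pooled-sample minor allele so a written
    # study reads back identically
    called = (geno >= 0).sum(axis=0)
    freq = np.where(geno >= 0, geno, 0).sum(axis=0) / np.maximum(1, 2 * called)
    flip_idx = np.flatnonzero(freq > 0.5)
    if flip_idx.size:
        sub = geno[:, flip_idx]
        miss = sub < 0
        sub = (2 - sub).astype(np.int8)
        sub[miss] = MISSING
        geno[:, flip_idx] = sub
        mn = snp_map["a_minor"].to_numpy().copy()
        mj = snp_map["a_major"].to_numpy().copy()
        snp_map["a_minor"] = np.where(freq > 0.5, mj, mn)
        snp_map["a_major"] = np.where(freq > 0.5, mn, mj)
    study = GenotypeStudy(genotypes=geno, snp_map=snp_map, subjects=subjects)
    truth = pd.DataFrame([
        {
            "chrom": str(l.chromosome + 1),
            "snp_start": min(l.snp_indices),
            "snp_end": max(l.snp_indices),
            "center_index": l.chromosome * cfg.snps_per_chromosome
                            + (min(l.snp_indices) + max(l.snp_indices)) // 2,
            "orientation": "".join("+" if o > 0 else "-" for o in l.risk_orientation),
            "effect_size": l.effect_size,
            "threshold": l.threshold,
            "sex_specific": l.sex_specific or "",
        }
        for l in cfg.planted_loci
    ], columns=["chrom", "snp_start", "snp_end", "center_index", "orientation",
                "effect_size", "threshold", "sex_specific"])
    return study, truth


def make_annotation(cfg: SynthConfig, coverage: float = 0.4, gene_span: int = 6,
                    seed: int | None = None) -> pd.DataFrame:
    """BED-style gene intervals: all planted loci plus random 'genes'.

    Intervals are 0-based half-open on bp coordinates and cover roughly
    ``coverage`` of the panel.  Planted loci are always covered.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seed if seed is None else seed, 303]))
    recs = []
    k = 0
    for locus in cfg.planted_loci:
        chrom = str(locus.chromosome + 1)
        lo = (min(locus.snp_indices) + 1) * _SNP_SPACING_BP
        hi = (max(locus.snp_indices) + 1) * _SNP_SPACING_BP
        recs.append((chrom, lo - 1, hi, f"PLANTED{k}"))
        k += 1
    n_rand = int(coverage * cfg.n_chromosomes * cfg.snps_per_chromosome / gene_span)
    for i in range(n_rand):
        chrom = int(rng.integers(cfg.n_chromosomes))
        start_snp = int(rng.integers(max(1, cfg.snps_per_chromosome - gene_span)))
        lo = (start_snp + 1) * _SNP_SPACING_BP
        hi = (start_snp + gene_span) * _SNP_SPACING_BP
        recs.append((str(chrom + 1), lo - 1, hi, f"GENE{i}"))
    bed = pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])
    return bed.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_study(study: GenotypeStudy, truth: pd.DataFrame, out_dir,
                annotation: pd.DataFrame | None = None, prefix="study") -> None:
    """Emit PLINK text, subject TSV, truth TSV and optional BED annotation."""
    from pathlib import Path

    from .io_qc import write_plink

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_plink(study, out / prefix)
    truth.to_csv(out / f"{prefix}.truth.tsv", sep="\t", index=False)
    if annotation is not None:
        annotation.to_csv(out / f"{prefix}.genes.bed", sep="\t",
                          index=False, header=False)
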