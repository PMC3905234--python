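"""Genotype study I/O and SNP-level quality control.

Reads case/control genotype matrices from PLINK text (.ped/.map) or VCF
together with a subject metadata TSV, codes genotypes as minor-allele
counts, and applies five SNP filters in a fixed order: minor-allele
frequency, missingness, one-sided Hardy-Weinberg heterozygote deficit,
adjacent-pair linkage disequilibrium, and a data-quality mu-score decile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import mucore

__all__ = [
    "GenotypeStudy",
    "QCReport",
    "QCThresholds",
    "read_genotypes",
    "read_plink",
    "read_vcf",
    "write_plink",
    "test_hwe_het_deficit",
    "neighbor_r2",
    "quality_mu_score",
    "apply_qc",
]

MISSING = -1

GROUPS = ("case-severe", "case-mild", "control")


@dataclass
class GenotypeStudy:
    """Subjects x SNPs minor-allele-count matrix with metadata.

    ``genotypes`` holds int8 entries in {0, 1, 2}, missing coded -1.
    ``snp_map`` columns: chrom, pos (1-based bp), rsid, a_minor, a_major.
    ``subjects`` columns: id, group (case-severe / case-mild / control),
    sex ('M'/'F'), stage (int).
    """

    genotypes: np.ndarray
    snp_map: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self):
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.subjects = self.subjects.reset_index(drop=True)
        if self.genotypes.shape != (len(self.subjects), len(self.snp_map)):
            raise ValueError("genotype matrix shape does not match metadata")
        if self.snp_map["rsid"].duplicated().any():
            dups = self.snp_map["rsid"][self.snp_map["rsid"].duplicated()].tolist()
            raise ValueError(f"duplicate rsIDs: {dups[:5]}")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def chromosomes(self):
        return self.snp_map["chrom"].unique()

    def snp_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.snp_map["chrom"] == chrom).to_numpy())

    def subset_snps(self, keep: np.ndarray) -> "GenotypeStudy":
        return GenotypeStudy(
            genotypes=self.genotypes[:, keep],
            snp_map=self.snp_map.iloc[keep],
            subjects=self.subjects,
        )

    def subset_subjects(self, keep: np.ndarray) -> "GenotypeStudy":
        return GenotypeStudy(
            genotypes=self.genotypes[keep],
            snp_map=self.snp_map,
            subjects=self.subjects.iloc[keep],
        )

    def group_mask(self, group: str) -> np.ndarray:
        return (self.subjects["group"] == group).to_numpy()

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency among non-missing calls."""
        g = self.genotypes
        called = (g >= 0).sum(axis=0)
        alt = np.where(g >= 0, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / (2.0 * called)
        return np.where(called > 0, freq, np.nan)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of genotypes 0/1/2 (columns) among called subjects."""
        g = self.genotypes
        return np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


@dataclass
class QCThresholds:
    maf: float = 0.02
    missing: float = 0.20
    hwe: float = 1e-4
    ld: float = 0.98
    quality_decile: float = 0.10


@dataclass
class QCReport:
    """Per-filter removal counts and rsID lists, in application order."""

    thresholds: QCThresholds
    removed: dict = field(default_factory=dict)   # filter name -> list of rsIDs
    n_input: int = 0
    n_output: int = 0

    FILTERS = ("maf", "missing", "hwe", "ld", "quality")

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.removed.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"filter": list(self.removed), "n_removed": [len(v) for v in self.removed.values()]}
        )

    def summary(self) -> str:
        lines = [f"input SNPs: {self.n_input}"]
        for k, v in self.removed.items():
            lines.append(f"removed by {k}: {len(v)}")
        lines.append(f"surviving SNPs: {self.n_output}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# readers / writers


def _finalize_coding(geno_alt: np.ndarray, alleles: list, snp_map: pd.DataFrame):
    """Recode ALT-count columns to minor-allele counts.

    ``geno_alt`` counts the second allele of each pair in ``alleles``
    [(a_ref, a_alt), ...]; the minor allele is the rarer one in the pooled
    sample, ties broken toward the alphabetically first allele.
    """
    g = geno_alt
    called = (g >= 0).sum(axis=0)
    alt_count = np.where(g >= 0, g, 0).sum(axis=0)
    minor = []
    major = []
    flip = np.zeros(g.shape[1], dtype=bool)
    for j, (a_ref, a_alt) in enumerate(alleles):
        freq = alt_count[j] / (2 * called[j]) if called[j] else 0.0
        if freq < 0.5:
            mn, mj = a_alt, a_ref
        elif freq > 0.5:
            mn, mj, flip[j] = a_ref, a_alt, True
        else:  # tie: alphabetically first allele is the minor one
            mn, mj = sorted([a_ref, a_alt])
            flip[j] = mn == a_ref and a_ref != a_alt
        minor.append(mn)
        major.append(mj)
    out = g.copy()
    cols = np.flatnonzero(flip)
    for j in cols:
        miss = g[:, j] < 0
        out[:, j] = 2 - g[:, j]
        out[miss, j] = MISSING
    snp_map = snp_map.copy()
    snp_map["a_minor"] = minor
    snp_map["a_major"] = major
    return out.astype(np.int8), snp_map


def _read_subjects(path) -> pd.DataFrame:
    subj = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "group"}
    if not required.issubset(subj.columns):
        raise ValueError(f"subject table must have columns {sorted(required)}")
    if "sex" not in subj.columns:
        subj["sex"] = "U"
    if "stage" not in subj.columns:
        subj["stage"] = 1
    return subj


def read_plink(ped_path, map_path, subjects_path) -> GenotypeStudy:
    """Read a PLINK text (.ped/.map) study with a subject metadata TSV."""
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "rsid", "cm", "pos"], dtype={"chrom": str, "rsid": str},
    )[["chrom", "pos", "rsid"]]
    n_snps = len(snp_map)
    ids, rows, allele_pairs = [], [], [dict() for _ in range(n_snps)]
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"ped row for {parts[0]}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            rows.append(parts[6:])
    geno = np.full((len(ids), n_snps), MISSING, dtype=np.int16)
    alleles = []
    cols = np.array(rows, dtype="U1") if rows else np.empty((0, 2 * n_snps), dtype="U1")
    for j in range(n_snps):
        a1 = cols[:, 2 * j]
        a2 = cols[:, 2 * j + 1]
        obs = sorted((set(a1) | set(a2)) - {"0"})
        bad = [a for a in obs if a not in "ACGT"]
        if bad:
            raise ValueError(f"unknown alleles {bad} at {snp_map['rsid'][j]}")
        if len(obs) > 2:
            raise ValueError(f"more than two alleles at {snp_map['rsid'][j]}: {obs}")
        if len(obs) == 0:
            obs = ["A"]
        ref = obs[0]
        alt = obs[1] if len(obs) > 1 else obs[0]
        called = (a1 != "0") & (a2 != "0")
        geno[called, j] = (a1[called] == alt).astype(int) + (a2[called] == alt).astype(int)
        if ref == alt:
            geno[called, j] = 0
        alleles.append((ref, alt))
    subjects = _read_subjects(subjects_path)
    return _assemble(geno, alleles, snp_map, subjects, ids)


def read_vcf(vcf_path, subjects_path) -> GenotypeStudy:
    """Read genotypes (GT field only) from a VCF 4.x file."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    ids = list(vcf.samples)
    rows, alleles, recs = [], [], []
    for var in vcf:
        rsid = var.ID
        if rsid is None or rsid == ".":
            rsid = ""
        if len(var.ALT) > 1:
            raise ValueError(f"multiallelic site at {var.CHROM}:{var.POS}")
        alt = var.ALT[0] if var.ALT else var.REF
        recs.append((str(var.CHROM), var.POS, rsid))
        alleles.append((var.REF, alt))
        gts = var.genotype.array()
        g = gts[:, 0] + gts[:, 1]
        g[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = MISSING
        rows.append(g)
    snp_map = pd.DataFrame(recs, columns=["chrom", "pos", "rsid"])
    geno = np.array(rows, dtype=np.int16).T if rows else np.empty((len(ids), 0), np.int16)
    subjects = _read_subjects(subjects_path)
    return _assemble(geno, alleles, snp_map, subjects, ids)


def _assemble(geno, alleles, snp_map, subjects, sample_ids) -> GenotypeStudy:
    # align subjects to genotype sample order
    order = {sid: k for k, sid in enumerate(sample_ids)}
    missing_ids = [sid for sid in subjects["id"] if sid not in order]
    extra = [sid for sid in sample_ids if sid not in set(subjects["id"])]
    if missing_ids or extra:
        raise ValueError(
            f"subject mismatch: absent from genotypes {missing_ids[:5]}, "
            f"absent from metadata {extra[:5]}"
        )
    subjects = subjects.iloc[np.argsort([order[s] for s in subjects["id"]])]
    # drop SNPs without an rsID, keep count
    has_rsid = snp_map["rsid"].astype(str).str.len() > 0
    n_dropped = int((~has_rsid).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} SNPs without an rsID")
        keep = np.flatnonzero(has_rsid.to_numpy())
        geno = geno[:, keep]
        alleles = [alleles[j] for j in keep]
        snp_map = snp_map.iloc[keep]
    # sort by position within chromosomes, chromosomes in order of appearance
    snp_map = snp_map.reset_index(drop=True)
    chrom_rank = {c: k for k, c in enumerate(snp_map["chrom"].unique())}
    key = np.lexsort((snp_map["pos"].to_numpy(),
                      snp_map["chrom"].map(chrom_rank).to_numpy()))
    geno, snp_map = geno[:, key], snp_map.iloc[key]
    geno, snp_map = _finalize_coding(geno, [alleles[j] for j in key], snp_map)
    return GenotypeStudy(genotypes=geno, snp_map=snp_map, subjects=subjects)


def read_genotypes(path, fmt: str, subjects_path, map_path=None) -> GenotypeStudy:
    """Dispatching reader; ``fmt`` is 'plink-text' or 'vcf'."""
    if fmt == "plink-text":
        p = str(path)
        ped = p if p.endswith(".ped") else p + ".ped"
        mp = map_path or ped[: -len(".ped")] + ".map"
        return read_plink(ped, mp, subjects_path)
    if fmt == "vcf":
        return read_vcf(path, subjects_path)
    raise ValueError(f"unknown format {fmt!r}")


def write_plink(study: GenotypeStudy, prefix) -> None:
    """Write the study as PLINK text (.ped/.map) plus a subject TSV."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for _, r in study.snp_map.iterrows():
            fh.write(f"{r['chrom']}\t{r['rsid']}\t0\t{r['pos']}\n")
    sex_code = {"M": "1", "F": "2"}
    with open(prefix + ".ped", "w") as fh:
        for i, (_, subj) in enumerate(study.subjects.iterrows()):
            fields = [str(subj["id"]), str(subj["id"]), "0", "0",
                      sex_code.get(subj.get("sex", "U"), "0"), "0"]
            row = study.genotypes[i]
            for j, g in enumerate(row):
                mn = study.snp_map["a_minor"].iloc[j]
                mj = study.snp_map["a_major"].iloc[j]
                if g < 0:
                    fields += ["0", "0"]
                else:
                    fields += [mn] * int(g) + [mj] * (2 - int(g))
            fh.write(" ".join(fields) + "\n")
    study.subjects.to_csv(prefix + ".subjects.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC statistics


def test_hwe_het_deficit(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-sided exact Hardy-Weinberg p-value for heterozygote deficit.

    Levene-Haldane conditional distribution: given the allele counts, the
    probability of observing at most the given number of heterozygotes.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    m = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    hs = np.arange(m % 2, m + 1, 2)
    hs = hs[(m - hs) // 2 + hs <= n]  # minor-homozygote count must fit
    # log P(h) ~ multinomial(n; nAA, h, naa) * 2^h / C(2n, m)
    n_min_hom = (m - hs) // 2
    n_maj_hom = n - n_min_hom - hs
    logp = (
        gammaln(n + 1)
        - gammaln(n_min_hom + 1)
        - gammaln(hs + 1)
        - gammaln(n_maj_hom + 1)
        + hs * np.log(2.0)
    )
    logp -= logsumexp(logp)
    return float(np.exp(logsumexp(logp[hs <= n_Aa])))


def hwe_deviation_z(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Signed z for departure from HWE proportions (negative = het deficit)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 0.0
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(np.sign(n_Aa - exp[1]) * np.sqrt(chi2))


def neighbor_r2(study: GenotypeStudy, window: int = 1) -> pd.DataFrame:
    """Squared Pearson correlation of adjacent SNP pairs within chromosomes.

    Computed on pairwise-complete subjects; undefined (monomorphic) pairs
    reported as NaN.  ``window`` > 1 extends the comparison to all pairs
    at most ``window`` SNPs apart.
    """
    rows = []
    g = study.genotypes.astype(np.float64)
    g[study.genotypes < 0] = np.nan
    for chrom in study.chromosomes():
        idx = study.snp_indices(chrom)
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1 : a_pos + 1 + window]:
                both = ~np.isnan(g[:, a]) & ~np.isnan(g[:, b])
                if both.sum() < 2:
                    r2 = np.nan
                else:
                    xa, xb = g[both, a], g[both, b]
                    if xa.std() == 0 or xb.std() == 0:
                        r2 = np.nan
                    else:
                        r2 = float(np.corrcoef(xa, xb)[0, 1] ** 2)
                rows.append((chrom, study.snp_map["rsid"].iloc[a],
                             study.snp_map["rsid"].iloc[b], r2))
    return pd.DataFrame(rows, columns=["chrom", "rsid_a", "rsid_b", "r2"])


def quality_mu_score(study: GenotypeStudy, components=("call_rate", "mac", "hwe_z")) -> np.ndarray:
    """Per-SNP data-quality mu-score (higher = better).

    Each SNP is described by a quality vector -- call rate, minor-allele
    count and -|HWE deviation z| by default -- and scored by the same
    partial-order comparison used for diplotypes, here across SNPs.
    """
    counts = study.genotype_counts()
    cols = []
    for comp in components:
        if comp == "call_rate":
            cols.append(1.0 - study.missing_rate())
        elif comp == "mac":
            mac = np.minimum(counts[:, 1] + 2 * counts[:, 2],
                             counts[:, 1] + 2 * counts[:, 0])
            cols.append(mac.astype(float))
        elif comp == "hwe_z":
            cols.append(np.array([
                -abs(hwe_deviation_z(*c)) for c in counts
            ]))
        else:
            raise ValueError(f"unknown quality component {comp!r}")
    quality = np.column_stack(cols)
    return mucore.mu_scores(quality).scores


def apply_qc(study: GenotypeStudy, thresholds: QCThresholds | None = None):
    """Apply the five SNP filters in order; returns (study, QCReport).

    Order: MAF < maf, missingness > missing, one-sided HWE het-deficit
    p < hwe, adjacent-pair LD r^2 > ld (the later SNP of the pair is
    removed), data-quality mu-score in the bottom decile.  Surviving SNPs
    keep their original order.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(thresholds=thr, n_input=study.n_snps)

    def drop(mask: np.ndarray, name: str, st: GenotypeStudy) -> GenotypeStudy:
        removed = st.snp_map["rsid"].to_numpy()[mask]
        report.removed[name] = list(removed)
        return st.subset_snps(np.flatnonzero(~mask))

    st = study
    maf = st.maf()
    st = drop(np.nan_to_num(maf, nan=0.0) < thr.maf, "maf", st)
    st = drop(st.missing_rate() > thr.missing, "missing", st)
    hwe_p = np.array([test_hwe_het_deficit(c[0], c[1], c[2])
                      for c in st.genotype_counts()])
    st = drop(hwe_p < thr.hwe, "hwe", st)

    # LD sweep: compare each SNP to its nearest surviving left neighbour
    g = st.genotypes.astype(np.float64)
    g[st.genotypes < 0] = np.nan
    ld_remove = np.zeros(st.n_snps, dtype=bool)
    for chrom in st.chromosomes():
        idx = st.snp_indices(chrom)
        last_kept = None
        for j in idx:
            if last_kept is None:
                last_kept = j
                continue
            both = ~np.isnan(g[:, last_kept]) & ~np.isnan(g[:, j])
            r2 = np.nan
            if both.sum() >= 2:
                xa, xb = g[both, last_kept], g[both, j]
                if xa.std() > 0 and xb.std() > 0:
                    r2 = np.corrcoef(xa, xb)[0, 1] ** 2
            if np.isfinite(r2) and r2 > thr.ld:
                ld_remove[j] = True
            else:
                last_kept = j
    st = drop(ld_remove, "ld", st)

    if st.n_snps > 1 and thr.quality_decile > 0:
        scores = quality_mu_score(st)
        k = int(thr.quality_decile * st.n_snps)
        if k > 0:
            # remove the bottom decile; boundary ties are kept
            cut = np.sort(scores)[k]
            st = drop(scores < cut, "quality", st)
        else:
            report.removed["quality"] = []
    else:
        report.removed["quality"] = []

    report.n_output = st.n_snps
    if st.n_snps == 0:
        warnings.warn("no SNPs survived QC")
    return st, report
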