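import numpy as np
import pandas as pd
import pytest

from mugwas.io_qc import GenotypeStudy


def make_study(geno, chrom=None, groups=None, sex=None, stage=None, pos=None):
    """Assemble a GenotypeStudy from a raw genotype matrix for tests."""
    geno = np.asarray(geno, dtype=np.int8)
    n, s = geno.shape
    chrom = ["1"] * s if chrom is None else list(chrom)
    pos = [(j + 1) * 1000 for j in range(s)] if pos is None else list(pos)
    snp_map = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "rsid": [f"rs{j + 1}" for j in range(s)],
        "a_minor": ["A"] * s,
        "a_major": ["G"] * s,
    })
    subjects = pd.DataFrame({
        "id": [f"S{i}" for i in range(n)],
        "group": ["case-severe" if i < n // 2 else "case-mild" for i in range(n)]
        if groups is None else list(groups),
        "sex": ["M"] * n if sex is None else list(sex),
        "stage": [1] * n if stage is None else list(stage),
    })
    return GenotypeStudy(genotypes=geno, snp_map=snp_map, subjects=subjects)


def brute_force_mu_scores(window):
    """O(n^2) definition of mu-scores: the oracle all fast paths must match."""
    window = np.asarray(window)
    if window.ndim == 1:
        window = window[:, None]
    n = window.shape[0]
    scores = np.zeros(n, dtype=np.int64)
    ordered = 0
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = window[i], window[j]
            shared = (vi >= 0) & (vj >= 0)
            if not shared.any():
                continue
            a, b = vi[shared], vj[shared]
            if np.all(a >= b) and np.any(a > b):
                scores[i] += 1
                scores[j] -= 1
                ordered += 1
            elif np.all(b >= a) and np.any(b > a):
                scores[j] += 1
                scores[i] -= 1
                ordered += 1
    total = n * (n - 1) // 2
    return scores, ordered / total, ordered, total


@pytest.fixture(scope="session")
def small_synth_study():
    """A small null synthetic study shared across tests."""
    from mugwas.synthdata import SynthConfig, generate_study

    cfg = SynthConfig(n_subjects_per_group=120, n_chromosomes=3,
                      snps_per_chromosome=20, missing_rate=0.02, seed=11)
    study, truth = generate_study(cfg)
    return cfg, study, truth
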