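"""Shared fixtures: deterministic synthetic loci and truth templates."""

from __future__ import annotations

import numpy as np
import pytest

from asmkit.locus import DiploidLocus, MethylationTruth, ReadSimConfig


def make_random_locus(
    rng: np.random.Generator,
    length: int = 240,
    n_cpgs: int = 12,
    snp_alleles: tuple = ("G", "T"),
    guide_interval=None,
) -> DiploidLocus:
    """Random amplicon with evenly spaced forced CpGs and a central SNP.

    The SNP neighbourhood is scrubbed so the SNP never sits inside a CpG and
    the two allele sequences stay CpG-identical.
    """
    seq = list(rng.choice(list("ACGT"), size=length))
    snp_pos = length // 2
    step = max((length - 30) // n_cpgs, 4)
    for p in range(10, length - 12, step):
        if abs(p - snp_pos) > 2:
            seq[p], seq[p + 1] = "C", "G"
    ref, alt = snp_alleles
    seq[snp_pos] = ref
    # avoid bisulfite-ambiguous or CpG-forming SNP context
    if seq[snp_pos - 1] == "C":
        seq[snp_pos - 1] = "A"
    if seq[snp_pos + 1] in "G":
        seq[snp_pos + 1] = "T"
    return DiploidLocus.from_sequence(
        "synthetic", "".join(seq), snp_pos, alt, guide_interval=guide_interval
    )


def uniform_truth(
    locus: DiploidLocus,
    untransfected: float = 0.0,
    scrambled: float = 0.06,
    guide_on: float = 0.60,
    guide_off: float = 0.06,
    on_allele: str = "allele1",
    footprint_attenuation: float | None = None,
) -> MethylationTruth:
    """Flat per-CpG truth with stated condition/allele probabilities."""
    n = len(locus.cpg_positions)
    off_allele = "allele2" if on_allele == "allele1" else "allele1"
    on = np.full(n, guide_on)
    if footprint_attenuation is not None and locus.guide_interval is not None:
        s, e = locus.guide_interval
        for i, p in enumerate(locus.cpg_positions):
            if s <= p < e:
                on[i] *= footprint_attenuation
    return MethylationTruth(
        probabilities={
            ("untransfected", "allele1"): np.full(n, untransfected),
            ("untransfected", "allele2"): np.full(n, untransfected),
            ("scrambled", "allele1"): np.full(n, scrambled),
            ("scrambled", "allele2"): np.full(n, scrambled),
            ("guide", on_allele): on,
            ("guide", off_allele): np.full(n, guide_off),
        },
        footprint_interval=locus.guide_interval,
        background_rate=scrambled,
    )


@pytest.fixture
def toy_locus() -> DiploidLocus:
    """Small handcrafted amplicon: 4 CpGs, G/T SNP at offset 30, plus
    non-CpG C/G bases on both strands so conversion marks the strand."""
    #          0         1         2         3         4         5
    #          0123456789012345678901234567890123456789012345678901234567
    sequence = "ATTACGATTTACGATCAAATGTAAATTATAGATTTACGTATTCTAGATTACGATTAAT"
    return DiploidLocus.from_sequence("toy", sequence, 30, "T")


@pytest.fixture
def random_locus() -> DiploidLocus:
    return make_random_locus(np.random.default_rng(11), guide_interval=(100, 123))


@pytest.fixture
def fast_cfg() -> ReadSimConfig:
    """Error-free, fully converting simulation settings."""
    return ReadSimConfig(
        depth=200,
        conversion_rate=1.0,
        methylated_protection=1.0,
        seq_error_rate=0.0,
        rng_seed=5,
    )
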