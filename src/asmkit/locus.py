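"""Diploid locus model shared by every stage of the pipeline.

A :class:`DiploidLocus` describes one PCR amplicon over a region carrying a
single heterozygous SNP: the reference (allele-1) sequence, the SNP position
and both allele bases, the CpG cytosine positions used for methylation
calling, and optionally the sgRNA binding interval.  All coordinates are
0-based offsets into ``sequence``; reports convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Tuple

import numpy as np

DNA_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")

#: Experimental conditions modelled throughout the package.
CONDITIONS = ("untransfected", "scrambled", "guide")
#: Allele labels. ``allele1`` always refers to the base stored in
#: ``DiploidLocus.allele1_base`` (the reference amplicon sequence).
ALLELES = ("allele1", "allele2")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC subset)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def find_cpg_positions(seq: str) -> Tuple[int, ...]:
    """0-based offsets of every CpG cytosine in ``seq``."""
    return tuple(i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")


@dataclass(frozen=True)
class DiploidLocus:
    """One heterozygous amplicon locus.

    Parameters
    ----------
    name:
        Locus identifier (e.g. gene symbol plus experiment label).
    sequence:
        Uppercase DNA of the allele-1 (reference) amplicon, top strand.
    snp_pos:
        0-based offset of the heterozygous SNP in ``sequence``.
    allele1_base, allele2_base:
        The two allele bases at ``snp_pos``; ``sequence[snp_pos]`` must equal
        ``allele1_base``.
    cpg_positions:
        Ascending 0-based offsets of CpG cytosines (top strand).
    guide_interval:
        Optional half-open ``[start, end)`` sgRNA binding site.
    control:
        Marks a no-guide control amplicon (off-target locus control).
    """

    name: str
    sequence: str
    snp_pos: int
    allele1_base: str
    allele2_base: str
    cpg_positions: Tuple[int, ...] = field(default=())
    guide_interval: Optional[Tuple[int, int]] = None
    control: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        if self.allele1_base == self.allele2_base:
            raise ValueError(
                f"{self.name}: SNP alleles must differ "
                f"({self.allele1_base}/{self.allele2_base})"
            )
        if not (0 <= self.snp_pos < len(seq)):
            raise ValueError(f"{self.name}: snp_pos {self.snp_pos} outside sequence")
        if seq[self.snp_pos] != self.allele1_base:
            raise ValueError(
                f"{self.name}: sequence[{self.snp_pos}]={seq[self.snp_pos]!r} "
                f"does not match allele1_base {self.allele1_base!r}"
            )
        for p in self.cpg_positions:
            if seq[p : p + 2] != "CG":
                raise ValueError(f"{self.name}: position {p} is not a CpG cytosine")
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValueError(f"{self.name}: cpg_positions must be ascending and unique")
        if self.guide_interval is not None:
            s, e = self.guide_interval
            if not (0 <= s < e <= len(seq)):
                raise ValueError(f"{self.name}: guide_interval {self.guide_interval} outside sequence")

    @classmethod
    def from_sequence(
        cls,
        name: str,
        sequence: str,
        snp_pos: int,
        allele2_base: str,
        guide_interval: Optional[Tuple[int, int]] = None,
        control: bool = False,
    ) -> "DiploidLocus":
        """Build a locus, taking allele 1 from the sequence and auto-detecting
        CpG sites on the allele-1 top strand."""
        sequence = sequence.upper()
        return cls(
            name=name,
            sequence=sequence,
            snp_pos=snp_pos,
            allele1_base=sequence[snp_pos],
            allele2_base=allele2_base.upper(),
            cpg_positions=find_cpg_positions(sequence),
            guide_interval=guide_interval,
            control=control,
        )

    def allele_base(self, allele: str) -> str:
        if allele == "allele1":
            return self.allele1_base
        if allele == "allele2":
            return self.allele2_base
        raise KeyError(allele)

    def allele_sequence(self, allele: str) -> str:
        """Top-strand sequence of the given allele."""
        base = self.allele_base(allele)
        s = self.sequence
        return s[: self.snp_pos] + base + s[self.snp_pos + 1 :]

    def swapped_alleles(self) -> "DiploidLocus":
        """The same locus with allele labels exchanged (allele-2 sequence
        becomes the reference)."""
        seq2 = self.allele_sequence("allele2")
        return replace(
            self,
            sequence=seq2,
            allele1_base=self.allele2_base,
            allele2_base=self.allele1_base,
            cpg_positions=tuple(
                p for p in self.cpg_positions if seq2[p : p + 2] == "CG"
            ),
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MethylationTruth:
    """Ground-truth per-CpG methylation probabilities for a simulation.

    ``probabilities`` maps ``(condition, allele)`` to an array of per-CpG
    Bernoulli probabilities aligned with ``DiploidLocus.cpg_positions``.
    ``footprint_interval`` records where on-allele probabilities were
    attenuated (the dCas9 binding footprint); ``background_rate`` is the
    untargeted methyltransferase activity added to every allele in
    transfected conditions.
    """

    probabilities: Mapping[Tuple[str, str], np.ndarray]
    footprint_interval: Optional[Tuple[int, int]] = None
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            key: np.asarray(val, dtype=float)
            for key, val in dict(self.probabilities).items()
        }
        for key, arr in probs.items():
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"methylation probabilities outside [0, 1] for {key}")
        object.__setattr__(self, "probabilities", probs)
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValueError("background_rate outside [0, 1]")

    def prob(self, condition: str, allele: str) -> np.ndarray:
        return self.probabilities[(condition, allele)]

    @property
    def conditions(self) -> Tuple[str, ...]:
        return tuple(dict.fromkeys(c for c, _ in self.probabilities))


def default_truth(
    locus: DiploidLocus,
    on_allele: str = "allele1",
    baseline: float = 0.02,
    background_rate: float = 0.07,
    on_gain: float = 0.65,
    footprint_attenuation: float = 0.2,
) -> MethylationTruth:
    """Truth template mirroring a typical editing experiment at a
    pre-selected unmethylated promoter CGI.

    Untransfected cells carry near-zero methylation (``baseline``); the
    scrambled-guide control adds only the untargeted background; the specific
    guide adds a large gain on the on-target allele with a dip inside the
    sgRNA binding site (footprint), while the off-target allele receives
    background only.
    """
    n = len(locus.cpg_positions)
    if not 0.0 <= footprint_attenuation <= 1.0:
        raise ValueError("footprint_attenuation outside [0, 1]")
    base = np.full(n, baseline)
    bg = np.clip(base + background_rate, 0, 1)
    on = np.clip(base + background_rate + on_gain, 0, 1)
    if locus.guide_interval is not None:
        s, e = locus.guide_interval
        inside = [i for i, p in enumerate(locus.cpg_positions) if s <= p < e]
        on = on.copy()
        # footprint only ever reduces delivered methylation
        on[inside] = base[inside] + (on[inside] - base[inside]) * footprint_attenuation
    off_allele = "allele2" if on_allele == "allele1" else "allele1"
    probs = {
        ("untransfected", "allele1"): base,
        ("untransfected", "allele2"): base,
        ("scrambled", "allele1"): bg,
        ("scrambled", "allele2"): bg,
        ("guide", on_allele): on,
        ("guide", off_allele): bg,
    }
    return MethylationTruth(
        probabilities=probs,
        footprint_interval=locus.guide_interval,
        background_rate=background_rate,
    )


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation settings for bisulfite amplicon libraries.

    read_length
        Length of each mate in nt; ``None`` emits one full-amplicon read per
        fragment (the merged-read equivalent of overlapping paired ends).
    paired
        Emit R1/R2 mate pairs from opposite fragment ends instead.
    depth
        Reads (or read pairs) per allele per condition.
    conversion_rate
        Probability that an unmethylated cytosine is read as T after
        bisulfite treatment.
    methylated_protection
        Probability that a methylated CpG cytosine resists conversion.
    seq_error_rate
        Per-base substitution probability applied after conversion.
    strand_mix
        Fraction of reads drawn from the original top (OT) strand; amplicon
        primers normally fix this at 1.0.
    """

    read_length: Optional[int] = None
    paired: bool = False
    depth: int = 1000
    conversion_rate: float = 0.995
    methylated_protection: float = 0.99
    seq_error_rate: float = 0.001
    strand_mix: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "methylated_protection", "seq_error_rate", "strand_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.paired and self.read_length is None:
            raise ValueError("paired mode requires read_length")
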