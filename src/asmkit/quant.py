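"""Bisulfite amplicon read processing: merge, align, split by allele, call.

This reimplements, at amplicon scale, the standard trim/merge/map/call chain
(PEAR + bwameth + MethylDackel) with explicit allele splitting.  Alignment is
ungapped (amplicons are fixed PCR products) and bisulfite-aware: reads are
compared to the reference in converted space (C->T for original-top-strand
reads, G->A for original-bottom-strand reads) at every offset, and the best
strand/orientation/offset wins.  The SNP base is excluded from mismatch
counting so that allele-2 reads are not penalised against the allele-1
reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .locus import DiploidLocus, revcomp

UNASSIGNABLE = "unassignable"


def _ct(seq: str) -> str:
    return seq.replace("C", "T")


def _ga(seq: str) -> str:
    return seq.replace("G", "A")


def _arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon with precomputed bisulfite-converted versions."""

    locus: DiploidLocus
    top_ct: str = ""
    bottom_ga: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "top_ct", _ct(self.locus.sequence))
        object.__setattr__(self, "bottom_ga", _ga(self.locus.sequence))

    def __len__(self) -> int:
        return len(self.locus.sequence)


@dataclass(frozen=True)
class AlignedRead:
    """An accepted ungapped alignment in top-strand reference coordinates.

    ``sequence`` holds the read's original bases, already oriented to the top
    strand of the reference (OB reads are stored reverse-complement-free: the
    raw read is reverse complemented when its reverse orientation aligned).
    """

    read_id: str
    offset: int
    strand: str  # OT / OB
    mismatches: int
    sequence: str

    def base_at(self, ref_pos: int) -> Optional[str]:
        i = ref_pos - self.offset
        if 0 <= i < len(self.sequence):
            return self.sequence[i]
        return None


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # "unmapped" | "ambiguous" | "unmerged" | "empty"


@dataclass
class MethylationProfile:
    """Per-CpG methylation counts and levels for one read subset.

    ``levels`` is NaN where coverage is below ``coverage_floor`` (a missing
    level is never reported as 0).
    """

    allele: str
    cpg_positions: Tuple[int, ...]
    meth: np.ndarray
    unmeth: np.ndarray
    n_reads: int = 0
    non_cpg_retention: Optional[float] = None
    coverage_floor: int = 10

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def levels(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(cov >= max(self.coverage_floor, 1), self.meth / cov, np.nan)
        return lv

    def mean_level(self, indices: Optional[Sequence[int]] = None) -> float:
        lv = self.levels if indices is None else self.levels[list(indices)]
        if np.all(np.isnan(lv)):
            return float("nan")
        return float(np.nanmean(lv))

    def to_frame(self, locus_name: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": locus_name,
                "allele": self.allele,
                "cpg_index": np.arange(len(self.cpg_positions)),
                "ref_pos_1based": np.asarray(self.cpg_positions) + 1,
                "meth": self.meth,
                "unmeth": self.unmeth,
                "level": self.levels,
            }
        )


@dataclass(frozen=True)
class MergeResult:
    sequence: str
    quality: str
    overlap: int
    mismatches: int


def merge_pairs(
    r1: str,
    r2: str,
    q1: Optional[str] = None,
    q2: Optional[str] = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[MergeResult]:
    """Merge a mate pair into one fragment, or return ``None`` on failure.

    ``r2`` is given 5'->3' on the opposite strand and is reverse complemented
    before the overlap search.  The overlap with the lowest mismatch fraction
    (ties: longest) wins; base disagreements resolve to the higher-quality
    mate.
    """
    if not r1 or not r2:
        return None
    if q1 is None:
        q1 = "I" * len(r1)
    if q2 is None:
        q2 = "I" * len(r2)
    r2rc = revcomp(r2)
    q2r = q2[::-1]
    best: Optional[Tuple[float, int, int]] = None  # (frac, -overlap, mismatches)
    for o in range(min_overlap, min(len(r1), len(r2rc)) + 1):
        a, b = r1[-o:], r2rc[:o]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        frac = mm / o
        if frac <= max_mismatch_frac:
            cand = (frac, -o, mm)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    frac, neg_o, mm = best
    o = -neg_o
    head = r1[:-o] if o < len(r1) else ""
    qhead = q1[:-o] if o < len(r1) else ""
    mid = []
    qmid = []
    for i in range(o):
        b1, b2 = r1[len(r1) - o + i], r2rc[i]
        c1, c2 = q1[len(r1) - o + i], q2r[i]
        if b1 == b2 or c1 >= c2:
            mid.append(b1)
            qmid.append(c1)
        else:
            mid.append(b2)
            qmid.append(c2)
    return MergeResult(
        sequence=head + "".join(mid) + r2rc[o:],
        quality=qhead + "".join(qmid) + q2r[o:],
        overlap=o,
        mismatches=mm,
    )


def _best_offset(
    read_conv: np.ndarray, ref_conv: np.ndarray, skip: Optional[int]
) -> Tuple[int, int]:
    """Best ungapped offset of ``read_conv`` on ``ref_conv`` by mismatch
    count, excluding reference position ``skip`` from counting."""
    n, m = len(ref_conv), len(read_conv)
    best_off, best_mm = -1, m + 1
    for off in range(n - m + 1):
        window = ref_conv[off : off + m]
        mm = int(np.count_nonzero(window != read_conv))
        if skip is not None and off <= skip < off + m:
            if window[skip - off] != read_conv[skip - off]:
                mm -= 1
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm


def align_to_amplicon(
    read: str,
    ref: AmpliconRef,
    read_id: str = "",
    max_mismatch_frac: float = 0.1,
) -> AlignedRead | Rejection:
    """Bisulfite-aware ungapped alignment of one read to the amplicon.

    Both orientations are tried against both converted spaces (read C->T vs
    top-converted reference for OT; read G->A vs bottom-converted reference
    for OB).  A tie in converted-space mismatches between the two strand
    calls is rejected as ``ambiguous``; a best hit above the mismatch
    threshold is ``unmapped``.
    """
    read = read.upper()
    if not read:
        return Rejection(read_id, "empty")
    if len(read) > len(ref):
        return Rejection(read_id, "unmapped")
    snp = ref.locus.snp_pos
    ref_ct = _arr(ref.top_ct)
    ref_ga = _arr(ref.bottom_ga)
    hits = []  # (mm, strand, offset, oriented_seq)
    for oriented in (read, revcomp(read)):
        for strand, rconv, refconv in (
            ("OT", _ct(oriented), ref_ct),
            ("OB", _ga(oriented), ref_ga),
        ):
            off, mm = _best_offset(_arr(rconv), refconv, snp)
            hits.append((mm, strand, off, oriented))
    hits.sort(key=lambda h: h[0])
    mm, strand, off, oriented = hits[0]
    denom = max(len(read) - 1, 1)  # SNP base excluded from the count
    if mm / denom > max_mismatch_frac:
        return Rejection(read_id, "unmapped")
    runner = hits[1]
    if runner[0] == mm and runner[1] != strand:
        return Rejection(read_id, "ambiguous")
    return AlignedRead(read_id=read_id, offset=off, strand=strand, mismatches=mm, sequence=oriented)


def assign_allele(aln: AlignedRead, locus: DiploidLocus) -> str:
    """Assign an aligned read to an allele via the SNP base, bisulfite-aware.

    Each allele base expands to its possible bisulfite observations on the
    read's strand (OT: C -> {C,T}; OB: G -> {G,A}; other bases map to
    themselves); the read is assigned iff its observed SNP base is compatible
    with exactly one allele.
    """
    obs = aln.base_at(locus.snp_pos)
    if obs is None:
        return UNASSIGNABLE
    compatible = []
    for allele in ("allele1", "allele2"):
        base = locus.allele_base(allele)
        if aln.strand == "OT":
            expected = {"C", "T"} if base == "C" else {base}
        else:
            expected = {"G", "A"} if base == "G" else {base}
        if obs in expected:
            compatible.append(allele)
    if len(compatible) == 1:
        return compatible[0]
    return UNASSIGNABLE


def call_methylation(
    assignments: Iterable[Tuple[AlignedRead, str]],
    ref: AmpliconRef,
    coverage_floor: int = 10,
) -> Dict[str, MethylationProfile]:
    """Per-CpG methylation profiles for allele1, allele2 and all reads.

    OT reads report C (methylated) / T (unmethylated) at the CpG cytosine;
    OB reads report G / A at the CpG guanine.  Cytosines outside CpG context
    estimate the bisulfite conversion failure rate (QC).
    """
    locus = ref.locus
    cpgs = locus.cpg_positions
    cpg_set = set(cpgs)
    groups = {"allele1": [], "allele2": [], "all": []}
    for aln, allele in assignments:
        groups["all"].append(aln)
        if allele in ("allele1", "allele2"):
            groups[allele].append(aln)

    seq = locus.sequence
    non_cpg_c = [i for i, b in enumerate(seq) if b == "C" and i not in cpg_set and i != locus.snp_pos]
    non_cpg_g = [
        i
        for i, b in enumerate(seq)
        if b == "G" and (i - 1) not in cpg_set and i != locus.snp_pos
    ]

    out: Dict[str, MethylationProfile] = {}
    for label, alns in groups.items():
        meth = np.zeros(len(cpgs), dtype=int)
        unmeth = np.zeros(len(cpgs), dtype=int)
        retained = converted = 0
        for aln in alns:
            if aln.strand == "OT":
                for j, p in enumerate(cpgs):
                    b = aln.base_at(p)
                    if b == "C":
                        meth[j] += 1
                    elif b == "T":
                        unmeth[j] += 1
                for p in non_cpg_c:
                    b = aln.base_at(p)
                    if b == "C":
                        retained += 1
                    elif b == "T":
                        converted += 1
            else:
                for j, p in enumerate(cpgs):
                    b = aln.base_at(p + 1)
                    if b == "G":
                        meth[j] += 1
                    elif b == "A":
                        unmeth[j] += 1
                for p in non_cpg_g:
                    b = aln.base_at(p)
                    if b == "G":
                        retained += 1
                    elif b == "A":
                        converted += 1
        qc = retained / (retained + converted) if (retained + converted) else None
        if label != "all" and not alns:
            warnings.warn(f"no reads assigned to {label}", stacklevel=2)
        out[label] = MethylationProfile(
            allele=label,
            cpg_positions=cpgs,
            meth=meth,
            unmeth=unmeth,
            n_reads=len(alns),
            non_cpg_retention=qc,
            coverage_floor=coverage_floor,
        )
    return out


@dataclass
class QuantResult:
    """Per-condition quantification output with read accounting."""

    profiles: Dict[str, MethylationProfile]
    counts: Dict[str, int]  # input / merged / mapped / assigned_* / unassignable / rejected

    def conservation_holds(self) -> bool:
        c = self.counts
        return (
            c["assigned_allele1"] + c["assigned_allele2"] + c["unassignable"] + c["rejected"]
            == c["input"]
        )


def quantify_reads(
    reads: Iterable,
    locus: DiploidLocus,
    max_mismatch_frac: float = 0.1,
    min_overlap: int = 10,
    coverage_floor: int = 10,
) -> QuantResult:
    """End-to-end quantification of one sample's reads for one locus.

    ``reads`` may be plain sequences, ``(id, seq)`` tuples, ``(id, r1, r2)``
    mate pairs, or :class:`~asmkit.simulate.SimRead` objects.  Pairs are
    merged first; merge failures fall back to mapping read 1 alone.
    """
    ref = AmpliconRef(locus)
    assignments: List[Tuple[AlignedRead, str]] = []
    counts = {
        "input": 0,
        "merged": 0,
        "mapped": 0,
        "assigned_allele1": 0,
        "assigned_allele2": 0,
        "unassignable": 0,
        "rejected": 0,
    }
    for item in reads:
        counts["input"] += 1
        if hasattr(item, "sequence"):
            rid = item.read_id
            seq, mate2 = item.sequence, getattr(item, "mate2", None)
        elif isinstance(item, str):
            rid, seq, mate2 = f"read{counts['input']}", item, None
        elif len(item) == 3:
            rid, seq, mate2 = item
        else:
            rid, seq = item
            mate2 = None
        if mate2 is not None:
            merged = merge_pairs(seq, mate2, min_overlap=min_overlap)
            if merged is not None:
                seq = merged.sequence
                counts["merged"] += 1
        result = align_to_amplicon(seq, ref, read_id=rid, max_mismatch_frac=max_mismatch_frac)
        if isinstance(result, Rejection):
            counts["rejected"] += 1
            continue
        counts["mapped"] += 1
        allele = assign_allele(result, locus)
        if allele == UNASSIGNABLE:
            counts["unassignable"] += 1
        else:
            counts[f"assigned_{allele}"] += 1
        assignments.append((result, allele))  # "all" profile includes unassignable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = call_methylation(assignments, ref, coverage_floor=coverage_floor)
    return QuantResult(profiles=profiles, counts=counts)
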