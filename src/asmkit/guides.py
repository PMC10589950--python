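"""Allele-discriminating sgRNA design around a heterozygous SNP.

dCas9 requires an NGG PAM 3' of a 20-nt protospacer, and its binding is most
sensitive to mismatches in the PAM-proximal "seed" of the protospacer.  A
heterozygous SNP therefore allows allele-selective binding in two ways:

* **PAM placement** — the SNP sits at PAM position 2 or 3 (the two G's;
  numbering N=1, G=2, G=3).  Only the G-carrying allele has a PAM, so exactly
  one guide can be designed and the non-G allele cannot be targeted.
* **Seed placement** — the SNP sits within ``seed_length`` (default 7) nt of
  the protospacer 3' end, with the PAM intact on both alleles.  One guide per
  allele can be designed, each matching one allele.

Candidates are annotated, never filtered, with efficiency/specificity risk
features: multiple PAMs inside the protospacer, and G-quadruplex-forming
(QGRS) motifs on either strand of the binding site.  G>Y PAM changes
(Y = C/T on the PAM strand) are flagged as preferred, since they discriminate
dCas9 binding better than G>R changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .locus import DiploidLocus, revcomp

PROTOSPACER_LEN = 20
DEFAULT_SEED_LENGTH = 7
#: local context pulled around a SNP for genome-wide guide enumeration:
#: 20-nt protospacer + 3-nt PAM + margin on each side.
SNP_CONTEXT = 30


@dataclass(frozen=True)
class PamSite:
    """One NGG PAM occurrence.

    ``pam_start`` is the top-strand 0-based offset of the PAM 'N' base; on the
    minus strand the motif runs right-to-left, so positions 2 and 3 map to
    ``pam_start - 1`` and ``pam_start - 2`` in top-strand coordinates.
    """

    strand: str
    pam_start: int
    pam_bases: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.pam_bases[1:3] != "GG":
            raise ValueError(f"PAM {self.pam_bases!r} is not NGG")

    def position_coord(self, pam_position: int) -> int:
        """Top-strand coordinate of PAM position 1, 2 or 3."""
        step = 1 if self.strand == "+" else -1
        return self.pam_start + step * (pam_position - 1)

    @property
    def span(self) -> Tuple[int, int]:
        """Half-open top-strand interval covered by the PAM triplet."""
        if self.strand == "+":
            return (self.pam_start, self.pam_start + 3)
        return (self.pam_start - 2, self.pam_start + 1)


@dataclass(frozen=True)
class QgrsMotif:
    """A putative G-quadruplex: four equal-length G-runs within a window."""

    start: int
    end: int
    g_run_length: int
    loop_lengths: Tuple[int, int, int]
    g_score: int

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GuideCandidate:
    """An allele-discriminating sgRNA candidate.

    ``protospacer`` is given 5'->3' on the guide strand (its last base is
    PAM-proximal).  ``placement`` is ``PAM2``/``PAM3`` or ``SEED_k``;
    ``target_allele`` is the top-strand base of the allele the guide binds.
    """

    locus_name: str
    protospacer: str
    strand: str
    placement: str
    target_allele: str
    pam_site: PamSite
    snp_offset_from_3prime: Optional[int] = None
    preferred_pam_change: Optional[bool] = None
    risk_flags: frozenset = field(default_factory=frozenset)

    @property
    def protospacer_span(self) -> Tuple[int, int]:
        """Half-open top-strand interval of the 20-nt binding site."""
        p = self.pam_site.pam_start
        if self.strand == "+":
            return (p - PROTOSPACER_LEN, p)
        return (p + 1, p + 1 + PROTOSPACER_LEN)


def find_pam_sites(seq: str) -> List[PamSite]:
    """All NGG PAM occurrences on both strands of ``seq``.

    Minus-strand PAMs appear as CCN on the top strand and are reported in
    top-strand coordinates.  Ambiguity codes never match G.  Sorted by the
    leftmost base of the PAM triplet, plus strand first on ties.
    """
    seq = seq.upper()
    sites: List[PamSite] = []
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri[1:3] == "GG":
            sites.append(PamSite("+", i, tri))
        if tri[0:2] == "CC":
            sites.append(PamSite("-", i + 2, revcomp(tri)))
    sites.sort(key=lambda s: (s.span[0], s.strand))
    return sites


def count_protospacer_pams(protospacer: str) -> int:
    """Number of (overlapping) NGG occurrences inside a protospacer.

    Multiple PAM sites in the binding site can titrate dCas9 and reduce
    efficiency; a G5 run alone contributes three overlapping NGGs.
    """
    s = protospacer.upper()
    return sum(1 for i in range(len(s) - 2) if s[i + 1 : i + 3] == "GG")


MULTI_PAM_THRESHOLD = 2


def _g_score(g_run: int, loops: Sequence[int], max_length: int, min_run: int) -> int:
    """QGRS-style motif score: more G-tetrads dominate, then shorter motifs,
    then evenly sized loops."""
    total = 4 * g_run + sum(loops)
    return 20 * (g_run - min_run) + (max_length - total) - (max(loops) - min(loops))


def qgrs_scan(
    seq: str,
    max_length: int = 30,
    min_run: int = 2,
    best_only: bool = True,
) -> List[QgrsMotif]:
    """Find G-quadruplex-forming sequences ``Gx N* Gx N* Gx N* Gx``.

    Every qualifying subsequence (four G-runs of equal length ``x >= min_run``
    within ``max_length`` nt) is enumerated; by default a greedy
    non-overlapping best-scoring subset is returned, sorted by position
    (``best_only=False`` returns the full enumeration).
    """
    seq = seq.upper()
    n = len(seq)
    is_g = [c == "G" for c in seq]
    candidates: List[QgrsMotif] = []
    max_run = max_length // 4
    for x in range(min_run, max_run + 1):
        run_ok = [
            all(is_g[i + k] for k in range(x)) if i + x <= n else False
            for i in range(n)
        ]
        starts = [i for i in range(n) if run_ok[i]]
        for s1 in starts:
            limit = s1 + max_length
            for s2 in starts:
                if s2 < s1 + x or s2 + x > limit:
                    continue
                for s3 in starts:
                    if s3 < s2 + x or s3 + x > limit:
                        continue
                    for s4 in starts:
                        if s4 < s3 + x or s4 + x > limit:
                            continue
                        loops = (s2 - s1 - x, s3 - s2 - x, s4 - s3 - x)
                        candidates.append(
                            QgrsMotif(
                                start=s1,
                                end=s4 + x,
                                g_run_length=x,
                                loop_lengths=loops,
                                g_score=_g_score(x, loops, max_length, min_run),
                            )
                        )
    if not best_only:
        candidates.sort(key=lambda m: (m.start, m.end, m.g_run_length))
        return candidates
    # greedy best-scoring non-overlapping selection
    candidates.sort(key=lambda m: (-m.g_score, m.start, m.end))
    chosen: List[QgrsMotif] = []
    for m in candidates:
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    chosen.sort(key=lambda m: m.start)
    return chosen


def max_g_score(seq: str, **kwargs) -> Optional[int]:
    motifs = qgrs_scan(seq, **kwargs)
    return max((m.g_score for m in motifs), default=None)


def _risk_flags(protospacer: str) -> frozenset:
    flags = set()
    if count_protospacer_pams(protospacer) >= MULTI_PAM_THRESHOLD:
        flags.add("MULTI_PAM_IN_PROTOSPACER")
    if qgrs_scan(protospacer):
        flags.add("QUADRUPLEX_SENSE")
    if qgrs_scan(revcomp(protospacer)):
        flags.add("QUADRUPLEX_ANTISENSE")
    return frozenset(flags)


def _protospacer(seq: str, pam: PamSite) -> Optional[str]:
    s, e = (
        (pam.pam_start - PROTOSPACER_LEN, pam.pam_start)
        if pam.strand == "+"
        else (pam.pam_start + 1, pam.pam_start + 1 + PROTOSPACER_LEN)
    )
    if s < 0 or e > len(seq):
        return None
    sub = seq[s:e]
    return sub if pam.strand == "+" else revcomp(sub)


def _strand_base(base: str, strand: str) -> str:
    return base if strand == "+" else revcomp(base)


def enumerate_allele_guides(
    locus: DiploidLocus,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> List[GuideCandidate]:
    """All allele-discriminating guide candidates for one heterozygous locus.

    PAMs are collected from both strands of both allele sequences.  A SNP at
    PAM position 2 or 3 yields one candidate targeting the G-carrying allele;
    a SNP within ``seed_length`` of the protospacer 3' end (PAM intact on both
    alleles) yields one candidate per allele.  Risk flags annotate, they do
    not filter.
    """
    if not 1 <= seed_length <= PROTOSPACER_LEN:
        raise ValueError("seed_length must be within the protospacer")
    seqs = {a: locus.allele_sequence(a) for a in ("allele1", "allele2")}
    sites: dict = {}
    for a, s in seqs.items():
        for pam in find_pam_sites(s):
            sites.setdefault((pam.strand, pam.pam_start), {})[a] = pam
    out: List[GuideCandidate] = []
    for (strand, pam_start), by_allele in sites.items():
        pam = next(iter(by_allele.values()))
        pos2, pos3 = pam.position_coord(2), pam.position_coord(3)
        if locus.snp_pos in (pos2, pos3):
            # SNP inside the PAM GG: only the allele reading G (on the PAM
            # strand) at that position has a PAM at all
            pam_position = 2 if locus.snp_pos == pos2 else 3
            carriers = [
                a
                for a in ("allele1", "allele2")
                if _strand_base(locus.allele_base(a), strand) == "G"
            ]
            if len(carriers) != 1:
                continue
            target = carriers[0]
            other = "allele2" if target == "allele1" else "allele1"
            proto = _protospacer(seqs[target], by_allele[target])
            if proto is None:
                continue
            other_on_strand = _strand_base(locus.allele_base(other), strand)
            out.append(
                GuideCandidate(
                    locus_name=locus.name,
                    protospacer=proto,
                    strand=strand,
                    placement=f"PAM{pam_position}",
                    target_allele=locus.allele_base(target),
                    pam_site=by_allele[target],
                    preferred_pam_change=other_on_strand in "CT",
                    risk_flags=_risk_flags(proto),
                )
            )
            continue
        # seed placement needs the PAM present on both alleles
        if len(by_allele) != 2:
            continue
        k = (pam_start - locus.snp_pos) if strand == "+" else (locus.snp_pos - pam_start)
        if not 1 <= k <= seed_length:
            continue
        for a in ("allele1", "allele2"):
            proto = _protospacer(seqs[a], by_allele[a])
            if proto is None:
                continue
            out.append(
                GuideCandidate(
                    locus_name=locus.name,
                    protospacer=proto,
                    strand=strand,
                    placement=f"SEED_{k}",
                    target_allele=locus.allele_base(a),
                    pam_site=by_allele[a],
                    snp_offset_from_3prime=k,
                    risk_flags=_risk_flags(proto),
                )
            )
    out.sort(
        key=lambda c: (c.pam_site.span[0], c.strand, c.placement, c.target_allele)
    )
    return out


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter window around a TSS (defaults: -50/+500 bp)."""

    upstream_bp: int = 50
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")

    def interval(self, tss: int, strand: str) -> Tuple[int, int]:
        """Half-open 0-based genomic interval for a TSS at 0-based ``tss``."""
        if strand == "-":
            return (tss - self.downstream_bp, tss + self.upstream_bp + 1)
        return (tss - self.upstream_bp, tss + self.downstream_bp + 1)


@dataclass
class ApplicabilityResult:
    """Genome-wide targetability summary.

    ``frac_tss_with_snp``: TSSs whose promoter window holds >=1 heterozygous
    SNP.  ``frac_snps_with_site``: in-window SNPs for which at least one
    allele-discriminating guide exists.  ``frac_tss_targetable``: TSSs with
    >=1 such suitable SNP.
    """

    n_tss: int
    n_tss_with_snp: int
    n_snps_in_windows: int
    n_snps_suitable: int
    n_tss_targetable: int
    no_snps: bool = False

    @property
    def frac_tss_with_snp(self) -> float:
        return self.n_tss_with_snp / self.n_tss if self.n_tss else 0.0

    @property
    def frac_snps_with_site(self) -> float:
        if self.n_snps_in_windows == 0:
            return 0.0
        return self.n_snps_suitable / self.n_snps_in_windows

    @property
    def frac_tss_targetable(self) -> float:
        return self.n_tss_targetable / self.n_tss if self.n_tss else 0.0

    @property
    def frac_snp_tss_with_site(self) -> float:
        """Per-TSS variant of ``frac_snps_with_site``: among TSSs with a
        SNP, the fraction with at least one suitable SNP."""
        if self.n_tss_with_snp == 0:
            return 0.0
        return self.n_tss_targetable / self.n_tss_with_snp

    def as_dict(self) -> dict:
        return {
            "n_tss": self.n_tss,
            "n_tss_with_snp": self.n_tss_with_snp,
            "n_snps_in_windows": self.n_snps_in_windows,
            "n_snps_suitable": self.n_snps_suitable,
            "n_tss_targetable": self.n_tss_targetable,
            "frac_tss_with_snp": self.frac_tss_with_snp,
            "frac_snps_with_site": self.frac_snps_with_site,
            "frac_snp_tss_with_site": self.frac_snp_tss_with_site,
            "frac_tss_targetable": self.frac_tss_targetable,
            "no_snps": self.no_snps,
        }


def snp_is_suitable(
    chrom_seq: str,
    snp_pos: int,
    ref: str,
    alt: str,
    seed_length: int = DEFAULT_SEED_LENGTH,
    context: int = SNP_CONTEXT,
) -> bool:
    """Whether a guide with allele-discriminating placement exists in the
    local context (+/- ``context`` nt) of a heterozygous SNP."""
    lo = max(0, snp_pos - context)
    hi = min(len(chrom_seq), snp_pos + context + 1)
    sub = chrom_seq[lo:hi].upper()
    local = snp_pos - lo
    if local >= len(sub) or sub[local] != ref.upper():
        return False
    try:
        locus = DiploidLocus(
            name="ctx",
            sequence=sub,
            snp_pos=local,
            allele1_base=ref.upper(),
            allele2_base=alt.upper(),
        )
    except ValueError:
        return False
    return len(enumerate_allele_guides(locus, seed_length=seed_length)) > 0


def applicability_estimate(
    snp_table: pd.DataFrame,
    tss_table: pd.DataFrame,
    genome: Mapping[str, str],
    window: PromoterWindow = PromoterWindow(),
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> ApplicabilityResult:
    """Estimate the fraction of TSSs directly targetable by allele-specific
    methylation editing.

    ``snp_table`` needs columns ``chrom, pos (1-based), ref, alt`` restricted
    to heterozygous SNPs; ``tss_table`` needs ``chrom, start, end, strand``
    (BED convention, TSS = start for + / end-1 for -); ``genome`` maps
    chromosome name to sequence (a dict or a ``pyfaidx.Fasta``-like object).
    """
    if tss_table is None or len(tss_table) == 0:
        raise ValueError("empty TSS table")
    windows = []  # (chrom, lo, hi, tss_index)
    for idx, row in tss_table.reset_index(drop=True).iterrows():
        strand = str(row.get("strand", "+"))
        tss = int(row["start"]) if strand != "-" else int(row["end"]) - 1
        lo, hi = window.interval(tss, strand)
        windows.append((str(row["chrom"]), max(0, lo), hi, idx))

    n_tss = len(windows)
    tss_has_snp = np.zeros(n_tss, dtype=bool)
    tss_targetable = np.zeros(n_tss, dtype=bool)
    n_in_windows = 0
    n_suitable = 0
    if snp_table is None or len(snp_table) == 0:
        warnings.warn("no heterozygous SNPs provided", stacklevel=2)
        return ApplicabilityResult(n_tss, 0, 0, 0, 0, no_snps=True)

    for _, snp in snp_table.iterrows():
        chrom = str(snp["chrom"])
        pos0 = int(snp["pos"]) - 1
        if chrom not in genome:
            warnings.warn(f"SNP chrom {chrom} not in genome; skipped", stacklevel=2)
            continue
        chrom_seq = str(genome[chrom][:])
        if not 0 <= pos0 < len(chrom_seq):
            warnings.warn(f"SNP {chrom}:{snp['pos']} outside genome; skipped", stacklevel=2)
            continue
        hit_windows = [i for (c, lo, hi, i) in windows if c == chrom and lo <= pos0 < hi]
        if not hit_windows:
            continue
        n_in_windows += 1
        tss_has_snp[hit_windows] = True
        if snp_is_suitable(chrom_seq, pos0, str(snp["ref"]), str(snp["alt"]), seed_length):
            n_suitable += 1
            tss_targetable[hit_windows] = True
    return ApplicabilityResult(
        n_tss=n_tss,
        n_tss_with_snp=int(tss_has_snp.sum()),
        n_snps_in_windows=n_in_windows,
        n_snps_suitable=n_suitable,
        n_tss_targetable=int(tss_targetable.sum()),
    )


def guides_to_frame(candidates: Iterable[GuideCandidate]) -> pd.DataFrame:
    """Tabular (1-based coordinates) report of guide candidates."""
    rows = []
    for c in candidates:
        s, e = c.protospacer_span
        rows.append(
            {
                "locus": c.locus_name,
                "protospacer": c.protospacer,
                "strand": c.strand,
                "placement": c.placement,
                "target_allele": c.target_allele,
                "protospacer_start_1based": s + 1,
                "protospacer_end_1based": e,
                "pam_start_1based": c.pam_site.pam_start + 1,
                "snp_offset_from_3prime": c.snp_offset_from_3prime,
                "preferred_pam_change": c.preferred_pam_change,
                "risk_flags": ";".join(sorted(c.risk_flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "protospacer",
            "strand",
            "placement",
            "target_allele",
            "protospacer_start_1based",
            "protospacer_end_1based",
            "pam_start_1based",
            "snp_offset_from_3prime",
            "preferred_pam_change",
            "risk_flags",
        ],
    )
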