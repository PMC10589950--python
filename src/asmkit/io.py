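"""Readers/writers for the pipeline's file formats and run configuration.

Formats: FASTA (amplicon references, genomes), FASTQ optionally gzipped
(reads), tab-separated SNP tables (or a minimal VCF body), BED6 TSS tables,
YAML run configs, TSV/bedGraph/JSON outputs.  All genomic coordinates are
1-based in files users edit (SNP tables, reports) and 0-based half-open
internally; BED keeps its native 0-based starts.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .locus import DiploidLocus
from .quant import MethylationProfile

SNP_COLUMNS = ["chrom", "pos", "ref", "alt"]


class ValidationError(ValueError):
    """Aggregated input-validation failure; ``errors`` lists every problem."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("input validation failed:\n" + "\n".join(f"- {e}" for e in errors))


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path) -> List[Tuple[str, str, str]]:
    """``(id, sequence, quality)`` triples from a FASTQ(.gz) file."""
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path, reads: Sequence[Tuple[str, str]], quality_char: str = "I") -> None:
    """Write ``(id, sequence)`` pairs with flat Phred+33 qualities; gzip when
    the path ends in .gz."""
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_snp_table(path) -> pd.DataFrame:
    """Heterozygous SNP definitions: ``chrom, pos (1-based), ref, alt``.

    Accepts a headered TSV or a minimal VCF body (``#`` lines skipped,
    CHROM/POS/REF/ALT taken from the first, second, fourth and fifth
    columns).
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
    is_vcf = first.startswith("##") or path.name.endswith((".vcf", ".vcf.gz"))
    if is_vcf:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        df = df.iloc[:, [0, 1, 3, 4]]
        df.columns = SNP_COLUMNS
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SNP_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError([f"SNP table {path} missing columns: {missing}"])
        df = df[SNP_COLUMNS]
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    return df


def write_snp_table(path, snps: pd.DataFrame) -> None:
    snps[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED6 (or narrower) as a DataFrame; starts stay 0-based."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    df["chrom"] = df["chrom"].astype(str)
    return df


def load_genome(path):
    """Indexed genome access; returns a ``pyfaidx.Fasta``."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_methylation_tsv(path, profiles: Dict[str, Dict[str, MethylationProfile]], locus_name: str) -> None:
    """Long-format per-CpG per-allele methylation table (one row per
    condition x allele x CpG; 1-based reference positions)."""
    frames = []
    for condition, by_allele in profiles.items():
        for allele, prof in by_allele.items():
            df = prof.to_frame(locus_name)
            df.insert(0, "condition", condition)
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_methylation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(path, profile: MethylationProfile, chrom: str) -> None:
    """bedGraph track of per-CpG levels (0-based starts, percent values)."""
    with open(path, "w") as fh:
        for pos, lv in zip(profile.cpg_positions, profile.levels):
            if lv == lv:  # skip NaN
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{100 * lv:.2f}\n")


@dataclass
class SampleSpec:
    condition: str
    replicate: int = 1
    timepoint: Optional[int] = None
    fastq: str = ""
    fastq2: Optional[str] = None


@dataclass
class RunConfig:
    """Validated run configuration for the quantify/asm/express stages."""

    locus: DiploidLocus
    samples: List[SampleSpec]
    coverage_floor: int = 10
    max_mismatch_frac: float = 0.1
    threshold_fraction: float = 0.5
    seed_length: int = 7
    seed: int = 0
    out_dir: str = "out"
    config_path: Optional[str] = None

    def samples_for(self, condition: str) -> List[SampleSpec]:
        return [s for s in self.samples if s.condition == condition]


def load_inputs(config_path) -> RunConfig:
    """Parse and validate a YAML run config; every problem found is reported
    in one aggregated :class:`ValidationError`."""
    config_path = Path(config_path)
    errors: List[str] = []
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    base = config_path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    loc = raw.get("locus", {})
    fasta_path = resolve(loc.get("fasta", ""))
    snp_path = resolve(loc.get("snp_table", ""))
    locus = None
    if not fasta_path.is_file():
        errors.append(f"reference FASTA not found: {fasta_path}")
    if not snp_path.is_file():
        errors.append(f"SNP table not found: {snp_path}")
    if not errors:
        seqs = read_fasta(fasta_path)
        name = loc.get("name") or next(iter(seqs))
        if name not in seqs:
            errors.append(f"locus {name!r} not in {fasta_path}")
        else:
            seq = seqs[name]
            snps = read_snp_table(snp_path)
            snps = snps[snps["chrom"] == name]
            if len(snps) != 1:
                errors.append(f"expected exactly 1 SNP for locus {name!r}, found {len(snps)}")
            else:
                snp = snps.iloc[0]
                pos0 = int(snp["pos"]) - 1
                if not 0 <= pos0 < len(seq):
                    errors.append(f"SNP position {snp['pos']} outside locus {name!r}")
                elif seq[pos0] != snp["ref"]:
                    errors.append(
                        f"SNP REF {snp['ref']!r} at {name}:{snp['pos']} disagrees with "
                        f"reference base {seq[pos0]!r}"
                    )
                else:
                    gi = loc.get("guide_interval")
                    try:
                        locus = DiploidLocus.from_sequence(
                            name=name,
                            sequence=seq,
                            snp_pos=pos0,
                            allele2_base=snp["alt"],
                            guide_interval=tuple(gi) if gi else None,
                            control=bool(loc.get("control", False)),
                        )
                    except ValueError as exc:
                        errors.append(str(exc))

    samples: List[SampleSpec] = []
    for i, s in enumerate(raw.get("samples", [])):
        spec = SampleSpec(
            condition=str(s.get("condition", "")),
            replicate=int(s.get("replicate", 1)),
            timepoint=s.get("timepoint"),
            fastq=str(resolve(s.get("fastq", ""))),
            fastq2=str(resolve(s["fastq2"])) if s.get("fastq2") else None,
        )
        if not spec.condition:
            errors.append(f"sample #{i + 1}: missing condition")
        for p in filter(None, [spec.fastq, spec.fastq2]):
            if not Path(p).is_file():
                errors.append(f"sample #{i + 1}: FASTQ not found: {p}")
        samples.append(spec)

    thr = raw.get("thresholds", {})
    cfg_kwargs = dict(
        coverage_floor=int(thr.get("coverage_floor", 10)),
        max_mismatch_frac=float(thr.get("max_mismatch_frac", 0.1)),
        threshold_fraction=float(thr.get("threshold_fraction", 0.5)),
        seed_length=int(thr.get("seed_length", 7)),
    )
    if not 0 < cfg_kwargs["threshold_fraction"] <= 1:
        errors.append("threshold_fraction must be in (0, 1]")
    if not 0 <= cfg_kwargs["max_mismatch_frac"] < 1:
        errors.append("max_mismatch_frac must be in [0, 1)")
    if cfg_kwargs["coverage_floor"] < 0:
        errors.append("coverage_floor must be non-negative")

    if errors:
        raise ValidationError(errors)
    return RunConfig(
        locus=locus,
        samples=samples,
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "out")),
        config_path=str(config_path),
        **cfg_kwargs,
    )


def _config_hash(config_path: Optional[str]) -> Optional[str]:
    if not config_path or not Path(config_path).is_file():
        return None
    return hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]


REPORT_COLUMNS = [
    "locus",
    "placement",
    "snp",
    "target_allele",
    "asm_delta_pct",
    "asm_ratio",
]


def write_report(
    rows: Sequence[dict],
    out_dir,
    seed: Optional[int] = None,
    config_path: Optional[str] = None,
    timestamp: Optional[str] = None,
) -> Tuple[Path, Path]:
    """Write the per-experiment ASM report.

    The TSV rounds Δ to integer percentage points and the ratio to one
    decimal (report convention); the JSON keeps full precision plus version,
    config hash and seed.  Returns ``(tsv_path, json_path)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "asm_report.tsv"
    json_path = out_dir / "asm_report.json"
    table_rows = []
    for r in rows:
        ratio = r.get("asm_ratio")
        table_rows.append(
            {
                "locus": r.get("locus", ""),
                "placement": r.get("placement", ""),
                "snp": r.get("snp", ""),
                "target_allele": r.get("target_allele", ""),
                "asm_delta_pct": "" if r.get("asm_delta") is None else round(r["asm_delta"]),
                "asm_ratio": "" if ratio is None else f"{ratio:.1f}",
            }
        )
    pd.DataFrame(table_rows, columns=REPORT_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    payload = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config_path),
        "timestamp": timestamp,
        "results": [
            {k: (None if isinstance(v, float) and v != v else v) for k, v in r.items()}
            for r in rows
        ],
    }
    json_path.write_text(json.dumps(payload, indent=2, default=float))
    return tsv_path, json_path
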