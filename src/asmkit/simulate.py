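"""Synthetic bisulfite-amplicon and cDNA read generation with known truth.

Reads are simulated per condition and per allele from a
:class:`~asmkit.locus.MethylationTruth`: each read draws an independent
Bernoulli methylation state at every CpG, the strand sequence is bisulfite
converted (unmethylated C -> T at ``conversion_rate``, methylated CpG C
retained at ``methylated_protection``), the SNP base is taken from the allele
of origin before conversion, and sequencing errors are applied last.  A
per-read truth table records allele, strand and the drawn states so that
downstream stages can be validated read by read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .locus import DiploidLocus, MethylationTruth, ReadSimConfig, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimRead:
    """One simulated read (or mate pair) with its provenance."""

    read_id: str
    condition: str
    sequence: str
    mate2: Optional[str] = None  # reverse mate for paired mode

    @property
    def paired(self) -> bool:
        return self.mate2 is not None


@dataclass
class SimulatedDataset:
    """A complete simulated experiment for one locus."""

    locus: DiploidLocus
    truth: MethylationTruth
    config: ReadSimConfig
    reads: List[SimRead] = field(default_factory=list)
    truth_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def reads_for(self, condition: str) -> List[SimRead]:
        return [r for r in self.reads if r.condition == condition]


def _convert_strand(
    seq: str,
    cpg_pos: Sequence[int],
    meth_states: np.ndarray,
    conversion_rate: float,
    protection: float,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert one strand given per-CpG methylation states.

    ``cpg_pos`` are the cytosine offsets *on this strand*; every other C is
    treated as unmethylated (non-CpG methylation is negligible in somatic
    human cells).
    """
    out = list(seq)
    meth_at = dict(zip(cpg_pos, meth_states))
    for i, b in enumerate(out):
        if b != "C":
            continue
        if meth_at.get(i, False):
            if rng.random() >= protection:
                out[i] = "T"
        else:
            if rng.random() < conversion_rate:
                out[i] = "T"
    return "".join(out)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def simulate_bisulfite_reads(
    locus: DiploidLocus,
    truth: MethylationTruth,
    cfg: ReadSimConfig,
) -> Tuple[List[SimRead], pd.DataFrame]:
    """Simulate bisulfite amplicon reads for every condition in ``truth``.

    Returns the read list and a truth table with one row per read
    (``read_id, condition, allele, strand`` plus one ``cpg{i}`` column per
    CpG holding the drawn methylation state).
    """
    for (cond, allele), arr in truth.probabilities.items():
        if len(arr) != len(locus.cpg_positions):
            raise ValueError(
                f"truth for ({cond}, {allele}) has {len(arr)} probabilities "
                f"but locus has {len(locus.cpg_positions)} CpGs"
            )
    rng = np.random.default_rng(cfg.rng_seed)
    reads: List[SimRead] = []
    records: List[dict] = []
    if cfg.depth == 0:
        warnings.warn("depth=0: simulating an empty read set", stacklevel=2)

    L = len(locus.sequence)
    # bottom-strand CpG cytosine offsets: complement of the top-strand G
    bottom_cpg = [L - 2 - p for p in locus.cpg_positions]

    for condition in truth.conditions:
        serial = 0
        for allele in ("allele1", "allele2"):
            if (condition, allele) not in truth.probabilities:
                continue
            probs = truth.prob(condition, allele)
            allele_seq = locus.allele_sequence(allele)
            for i in range(cfg.depth):
                states = rng.random(len(probs)) < probs
                strand = "OT" if rng.random() < cfg.strand_mix else "OB"
                if strand == "OT":
                    frag = _convert_strand(
                        allele_seq,
                        locus.cpg_positions,
                        states,
                        cfg.conversion_rate,
                        cfg.methylated_protection,
                        rng,
                    )
                else:
                    # the drawn state applies to both strands of the CpG dyad
                    frag = _convert_strand(
                        revcomp(allele_seq),
                        bottom_cpg,
                        states,
                        cfg.conversion_rate,
                        cfg.methylated_protection,
                        rng,
                    )
                read_id = f"{locus.name}:{condition}:{serial}"
                serial += 1
                if cfg.paired:
                    rl = min(cfg.read_length, len(frag))
                    r1 = _apply_errors(frag[:rl], cfg.seq_error_rate, rng)
                    r2 = _apply_errors(revcomp(frag[-rl:]), cfg.seq_error_rate, rng)
                    reads.append(SimRead(read_id, condition, r1, mate2=r2))
                else:
                    if cfg.read_length is not None:
                        frag = frag[: cfg.read_length]
                    seq = _apply_errors(frag, cfg.seq_error_rate, rng)
                    reads.append(SimRead(read_id, condition, seq))
                rec = {
                    "read_id": read_id,
                    "condition": condition,
                    "allele": allele,
                    "strand": strand,
                }
                for j, s in enumerate(states):
                    rec[f"cpg{j}"] = bool(s)
                records.append(rec)
    cols = ["read_id", "condition", "allele", "strand"] + [
        f"cpg{j}" for j in range(len(locus.cpg_positions))
    ]
    table = pd.DataFrame(records, columns=cols)
    return reads, table


def write_fixture(
    dataset: SimulatedDataset,
    out_dir,
    gzip_fastq: bool = False,
) -> Dict[str, object]:
    """Write a simulated dataset to disk as a self-contained fixture.

    Emits the amplicon reference FASTA, the SNP table, one FASTQ per
    condition (two in paired mode, ``_R1``/``_R2``), the per-read truth
    table and a run-config manifest that round-trips through
    :func:`asmkit.io.load_inputs`.  Returns a mapping of logical names to
    written paths.
    """
    from pathlib import Path

    import yaml

    from . import io as aio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locus = dataset.locus
    paths: Dict[str, object] = {}

    fasta = out_dir / f"{locus.name}.fa"
    aio.write_fasta(fasta, {locus.name: locus.sequence})
    paths["fasta"] = fasta

    snp_path = out_dir / f"{locus.name}_snps.tsv"
    pd.DataFrame(
        [
            {
                "chrom": locus.name,
                "pos": locus.snp_pos + 1,
                "ref": locus.allele1_base,
                "alt": locus.allele2_base,
            }
        ]
    ).to_csv(snp_path, sep="\t", index=False)
    paths["snp_table"] = snp_path

    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    samples = []
    fastq_paths: Dict[str, object] = {}
    for condition in dataset.truth.conditions:
        reads = dataset.reads_for(condition)
        if dataset.config.paired:
            p1 = out_dir / f"{locus.name}_{condition}_R1{ext}"
            p2 = out_dir / f"{locus.name}_{condition}_R2{ext}"
            aio.write_fastq(p1, [(r.read_id, r.sequence) for r in reads])
            aio.write_fastq(p2, [(r.read_id, r.mate2) for r in reads])
            fastq_paths[condition] = (p1, p2)
            samples.append(
                {"condition": condition, "replicate": 1, "fastq": p1.name, "fastq2": p2.name}
            )
        else:
            p = out_dir / f"{locus.name}_{condition}{ext}"
            aio.write_fastq(p, [(r.read_id, r.sequence) for r in reads])
            fastq_paths[condition] = p
            samples.append({"condition": condition, "replicate": 1, "fastq": p.name})
    paths["fastq"] = fastq_paths

    truth_path = out_dir / f"{locus.name}_truth.tsv"
    dataset.truth_table.to_csv(truth_path, sep="\t", index=False)
    paths["truth_table"] = truth_path

    config = {
        "locus": {
            "name": locus.name,
            "fasta": fasta.name,
            "snp_table": snp_path.name,
            "guide_interval": list(locus.guide_interval) if locus.guide_interval else None,
        },
        "samples": samples,
        "seed": dataset.config.rng_seed,
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    paths["config"] = config_path
    return paths


def simulate_expression_reads(
    allele_ratio: Tuple[float, float],
    depth: int,
    n_replicates: int,
    dispersion: float = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate cDNA allele counts at a specified allele ratio.

    Counts are binomial around ``allele_ratio`` when ``dispersion`` is 0 and
    beta-binomial otherwise; the beta distribution has mean ``allele_ratio[0]``
    and concentration ``1/dispersion`` (larger dispersion, noisier replicate
    proportions).
    """
    p1, p2 = allele_ratio
    if not np.isclose(p1 + p2, 1.0):
        raise ValueError("allele_ratio proportions must sum to 1")
    if not (0.0 <= p1 <= 1.0):
        raise ValueError("allele_ratio proportions must be in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        if dispersion == 0 or p1 in (0.0, 1.0):
            p = p1
        else:
            conc = 1.0 / dispersion
            p = rng.beta(p1 * conc, (1 - p1) * conc)
        a1 = int(rng.binomial(depth, p))
        rows.append({"replicate": rep, "allele1": a1, "allele2": depth - a1})
    return pd.DataFrame(rows)


def simulate_cdna_reads(
    locus: DiploidLocus,
    counts: pd.DataFrame,
    seq_error_rate: float = 0.0,
    rng_seed: int = 0,
) -> Dict[int, List[str]]:
    """Expand per-replicate allele counts into plain (non-bisulfite) exon
    amplicon reads, for exercising the expression read counter end to end."""
    rng = np.random.default_rng(rng_seed)
    out: Dict[int, List[str]] = {}
    for _, row in counts.iterrows():
        reads: List[str] = []
        for allele, n in (("allele1", int(row["allele1"])), ("allele2", int(row["allele2"]))):
            seq = locus.allele_sequence(allele)
            for _ in range(n):
                reads.append(_apply_errors(seq, seq_error_rate, rng))
        out[int(row["replicate"])] = reads
    return out
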