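"""Bisulfite quantification: merging, alignment, allele splitting, calling."""

from __future__ import annotations

import numpy as np
import pytest

from asmkit.locus import DiploidLocus, ReadSimConfig, revcomp
from asmkit.quant import (
    AlignedRead,
    AmpliconRef,
    Rejection,
    align_to_amplicon,
    assign_allele,
    call_methylation,
    merge_pairs,
    quantify_reads,
)
from asmkit.simulate import simulate_bisulfite_reads

from conftest import make_random_locus, uniform_truth


# ------------------------------------------------------------- merge_pairs
class TestMergePairs:
    def test_exact_overlap(self):
        rng = np.random.default_rng(0)
        frag = "".join(rng.choice(list("ACGT"), size=120))
        r1 = frag[:100]
        r2 = revcomp(frag[20:])  # mate given 5'->3' on the opposite strand
        m = merge_pairs(r1, r2)
        assert m is not None
        assert m.sequence == frag
        assert m.overlap == 80 and m.mismatches == 0

    def test_no_sufficient_overlap_fails(self):
        assert merge_pairs("A" * 50, "C" * 50, min_overlap=30) is None

    def test_empty_read_fails(self):
        assert merge_pairs("", "ACGT") is None

    def test_quality_resolves_disagreement(self):
        r1 = "ACGTACGTACGTACG"
        frag2 = "ACGTACGTACGTACG"
        frag2 = frag2[:5] + "T" + frag2[6:]
        r2 = revcomp(frag2)
        hi, lo = "I" * 15, "#" * 15
        m = merge_pairs(r1, r2, q1=lo, q2=hi, min_overlap=10)
        assert m.sequence[5] == "T"
        m = merge_pairs(r1, r2, q1=hi, q2=lo, min_overlap=10)
        assert m.sequence[5] == "C"

    def test_matches_bruteforce_best_overlap(self):
        """Merged length equals the all-offset-scan oracle on random pairs."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            frag = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 150))))
            cut = int(rng.integers(10, len(frag) - 50))
            r1, r2 = frag[: cut + 40], revcomp(frag[cut:])
            m = merge_pairs(r1, r2)
            # oracle: best (lowest-mismatch, longest) overlap by direct scan
            r2rc = revcomp(r2)
            best = min(
                (
                    (sum(a != b for a, b in zip(r1[-o:], r2rc[:o])) / o, -o)
                    for o in range(10, min(len(r1), len(r2rc)) + 1)
                ),
            )
            assert m is not None
            assert len(m.sequence) == len(r1) + len(r2rc) + best[1]


# -------------------------------------------------------- align_to_amplicon
class TestAlign:
    def test_fully_converted_read_maps_ot_zero_mismatch(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        read = toy_locus.sequence.replace("C", "T")
        aln = align_to_amplicon(read, ref)
        assert isinstance(aln, AlignedRead)
        assert (aln.strand, aln.offset, aln.mismatches) == ("OT", 0, 0)

    def test_methylated_cpg_not_a_mismatch(self, toy_locus):
        """A retained (methylated) C at a CpG still aligns with 0
        converted-space mismatches."""
        ref = AmpliconRef(toy_locus)
        seq = list(toy_locus.sequence)
        keep = toy_locus.cpg_positions[0]
        read = "".join(
            b if (i == keep and b == "C") else (b.replace("C", "T")) for i, b in enumerate(seq)
        )
        aln = align_to_amplicon(read, ref)
        assert aln.mismatches == 0 and aln.strand == "OT"

    def test_allele2_read_not_penalised_at_snp(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        read = toy_locus.allele_sequence("allele2").replace("C", "T")
        aln = align_to_amplicon(read, ref)
        assert aln.mismatches == 0

    def test_ob_read_recovered(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        bottom = revcomp(toy_locus.sequence).replace("C", "T")  # converted OB
        aln = align_to_amplicon(bottom, ref)
        assert aln.strand == "OB" and aln.offset == 0

    def test_garbage_rejected_unmapped(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        rng = np.random.default_rng(2)
        read = "".join(rng.choice(list("ACGT"), size=len(toy_locus.sequence)))
        result = align_to_amplicon(read, ref)
        assert isinstance(result, Rejection) and result.reason == "unmapped"

    def test_simulated_reads_all_map_with_true_strand(self, toy_locus, fast_cfg):
        """Error-free simulated reads map 100% and recover the truth-table
        strand call."""
        truth = uniform_truth(toy_locus, guide_on=0.5, guide_off=0.5)
        cfg = ReadSimConfig(
            depth=150, conversion_rate=1.0, methylated_protection=1.0,
            seq_error_rate=0.0, strand_mix=0.5, rng_seed=8,
        )
        reads, table = simulate_bisulfite_reads(toy_locus, truth, cfg)
        ref = AmpliconRef(toy_locus)
        truth_strand = dict(zip(table["read_id"], table["strand"]))
        for r in reads:
            aln = align_to_amplicon(r.sequence, ref, read_id=r.read_id)
            assert isinstance(aln, AlignedRead), r.read_id
            assert aln.offset == 0
            assert aln.strand == truth_strand[r.read_id]


# ------------------------------------------------------------ assign_allele
def _aln(seq: str, strand: str, offset: int = 0) -> AlignedRead:
    return AlignedRead(read_id="r", offset=offset, strand=strand, mismatches=0, sequence=seq)


class TestAssignAllele:
    def _locus(self, ref_base, alt_base):
        seq = "ATTAA" + ref_base + "TTAAA"
        return DiploidLocus.from_sequence("mini", seq, 5, alt_base)

    def test_gt_snp_ot_unambiguous(self):
        locus = self._locus("G", "T")
        assert assign_allele(_aln("ATTAAGTTAAA", "OT"), locus) == "allele1"
        assert assign_allele(_aln("ATTAATTTAAA", "OT"), locus) == "allele2"

    def test_cg_snp_ot_conversion_aware(self):
        """SNP C/G observed 'T' on OT: T is a converted C, not a G."""
        locus = self._locus("C", "G")
        assert assign_allele(_aln("ATTAATTTAAA", "OT"), locus) == "allele1"
        assert assign_allele(_aln("ATTAACTTAAA", "OT"), locus) == "allele1"
        assert assign_allele(_aln("ATTAAGTTAAA", "OT"), locus) == "allele2"

    def test_ga_snp_ob_ambiguous(self):
        """SNP G/A on an OB read: observed A fits both alleles."""
        locus = self._locus("G", "A")
        assert assign_allele(_aln("ATTAAATTAAA", "OB"), locus) == "unassignable"
        assert assign_allele(_aln("ATTAAGTTAAA", "OB"), locus) == "allele1"

    def test_read_not_covering_snp_unassignable(self):
        locus = self._locus("G", "T")
        assert assign_allele(_aln("ATT", "OT"), locus) == "unassignable"

    def test_other_base_unassignable(self):
        locus = self._locus("G", "T")
        assert assign_allele(_aln("ATTAACTTAAA", "OT"), locus) == "unassignable"


# --------------------------------------------------------- call_methylation
class TestCallMethylation:
    def test_level_arithmetic(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        cpg = toy_locus.cpg_positions[0]
        conv = toy_locus.sequence.replace("C", "T")
        meth_read = conv[:cpg] + "C" + conv[cpg + 1 :]
        assignments = [(_aln(meth_read, "OT"), "allele1")] * 4 + [
            (_aln(conv, "OT"), "allele1")
        ] * 6
        prof = call_methylation(assignments, ref, coverage_floor=1)["allele1"]
        idx = toy_locus.cpg_positions.index(cpg)
        assert prof.meth[idx] == 4 and prof.unmeth[idx] == 6
        assert prof.levels[idx] == pytest.approx(0.4)

    def test_all_methylated_level_one(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        # retain every CpG C, convert the rest
        seq = list(toy_locus.sequence)
        read = "".join(
            b if i in toy_locus.cpg_positions else b.replace("C", "T")
            for i, b in enumerate(seq)
        )
        assignments = [(_aln(read, "OT"), "allele1")] * 10
        prof = call_methylation(assignments, ref, coverage_floor=10)["allele1"]
        assert np.all(prof.meth == 10) and np.all(prof.unmeth == 0)
        assert np.allclose(prof.levels, 1.0)

    def test_zero_coverage_is_missing_not_zero(self, toy_locus):
        ref = AmpliconRef(toy_locus)
        with pytest.warns(UserWarning):
            prof = call_methylation([], ref)["allele1"]
        assert np.all(np.isnan(prof.levels))

    def test_conversion_failure_qc_recovered(self, toy_locus):
        """With conversion_rate<1 the non-CpG retention estimate recovers
        1 - conversion_rate within sampling error."""
        truth = uniform_truth(toy_locus, guide_on=0.3, guide_off=0.3)
        cfg = ReadSimConfig(
            depth=400, conversion_rate=0.95, methylated_protection=1.0,
            seq_error_rate=0.0, rng_seed=6,
        )
        reads, _ = simulate_bisulfite_reads(toy_locus, truth, cfg)
        res = quantify_reads([r for r in reads if r.condition == "guide"], toy_locus)
        qc = res.profiles["all"].non_cpg_retention
        n_obs = 800 * sum(
            1 for i, b in enumerate(toy_locus.sequence)
            if b == "C" and i not in toy_locus.cpg_positions
        )
        assert qc == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_obs))


# ------------------------------------------------------------ full pipeline
class TestQuantifyPipeline:
    def test_parameter_recovery_within_binomial_error(self):
        """Recovered per-CpG levels within 3 binomial SD of truth on both
        alleles (depth 500, on 0.7 / off 0.1, perfect chemistry)."""
        locus = make_random_locus(np.random.default_rng(10))
        truth = uniform_truth(locus, guide_on=0.7, guide_off=0.1)
        cfg = ReadSimConfig(
            depth=500, conversion_rate=1.0, methylated_protection=1.0,
            seq_error_rate=0.0, rng_seed=11,
        )
        reads, _ = simulate_bisulfite_reads(locus, truth, cfg)
        res = quantify_reads([r for r in reads if r.condition == "guide"], locus)
        for allele, p in (("allele1", 0.7), ("allele2", 0.1)):
            levels = res.profiles[allele].levels
            sd = np.sqrt(p * (1 - p) / 500)
            assert np.all(np.abs(levels - p) < 3 * sd + 1e-12)

    def test_conservation_and_zero_misassignment(self, toy_locus, fast_cfg):
        truth = uniform_truth(toy_locus)
        reads, table = simulate_bisulfite_reads(toy_locus, truth, fast_cfg)
        truth_allele = dict(zip(table["read_id"], table["allele"]))
        for cond in ("untransfected", "scrambled", "guide"):
            sub = [r for r in reads if r.condition == cond]
            res = quantify_reads(sub, toy_locus)
            assert res.conservation_holds()
            assert res.counts["assigned_allele1"] == sum(
                1 for r in sub if truth_allele[r.read_id] == "allele1"
            )

    def test_allele_label_swap_swaps_profiles(self, toy_locus, fast_cfg):
        truth = uniform_truth(toy_locus, guide_on=0.8, guide_off=0.1)
        reads, _ = simulate_bisulfite_reads(toy_locus, truth, fast_cfg)
        sub = [r for r in reads if r.condition == "guide"]
        res = quantify_reads(sub, toy_locus)
        res_swapped = quantify_reads(sub, toy_locus.swapped_alleles())
        np.testing.assert_array_equal(
            res.profiles["allele1"].meth, res_swapped.profiles["allele2"].meth
        )
        np.testing.assert_array_equal(
            res.profiles["allele2"].unmeth, res_swapped.profiles["allele1"].unmeth
        )

    def test_paired_reads_merge_and_quantify(self, toy_locus):
        truth = uniform_truth(toy_locus, guide_on=0.6, guide_off=0.1)
        cfg = ReadSimConfig(
            read_length=40, paired=True, depth=100, conversion_rate=1.0,
            methylated_protection=1.0, seq_error_rate=0.0, rng_seed=12,
        )
        reads, _ = simulate_bisulfite_reads(toy_locus, truth, cfg)
        sub = [r for r in reads if r.condition == "guide"]
        res = quantify_reads(sub, toy_locus, coverage_floor=1)
        assert res.counts["merged"] == len(sub)  # 58-nt amplicon, 40-nt mates overlap
        assert res.conservation_holds()
        assert res.counts["assigned_allele1"] + res.counts["assigned_allele2"] == len(sub)
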