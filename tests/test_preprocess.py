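import numpy as np
import pytest

from its2otu.preprocess import (
    FilterPolicy,
    demultiplex,
    dereplicate,
    flag_chimeras,
    preprocess_reads,
    quality_filter,
    remove_singletons,
    trim_reverse_primer,
)
from its2otu.seqio import MappingRow, MappingTable, SequenceRecord, UniqueSequence
from conftest import make_count_table

BARCODE = "AACCGGTT"
FWD = "GAATTGCAGAACTCCGTG"
REV = "GGGATCCATATGCTTAAGTTCAGCGGGT"
MAPPING = MappingTable([MappingRow("s1", BARCODE, FWD, REV)])


def _read(insert: str, barcode: str = BARCODE, fwd: str = FWD, rid: str = "r1"):
    return SequenceRecord(rid, barcode + fwd + insert)


class TestDemultiplex:
    def test_exact_read_assigned_and_trimmed(self):
        insert = "ACGT" * 20
        per_sample, report = demultiplex([_read(insert)], MAPPING)
        assert [r.seq for r in per_sample["s1"]] == [insert]
        assert report.n_kept == 1
        assert report.check_conservation()

    def test_one_barcode_mismatch_discarded(self):
        bad = "T" + BARCODE[1:]
        _, report = demultiplex([_read("ACGT" * 20, barcode=bad)], MAPPING)
        assert report.n_kept == 0
        assert report.discarded["_unassigned"]["barcode"] == 1

    def test_two_primer_mismatches_kept_three_discarded(self):
        fwd2 = "TT" + FWD[2:]
        fwd3 = "TTT" + FWD[3:]
        per_sample, report = demultiplex(
            [
                _read("ACGT" * 20, fwd=fwd2, rid="ok"),
                _read("ACGT" * 20, fwd=fwd3, rid="bad"),
            ],
            MAPPING,
        )
        assert [r.id for r in per_sample["s1"]] == ["ok"]
        assert report.discarded["s1"]["fwd_primer"] == 1

    def test_iupac_degenerate_primer_matches(self):
        mapping = MappingTable([MappingRow("s1", BARCODE, "GAWTTG", REV)])
        per_sample, _ = demultiplex(
            [SequenceRecord("r1", BARCODE + "GATTTG" + "ACGT" * 20)], mapping
        )
        assert len(per_sample["s1"]) == 1

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], MappingTable([]))


class TestTrimReversePrimer:
    def test_exact_primer_trimmed(self):
        insert = "ACGT" * 30
        read = SequenceRecord("r", insert + REV)
        out, found = trim_reverse_primer(read, REV, 0.15)
        assert found and out.seq == insert

    def test_two_mismatches_within_rate_trimmed(self):
        primer = "GGGATCCATATGCTTAAG"  # 18 nt; 2/18 ~ 0.11 <= 0.15
        mutated = "TT" + primer[2:]
        insert = "ACGT" * 30
        out, found = trim_reverse_primer(
            SequenceRecord("r", insert + mutated), primer, 0.15
        )
        assert found and out.seq == insert

    def test_three_mismatches_not_trimmed(self):
        primer = "GGGATCCATATGCTTAAG"  # 3/18 ~ 0.167 > 0.15
        mutated = "TTT" + primer[3:]
        insert = "ACGT" * 30
        read = SequenceRecord("r", insert + mutated)
        out, found = trim_reverse_primer(read, primer, 0.15)
        assert not found and out.seq == read.seq

    def test_absent_primer_unchanged(self):
        read = SequenceRecord("r", "ACGT" * 30)
        out, found = trim_reverse_primer(read, "TTTTGGGGCCCCAAAATTTT", 0.15)
        assert not found and out is read

    def test_partial_suffix_overlap_trimmed(self):
        insert = "ACGT" * 30
        read = SequenceRecord("r", insert + REV[:10])  # primer runs off the 3' end
        out, found = trim_reverse_primer(read, REV, 0.15)
        assert found and out.seq == insert


class TestQualityFilter:
    def test_homopolymer_run_of_five_discarded(self):
        seq = "ACGT" * 40 + "AAAAA" + "CGTA" * 40
        assert quality_filter(SequenceRecord("r", seq)) == "homopolymer"

    def test_short_read_discarded(self):
        seq = ("ACGT" * 63)[:249]
        assert quality_filter(SequenceRecord("r", seq)) == "length"

    def test_clean_read_kept(self):
        seq = "ACGT" * 75  # 300 nt, max run 1
        assert quality_filter(SequenceRecord("r", seq)) is None

    def test_run_of_exactly_four_kept(self):
        seq = "AAAA" + "CGTA" * 74
        assert quality_filter(SequenceRecord("r", seq)) is None

    def test_ambiguity_discarded_first(self):
        seq = "N" + "AAAAA" + "ACGT" * 80
        assert quality_filter(SequenceRecord("r", seq)) == "ambiguity"

    def test_idempotent(self):
        reads = [
            SequenceRecord("a", "ACGT" * 75),
            SequenceRecord("b", "ACGT" * 80),
        ]
        survivors = [r for r in reads if quality_filter(r) is None]
        assert [r for r in survivors if quality_filter(r) is None] == survivors


class TestDereplicate:
    def test_identical_reads_collapse(self):
        reads = {"s1": [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]}
        table = dereplicate(reads)
        assert len(table) == 1
        assert table.variants[0].counts == {"s1": 2}

    def test_empty_input(self):
        assert len(dereplicate({})) == 0

    def test_order_independence(self, rng):
        reads = [
            SequenceRecord(f"r{i}", rng.choice(["AAAA", "CCCC", "GGGG"]))
            for i in range(60)
        ]
        t1 = dereplicate({"s1": reads})
        t2 = dereplicate({"s1": list(reversed(reads))})
        assert t1 == t2

    def test_zero_error_simulation_matches_draw_tally(self):
        """With no errors, derep recovers exactly the simulator's draw counts."""
        from collections import Counter

        from its2otu.simulate import GenomeModel, ReadModel, simulate_sample

        g = GenomeModel(
            "sp", "A", ("ACGTACGTCA" * 10,), n_rare_variants=9, max_intra_divergence=0.03
        )
        rm = ReadModel(substitution_rate=0, homopolymer_indel_rate=0, chimera_rate=0)
        sim = simulate_sample([g], [1.0], 1000, rm, seed=9, sample_id="s1")
        # strip adapters directly: template = read minus barcode/primers
        pre = len(rm.barcode) + len(rm.fwd_primer)
        suf = len(rm.rev_primer)
        stripped = [
            SequenceRecord(r.id, r.seq[pre:-suf]) for r in sim.reads
        ]
        table = dereplicate({"s1": stripped})
        truth_tally = Counter(sim.truth["template_id"])
        assert {v.id: v.total for v in table} == dict(truth_tally)


class TestRemoveSingletons:
    def test_total_one_removed(self):
        t = make_count_table({"AAAA": 1, "CCCC": 2})
        out = remove_singletons(t)
        assert [v.seq for v in out] == ["CCCC"]

    def test_cross_sample_total_two_retained(self):
        t = make_count_table(
            {"AAAA": {"s1": 1, "s2": 1}}, samples=("s1", "s2")
        )
        assert len(remove_singletons(t)) == 1

    def test_idempotent(self):
        t = make_count_table({"AAAA": 1, "CCCC": 2, "GGGG": 5})
        once = remove_singletons(t)
        assert remove_singletons(once) == once


class TestFlagChimeras:
    def test_single_variant_not_flagged(self):
        t = make_count_table({"ACGTACGTAC" * 3: 50})
        out, flagged = flag_chimeras(t)
        assert flagged == [] and len(out) == 1

    def test_constructed_chimera_flagged(self, rng):
        p1 = "".join(rng.choice(list("ACGT"), size=60))
        p2 = p1[:10] + "".join(rng.choice(list("ACGT"), size=50))
        chimera = p1[:30] + p2[30:]
        assert chimera not in (p1, p2)
        t = make_count_table({p1: 100, p2: 100, chimera: 10})
        out, flagged = flag_chimeras(t)
        from its2otu.seqio import sequence_id

        assert flagged == [sequence_id(chimera)]
        assert len(out) == 2

    def test_variant_identical_to_parent_not_flagged(self):
        p1 = "ACGT" * 15
        t = make_count_table({p1: 100})
        _, flagged = flag_chimeras(t)
        assert flagged == []

    def test_low_skew_parent_not_used(self, rng):
        """Parents must be at least 2x more abundant than the candidate."""
        p1 = "".join(rng.choice(list("ACGT"), size=60))
        p2 = p1[:10] + "".join(rng.choice(list("ACGT"), size=50))
        chimera = p1[:30] + p2[30:]
        t = make_count_table({p1: 15, p2: 15, chimera: 10})
        _, flagged = flag_chimeras(t)
        assert flagged == []


class TestEndToEnd:
    def test_conservation_through_filters(self, small_isoclonal_sample):
        sim, mapping = small_isoclonal_sample
        table, report, _ = preprocess_reads(sim.reads, mapping)
        assert report.n_input == len(sim.reads)
        assert report.check_conservation()

    def test_zero_error_retained_set_is_templates_minus_singletons(
        self, two_clade_genomes
    ):
        from collections import Counter

        from its2otu.simulate import ReadModel, make_mapping, simulate_sample

        g = two_clade_genomes[0]
        mapping = make_mapping(["s1"], seed=13)
        rm = ReadModel(
            barcode=mapping.rows[0].barcode,
            substitution_rate=0,
            homopolymer_indel_rate=0,
            chimera_rate=0,
        )
        sim = simulate_sample([g], [1.0], 1500, rm, seed=14, sample_id="s1")
        table, _, _ = preprocess_reads(sim.reads, mapping)
        tally = Counter(sim.truth["template_id"])
        expected = {tid for tid, n in tally.items() if n > 1}
        assert set(table.ids) == expected
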