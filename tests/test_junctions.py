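import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_seq
from ntmap.dna import revcomp
from ntmap.errors import ConsensusError, CoordinateError
from ntmap.index import ReferenceDB
from ntmap.io import SequenceRecord
from ntmap.junctions import (
    RemnantHit,
    compute_consensus,
    crop_terminal_queries,
    extract_junction_queries,
    flanking_at_coordinate,
)
from oracles import consensus_by_frequency


class TestCrop:
    def test_crops_are_the_terminal_sixty_mers(self, rng):
        nt = SequenceRecord(id="P_element", seq=random_seq(rng, 2907))
        q5, q3 = crop_terminal_queries(nt, 60)
        assert q5.seq == nt.seq[:60] and q3.seq == nt.seq[-60:]
        assert q5.id.endswith("TIR5") and q3.id.endswith("TIR3")
        assert len(q5.seq) == len(q3.seq) == 60

    def test_transposon_shorter_than_two_crops_errors(self, rng):
        nt = SequenceRecord(id="short", seq=random_seq(rng, 100))
        with pytest.raises(CoordinateError):
            crop_terminal_queries(nt, 60)


class TestExtraction:
    def _contig(self, rng, nt, pos, flank_needed=4000):
        genome = random_seq(rng, 2 * flank_needed + len(nt))
        return SequenceRecord(
            id="ctg", seq=genome[:pos] + nt + genome[pos:]
        )

    def test_double_tir_junction_queries_have_crop_plus_flank(self, rng):
        nt = random_seq(rng, 2000)
        contig = self._contig(rng, nt, 4000)
        hits = [
            RemnantHit("ctg", "5'", 4000, 4060, "+", 60),
            RemnantHit("ctg", "3'", 5940, 6000, "+", 60),
        ]
        jqs = extract_junction_queries([contig], hits, flank=3000, nt_len=2000)
        by_side = {j.side: j for j in jqs}
        assert len(jqs) == 2
        assert len(by_side["5'"].seq) == 3060 and len(by_side["3'"].seq) == 3060
        # the JQ embeds the terminal region verbatim
        assert by_side["5'"].seq.endswith(nt[:60])
        assert by_side["3'"].seq.startswith(nt[-60:])

    def test_minus_strand_queries_are_canonicalized(self, rng):
        nt = random_seq(rng, 2000)
        pos = 4000
        genome = random_seq(rng, 10_000)
        contig = SequenceRecord(id="ctg", seq=genome[:pos] + revcomp(nt) + genome[pos:])
        # Q5' matches the reverse strand at the high end of the reversed copy
        hits = [RemnantHit("ctg", "5'", pos + 2000 - 60, pos + 2000, "-", 60)]
        jqs = extract_junction_queries([contig], hits, flank=3000)
        assert jqs[0].seq.endswith(nt[:60])
        assert len(jqs[0].seq) == 3060

    def test_remnant_near_contig_end_sets_alert(self, rng):
        nt = random_seq(rng, 2000)
        genome = random_seq(rng, 1000)
        contig = SequenceRecord(id="ctg", seq=genome[:500] + nt + genome[500:])
        hits = [RemnantHit("ctg", "5'", 500, 560, "+", 60)]
        jqs = extract_junction_queries([contig], hits, flank=3000)
        assert jqs[0].alert
        assert "ALERT" in jqs[0].to_record().description or "ALERT" in jqs[0].id
        assert len(jqs[0].seq) == 560  # truncated at the contig start

    def test_single_tir_remnant_gets_the_three_part_join(self, rng):
        remnant = random_seq(rng, 1500)  # 5' half of a 2907-nt transposon
        genome = random_seq(rng, 14_000)
        contig = SequenceRecord(id="ctg", seq=genome[:7000] + remnant + genome[7000:])
        hits = [RemnantHit("ctg", "5'", 7000, 7060, "+", 60)]
        jqs = extract_junction_queries([contig], hits, flank=3000,
                                       nt_len=2907, tail=2000)
        joined = [j for j in jqs if j.joined]
        assert len(joined) == 1
        assert joined[0].side == "3'"
        assert len(joined[0].seq) == 60 + 2907 + 2000

    def test_paired_hits_do_not_trigger_the_join(self, rng):
        nt = random_seq(rng, 2000)
        contig = self._contig(rng, nt, 4000)
        hits = [
            RemnantHit("ctg", "5'", 4000, 4060, "+", 60),
            RemnantHit("ctg", "3'", 5940, 6000, "+", 60),
        ]
        jqs = extract_junction_queries([contig], hits, flank=3000, nt_len=2000)
        assert not any(j.joined for j in jqs)

    def test_hit_outside_contig_errors(self, rng):
        contig = SequenceRecord(id="ctg", seq=random_seq(rng, 100))
        with pytest.raises(CoordinateError):
            extract_junction_queries([contig],
                                     [RemnantHit("ctg", "5'", 90, 150, "+", 60)])


class TestFlankingAtCoordinate:
    def _db(self, seq="AAACCCGGGTTT"):
        return ReferenceDB([SequenceRecord(id="r", seq=seq)], role="genome")

    def test_hand_indexed_example(self):
        rec = flanking_at_coordinate(self._db(), "r", coordinate=7, half_len=3)
        assert rec.seq == "CCCGGG"

    @pytest.mark.parametrize("half_len,expected_len", [(8, 16), (20, 40)])
    def test_output_length_is_twice_half_len(self, rng, half_len, expected_len):
        db = ReferenceDB([SequenceRecord(id="r", seq=random_seq(rng, 200))],
                         role="genome")
        rec = flanking_at_coordinate(db, "r", coordinate=100, half_len=half_len)
        assert len(rec.seq) == expected_len

    def test_coordinate_too_close_to_end_errors(self):
        with pytest.raises(CoordinateError):
            flanking_at_coordinate(self._db(), "r", coordinate=2, half_len=3)


class TestConsensus:
    def test_minority_at_quarter_enters_with_default_threshold(self):
        res = compute_consensus(["ACGT", "ACGA", "ACGA", "ACGA"], 20)
        assert res.consensus == "ACGW"

    def test_identical_sequences_at_hundred_percent(self):
        res = compute_consensus(["GTCTAGAC"] * 3, 100)
        assert res.consensus == "GTCTAGAC"

    def test_non_identical_at_hundred_percent_errors(self):
        with pytest.raises(ConsensusError):
            compute_consensus(["ACGT", "ACGA"], 100)

    def test_four_way_split_yields_n(self):
        res = compute_consensus(["A", "C", "G", "T"], 20)
        assert res.consensus == "N"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ConsensusError):
            compute_consensus(["ACGT", "ACG"], 20)

    def test_matches_frequency_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            length = int(rng.integers(1, 15))
            seqs = [random_seq(rng, length) for _ in range(n)]
            threshold = float(rng.choice([5, 10, 20, 25, 34, 50, 80]))
            got = compute_consensus(seqs, threshold).consensus
            assert got == consensus_by_frequency(seqs, threshold)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_raising_threshold_never_widens_a_position_set(self, case):
        """Each position's qualifying-nucleotide set shrinks monotonically."""
        rng = np.random.default_rng(case)
        seqs = [random_seq(rng, 6) for _ in range(int(rng.integers(2, 9)))]
        prev = None
        for threshold in (10, 20, 35, 50, 75):
            sets = compute_consensus(seqs, threshold).position_sets
            if prev is not None:
                assert all(s <= p for s, p in zip(sets, prev))
            prev = sets
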