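import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_seq
from ntmap.align import (
    DEFAULT_SCHEME,
    ScoringScheme,
    align_query,
    banded_local_align,
    score_from_cigar,
    trim_query_interval,
)
from ntmap.dna import encode, revcomp
from ntmap.errors import QueryTooShortError
from ntmap.index import Parameters, ReferenceDB
from ntmap.io import SequenceRecord
from oracles import sw_score


def genome_db(*records):
    return ReferenceDB(records, role="genome")


EMPTY_TD = ReferenceDB(role="transposon")
PARAMS = Parameters(nucleus_size=12, number_of_results=100)


class TestScoringScheme:
    def test_default_scores_perfect_sixty_mer_at_sixty(self, rng):
        ref = random_seq(rng, 400)
        q = ref[100:160]
        res = banded_local_align(encode(q), encode(ref), -60, 400)
        assert res is not None and res[0] == 60

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1, mismatch=1)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1, gap_extend=-2)  # open must be <= extend


class TestExtension:
    def test_single_internal_mismatch_costs_two(self, rng):
        ref = random_seq(rng, 500)
        q = list(ref[200:260])
        q[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[30]]
        res = banded_local_align(encode("".join(q)), encode(ref), -60, 500)
        assert res[0] == 58  # 59 matches - 1 mismatch

    def test_cigar_rescoring_reproduces_score(self, rng):
        for trial in range(30):
            ref = random_seq(rng, 400)
            start = int(rng.integers(0, 300))
            q = list(ref[start:start + int(rng.integers(30, 90))])
            for _ in range(int(rng.integers(0, 5))):
                q[int(rng.integers(0, len(q)))] = random_seq(rng, 1)
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(1, len(q)))
                if rng.random() < 0.5:
                    q.insert(p, random_seq(rng, 1))
                else:
                    del q[p]
            res = banded_local_align(encode("".join(q)), encode(ref), -len(q), 400)
            if res is None:
                continue
            score, _, _, cigar = res
            assert score_from_cigar(cigar) == score

    def test_matches_exhaustive_smith_waterman(self, rng):
        """Banded seed extension finds the same optimum as full-matrix DP."""
        for trial in range(20):
            ref = random_seq(rng, 600)
            start = int(rng.integers(0, 400))
            q = list(ref[start:start + 150])
            for _ in range(int(rng.integers(0, 8))):
                q[int(rng.integers(0, len(q)))] = random_seq(rng, 1)
            q = "".join(q)
            query = SequenceRecord(id=f"t{trial}", seq=q)
            subs = align_query(query, genome_db(SequenceRecord(id="r", seq=ref)),
                               EMPTY_TD, PARAMS)
            assert subs, "homologous query must produce a subalignment"
            assert subs[0].score == sw_score(q, ref)


class TestAlignQuery:
    def test_query_against_its_source_is_full_length_and_maximal(self, rng):
        ref = random_seq(rng, 800)
        query = SequenceRecord(id="q", seq=ref[100:400])
        subs = align_query(query, genome_db(SequenceRecord(id="r", seq=ref)),
                           EMPTY_TD, PARAMS)
        best = subs[0]
        assert best.query_interval == (0, 300)
        assert best.reference_interval == (100, 400)
        assert best.score == 300
        assert best.cigar == "300M"

    def test_strand_symmetry(self, rng):
        ref = random_seq(rng, 500)
        q = ref[50:250]
        db = genome_db(SequenceRecord(id="r", seq=ref))
        fwd = align_query(SequenceRecord(id="f", seq=q), db, EMPTY_TD, PARAMS)
        rev = align_query(SequenceRecord(id="r", seq=revcomp(q)), db, EMPTY_TD, PARAMS)
        assert fwd[0].score == rev[0].score
        assert fwd[0].reference_interval == rev[0].reference_interval
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}

    def test_junction_query_hits_both_databases(self, rng):
        genome = random_seq(rng, 2000)
        nt = random_seq(rng, 600)
        jq = genome[500:1000] + nt[:60]  # flank + transposon 5' end
        gd = genome_db(SequenceRecord(id="chr", seq=genome))
        td = ReferenceDB([SequenceRecord(id="NT", seq=nt)], role="transposon")
        subs = align_query(SequenceRecord(id="jq", seq=jq), gd, td, PARAMS)
        origins = {s.origin for s in subs}
        assert origins == {"genome", "transposon"}

    def test_transposon_sixty_mer_covers_the_terminal(self, rng):
        nt = random_seq(rng, 600)
        td = ReferenceDB([SequenceRecord(id="NT", seq=nt)], role="transposon")
        subs = align_query(SequenceRecord(id="q5", seq=nt[:60]),
                           ReferenceDB(role="genome"), td, PARAMS)
        assert subs[0].origin == "transposon"
        assert subs[0].reference_interval == (0, 60)
        assert subs[0].score == 60

    def test_query_shorter_than_nucleus_errors(self, small_db):
        with pytest.raises(QueryTooShortError):
            align_query(SequenceRecord(id="q", seq="ACGTACGT"), small_db,
                        EMPTY_TD, Parameters(nucleus_size=20))


class TestTrim:
    def _sub(self, rng):
        ref = random_seq(rng, 300)
        q = ref[40:160]
        db = genome_db(SequenceRecord(id="r", seq=ref))
        return align_query(SequenceRecord(id="q", seq=q), db, EMPTY_TD, PARAMS)[0]

    def test_trim_shrinks_interval_and_rescoring_agrees(self, rng):
        sub = self._sub(rng)
        cut = trim_query_interval(sub, new_q_end=100)
        assert cut.q_end == 100
        assert cut.score == score_from_cigar(cut.cigar)
        assert cut.r_end - cut.r_start <= sub.r_end - sub.r_start

    def test_trim_to_nothing_returns_none(self, rng):
        sub = self._sub(rng)
        assert trim_query_interval(sub, new_q_end=sub.q_start) is None

    @given(cut=st.integers(min_value=1, max_value=119))
    def test_trim_is_consistent_for_any_cut(self, cut):
        rng = np.random.default_rng(7)
        sub = self._sub(rng)
        left = trim_query_interval(sub, new_q_end=cut)
        if left is not None:
            assert left.q_end <= cut
            assert left.score == score_from_cigar(left.cigar)
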