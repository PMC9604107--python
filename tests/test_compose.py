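import numpy as np
import pytest

from conftest import random_seq
from ntmap.align import Subalignment
from ntmap.annotate import Feature
from ntmap.compose import (
    BONUS,
    apply_bonus,
    compose,
    pick_placements,
    ranking_key,
    suppress_covered_junctions,
)
from ntmap.index import Parameters, ReferenceDB
from ntmap.io import SequenceRecord
from oracles import enumerate_composites

QLEN = 10_000


def sub(qs, qe, rs, origin="genome", rid="chr", strand="+", score=None, cigar=None):
    length = qe - qs
    return Subalignment(
        query_id="q", query_interval=(qs, qe), reference_id=rid,
        reference_interval=(rs, rs + length), origin=origin, strand=strand,
        score=score if score is not None else length,
        cigar=cigar or f"{length}M", query_length=QLEN,
    )


PARAMS = Parameters(number_of_results=1000)


class TestGenomicMerging:
    @pytest.mark.parametrize("gap,merged", [(0, True), (150, True), (200, True),
                                            (201, False), (500, False)])
    def test_reference_gap_rule(self, gap, merged):
        a = sub(0, 1000, 0)
        b = sub(1000, 2000, 1000 + gap)
        top = compose([a, b], PARAMS)[0]
        assert (len(top.parts) == 2) == merged
        if merged:
            assert top.total_score == 2000

    def test_overlapping_genomic_coordinates_never_merge(self):
        a = sub(0, 1000, 0)
        b = sub(1000, 2000, 950)  # reference overlap: genomic distance < 0
        assert all(len(c.parts) == 1 for c in compose([a, b], PARAMS))

    def test_minus_strand_pair_merges_in_reference_order(self):
        a = sub(0, 1000, 1100, strand="-")
        b = sub(1000, 2000, 50, strand="-")  # downstream on query = upstream on ref
        top = compose([a, b], PARAMS)[0]
        assert len(top.parts) == 2

    def test_different_references_stay_separate(self):
        a = sub(0, 1000, 0, rid="chr1")
        b = sub(1000, 2000, 1000, rid="chr2")
        assert all(len(c.parts) == 1 for c in compose([a, b], PARAMS))


class TestJunctionComposition:
    def test_genome_plus_transposon_scores_add(self):
        blue = sub(0, 3000, 5000)
        red = sub(3000, 3060, 0, origin="transposon", rid="NT")
        top = compose([blue, red], PARAMS)[0]
        assert top.classification == "junction"
        assert top.total_score == 3060

    def test_red_red_overlapping_transposon_coordinates_compose(self):
        # self-insertion: both parts cover the transposon 5' end
        r1 = sub(0, 500, 0, origin="transposon", rid="NT")
        r2 = sub(500, 900, 0, origin="transposon", rid="NT")
        top = compose([r1, r2], PARAMS)[0]
        assert len(top.parts) == 2
        assert top.classification == "transposon_internal"

    def test_gap_rule_not_applied_across_origins(self):
        blue = sub(0, 1000, 0)
        red = sub(1000, 1500, 5000, origin="transposon", rid="NT")
        blue2 = sub(1500, 2500, 90_000)  # far from blue on the reference
        top = compose([blue, red, blue2], PARAMS)[0]
        assert len(top.parts) == 3  # transposon part lifts all restrictions


class TestBruteForceEquivalence:
    def _random_subs(self, rng, n):
        subs = []
        qpos = 0
        for _ in range(n):
            qpos += int(rng.integers(0, 50))
            length = int(rng.integers(30, 300))
            origin = "genome" if rng.random() < 0.7 else "transposon"
            rid = "chr" if origin == "genome" else "NT"
            rs = int(rng.integers(0, 3000))
            subs.append(sub(qpos, qpos + length, rs, origin=origin, rid=rid))
            qpos += length
        order = rng.permutation(len(subs))
        return [subs[i] for i in order]

    def test_output_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for trial in range(40):
            subs = self._random_subs(rng, int(rng.integers(2, 7)))
            got = compose(subs, PARAMS)
            expected = enumerate_composites(subs, PARAMS.max_genomic_gap)
            got_set = {(c.total_score, tuple(id(p) for p in c.parts)) for c in got}
            exp_set = {(s, tuple(id(p) for p in parts)) for s, parts in expected}
            assert got_set == exp_set, f"trial {trial}"

    def test_score_conservation_and_rule_validity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            subs = self._random_subs(rng, 6)
            for c in compose(subs, PARAMS):
                assert c.total_score == sum(p.score for p in c.parts)
                for a, b in zip(c.parts, c.parts[1:]):
                    assert b.q_start >= a.q_end
                    if a.origin == b.origin == "genome":
                        gap = (b.r_start - a.r_end if a.strand == "+"
                               else a.r_start - b.r_end)
                        assert 0 <= gap <= PARAMS.max_genomic_gap


class TestBonus:
    def _junction(self, tir_cigar="60M"):
        blue = sub(0, 3000, 5000)
        red = sub(3000, 3060, 0, origin="transposon", rid="NT", cigar=tir_cigar,
                  score=60)
        return compose([blue, red], PARAMS)[0]

    def _tirs(self):
        return {"NT": [Feature("NT", "NT_TIR5", "TIR5", (0, 31)),
                       Feature("NT", "NT_TIR3", "TIR3", (1969, 2000))]}

    def test_intact_tir_at_border_gains_exactly_500(self):
        c = self._junction()
        td = ReferenceDB(role="transposon")
        boosted = apply_bonus(c, td, self._tirs(), Parameters(bonus=True))
        assert boosted.total_score == c.total_score + BONUS
        assert boosted.bonus_applied

    def test_bonus_off_leaves_score_unchanged(self):
        c = self._junction()
        same = apply_bonus(c, ReferenceDB(role="transposon"), self._tirs(),
                           Parameters(bonus=False))
        assert same.total_score == c.total_score and not same.bonus_applied

    def test_degraded_tir_gets_no_bonus(self):
        # identity over the 31-nt TIR interval is 15/31 < 90%
        c = self._junction(tir_cigar="15M16X29M")
        same = apply_bonus(c, ReferenceDB(role="transposon"), self._tirs(),
                           Parameters(bonus=True))
        assert not same.bonus_applied

    def test_half_deleted_tir_gets_no_bonus(self):
        # transposon part starts 16 nt into the TIR: coverage 15/31 < 90%
        blue = sub(0, 3000, 5000)
        red = sub(3000, 3044, 16, origin="transposon", rid="NT")
        c = compose([blue, red], PARAMS)[0]
        same = apply_bonus(c, ReferenceDB(role="transposon"), self._tirs(),
                           Parameters(bonus=True))
        assert not same.bonus_applied


class TestSuppression:
    def test_fully_blue_cover_excludes_equal_scoring_junction(self):
        full_blue = compose([sub(0, 3060, 5000)], PARAMS)[0]
        junction = compose([sub(0, 3000, 5000),
                            sub(3000, 3060, 0, origin="transposon", rid="NT")],
                           PARAMS)[0]
        kept = suppress_covered_junctions([full_blue, junction])
        assert kept == [full_blue]

    def test_higher_scoring_junction_survives(self):
        partial_blue = compose([sub(0, 3000, 5000)], PARAMS)[0]
        junction = compose([sub(0, 3000, 5000),
                            sub(3000, 3060, 0, origin="transposon", rid="NT")],
                           PARAMS)[0]
        kept = suppress_covered_junctions([partial_blue, junction])
        assert junction in kept


class TestPickingDepth:
    def _two_placements(self):
        # one query span, two identical loci in one reference
        c1 = compose([sub(0, 300, 1000)], PARAMS)[0]
        c2 = compose([sub(0, 300, 21_000)], PARAMS)[0]
        return [c1, c2]

    @pytest.mark.parametrize("depth,expected", [(1, 1), (2, 2), (10_000, 2)])
    def test_depth_limits_equal_placements(self, depth, expected):
        got = pick_placements(self._two_placements(), Parameters(picking_depth=depth))
        assert len(got) == expected
        assert [c.placement_rank for c in got] == list(range(1, expected + 1))

    def test_placements_on_different_references_not_limited(self):
        c1 = compose([sub(0, 300, 1000, rid="ctg1")], PARAMS)[0]
        c2 = compose([sub(0, 300, 1000, rid="ctg2")], PARAMS)[0]
        got = pick_placements([c1, c2], Parameters(picking_depth=1))
        assert len(got) == 2
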