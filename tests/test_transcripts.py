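"""Candidate enumeration, containment counting and the sequential ratio filter."""

import numpy as np
import pytest

from conftest import make_reads, random_read_set
from proktx.boundaries import LEFT, RIGHT, BoundarySite, SiteGroup
from proktx.regions import CTRegion, build_ct_regions
from proktx.transcripts import (
    DISCARDED,
    RETAINED,
    CandidateTranscript,
    PredictionParams,
    assign_exclusive,
    count_containment,
    enumerate_candidates,
    filter_by_ratio,
    predict_transcripts,
)


def _groups(side, positions):
    return [SiteGroup(side, p, (BoundarySite(p, side, 99),)) for p in positions]


def _candidates(pairs, region_id="rg"):
    cands = [CandidateTranscript(region_id, l, r) for l, r in pairs]
    cands.sort(key=lambda c: (c.length, c.left))
    return cands


class TestEnumerate:
    def test_cartesian_product(self):
        cands = enumerate_candidates(
            _groups(LEFT, [0, 100]), _groups(RIGHT, [500, 700, 900]), "rg", min_length=50
        )
        assert len(cands) == 6

    def test_inverted_pairs_excluded(self):
        cands = enumerate_candidates(
            _groups(LEFT, [500]), _groups(RIGHT, [400, 800]), "rg", min_length=50
        )
        assert [(c.left, c.right) for c in cands] == [(500, 800)]

    def test_min_length_excludes_micro_candidates(self):
        cands = enumerate_candidates(
            _groups(LEFT, [0]), _groups(RIGHT, [30, 80]), "rg", min_length=50
        )
        assert [(c.left, c.right) for c in cands] == [(0, 80)]

    def test_sorted_by_length_then_left(self):
        cands = enumerate_candidates(
            _groups(LEFT, [0, 200]), _groups(RIGHT, [500, 700]), "rg", min_length=50
        )
        assert [(c.length, c.left) for c in cands] == [
            (300, 200), (500, 0), (500, 200), (700, 0),
        ]


class TestContainment:
    def test_read_counts_toward_every_container(self):
        cands = _candidates([(100, 400), (50, 600)])
        count_containment(cands, make_reads([(100, 400)]), slack=0)
        assert [c.n_tot for c in cands] == [1, 1]

    def test_slack_rule(self):
        reads = make_reads([(95, 400)])
        strict = _candidates([(100, 400)])
        count_containment(strict, reads, slack=0)
        assert strict[0].n_tot == 0
        slacked = _candidates([(100, 400)])
        count_containment(slacked, reads, slack=10)
        assert slacked[0].n_tot == 1

    def test_no_reads(self):
        cands = _candidates([(0, 100), (0, 200)])
        count_containment(cands, [], slack=0)
        assert [c.n_tot for c in cands] == [0, 0]


class TestAssignExclusive:
    def test_shortest_container_wins(self):
        cands = _candidates([(100, 400), (50, 600)])
        homes = assign_exclusive(cands, make_reads([(120, 380)]), slack=0)
        assert cands[homes[0]].length == 300

    def test_equal_length_tie_breaks_by_left(self):
        cands = _candidates([(0, 500), (100, 600)])
        homes = assign_exclusive(cands, make_reads([(150, 450)]), slack=0)
        assert cands[homes[0]].left == 0

    def test_sole_container(self):
        cands = _candidates([(0, 500)])
        homes = assign_exclusive(cands, make_reads([(10, 490)]), slack=0)
        assert homes == [0]

    def test_discarded_candidates_are_skipped(self):
        cands = _candidates([(100, 400), (50, 600)])
        cands[0].status = DISCARDED
        homes = assign_exclusive(cands, make_reads([(120, 380)]), slack=0)
        assert cands[homes[0]].length == 550


class TestFilterByRatio:
    def test_single_candidate_keeps_everything(self):
        cands = _candidates([(0, 500)])
        reads = make_reads([(0, 500)] * 7)
        count_containment(cands, reads, slack=0)
        filter_by_ratio(cands, reads, slack=0, ratio_threshold=0.2)
        assert cands[0].status == RETAINED
        assert cands[0].n_ea == cands[0].n_tot == 7

    def test_nested_pair_both_retained(self):
        # short candidate inside long; 10 reads live only in the long extra
        # span, 1 read inside the short one
        cands = _candidates([(100, 400), (0, 1000)])
        reads = make_reads([(150, 350)]) + make_reads([(450, 900)] * 10)
        count_containment(cands, reads, slack=0)
        filter_by_ratio(cands, reads, slack=0, ratio_threshold=0.2)
        short, long_ = cands
        assert (short.status, short.n_tot, short.n_ea) == (RETAINED, 1, 1)
        assert (long_.status, long_.n_tot, long_.n_ea) == (RETAINED, 11, 10)

    def test_low_ratio_long_discarded_and_orphan_dropped(self):
        cands = _candidates([(100, 400), (0, 1000)])
        reads = make_reads([(150, 350)] * 9) + make_reads([(50, 950)])
        count_containment(cands, reads, slack=0)
        homes = filter_by_ratio(cands, reads, slack=0, ratio_threshold=0.2)
        short, long_ = cands
        assert short.status == RETAINED and short.ratio == 1.0
        assert long_.status == DISCARDED and long_.n_ea == 0
        assert homes[-1] is None  # the spanning read has no surviving container

    def test_reads_rehomed_support_longer_candidate(self):
        # the mid-length candidate fails (most of its reads home at the
        # shortest one); its lone read immediately re-homes to the longest
        # candidate and is counted there
        cands = _candidates([(200, 300), (180, 400), (0, 1000)])
        reads = (
            make_reads([(200, 300)] * 5)   # exclusive to the shortest
            + make_reads([(185, 395)])     # mid and long only
            + make_reads([(50, 950)] * 2)  # long only
        )
        count_containment(cands, reads, slack=0)
        homes = filter_by_ratio(cands, reads, slack=0, ratio_threshold=0.2)
        short, mid, long_ = cands
        assert (short.status, short.n_ea, short.n_tot) == (RETAINED, 5, 5)
        assert (mid.status, mid.n_tot) == (DISCARDED, 6)  # 1/6 < 0.2
        assert (long_.status, long_.n_tot, long_.n_ea) == (RETAINED, 8, 3)
        assert cands[homes[5]] is long_  # the re-homed read

    def test_retained_ratios_meet_threshold_on_random_instances(self, rng):
        for _ in range(30):
            lefts = sorted(int(p) for p in rng.integers(0, 400, rng.integers(1, 4)))
            rights = sorted(int(p) for p in rng.integers(500, 900, rng.integers(1, 4)))
            cands = _candidates([(l, r) for l in lefts for r in rights])
            reads = random_read_set(rng, span=1000, max_reads=60)
            count_containment(cands, reads, slack=50)
            homes = filter_by_ratio(cands, reads, slack=50, ratio_threshold=0.2)
            retained_idx = [i for i, c in enumerate(cands) if c.status == RETAINED]
            for i in retained_idx:
                assert cands[i].n_tot > 0
                assert cands[i].n_ea / cands[i].n_tot >= 0.2
            # every assigned read homes at exactly one retained candidate
            for h in homes:
                assert h is None or cands[h].status == RETAINED
            assert sum(cands[i].n_ea for i in retained_idx) == sum(
                1 for h in homes if h is not None
            )

    def test_raising_threshold_never_increases_retained_count(self, rng):
        for _ in range(20):
            lefts = sorted(int(p) for p in rng.integers(0, 400, rng.integers(1, 4)))
            rights = sorted(int(p) for p in rng.integers(500, 900, rng.integers(1, 4)))
            reads = random_read_set(rng, span=1000, max_reads=60)
            counts = []
            for thr in (0.05, 0.2, 0.5, 0.9):
                cands = _candidates([(l, r) for l in lefts for r in rights])
                count_containment(cands, reads, slack=50)
                filter_by_ratio(cands, reads, slack=50, ratio_threshold=thr)
                counts.append(sum(1 for c in cands if c.status == RETAINED))
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPredictTranscripts:
    def test_single_pileup_gives_one_transcript(self):
        region = build_ct_regions(make_reads([(1000, 2500)] * 30))[0]
        txs = predict_transcripts(region, PredictionParams())
        assert [(t.start, t.end, t.n_tot, t.n_ea) for t in txs] == [(1000, 2500, 30, 30)]
        assert txs[0].ratio == 1.0

    def test_two_pileups_sharing_a_region_give_two_transcripts(self):
        reads = make_reads([(0, 500)] * 30 + [(1500, 2000)] * 30)
        region = CTRegion("chr1", 0, 2000, "+", tuple(sorted(
            reads, key=lambda r: (r.start, r.end, r.read_id))))
        txs = predict_transcripts(region, PredictionParams())
        assert [(t.start, t.end) for t in txs] == [(0, 500), (1500, 2000)]

    def test_region_too_short_for_any_candidate(self):
        region = build_ct_regions(make_reads([(100, 130)] * 10))[0]
        assert predict_transcripts(region, PredictionParams(min_length=50)) == []

    def test_deterministic_under_read_input_order(self, rng):
        reads = random_read_set(rng, span=3000, max_reads=200)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        def run(rs):
            out = []
            for region in build_ct_regions(rs):
                out.extend(predict_transcripts(region, PredictionParams()))
            return [(t.start, t.end, t.n_tot, t.n_ea) for t in out]
        assert run(reads) == run(shuffled)

    def test_transcript_ids_are_stable_and_unique(self):
        region = build_ct_regions(make_reads([(0, 1000)] * 25))[0]
        txs = predict_transcripts(region, PredictionParams())
        assert [t.transcript_id for t in txs] == [f"{region.region_id}.t1"]
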