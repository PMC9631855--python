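import math

import numpy as np
import pytest

from fogcombine import (
    CHECK_TRIGGER,
    CHECK_TYPE,
    Color,
    CombineConfig,
    Correction,
    GrayClass,
    Outcome,
    Phenotype,
    Provenance,
    discussion_items,
    flag_label_disagreements,
    merge_episodes,
    partition_timeline,
    resolve,
)

import oracle
from conftest import make_track

INCLUDE = CombineConfig(2000, Correction.INCLUDE)
EXCLUDE = CombineConfig(2000, Correction.EXCLUDE)


def pair(a_intervals, b_intervals, duration=10_000, **kw):
    a = make_track(a_intervals, rater_id="rater1", trial_duration_ms=duration, **kw)
    b = make_track(b_intervals, rater_id="rater2", trial_duration_ms=duration, **kw)
    return a, b


def seg_tuples(partition):
    return [(s.begin_ms, s.end_ms, s.color.value, s.gray_class.value) for s in partition.segments]


class TestPartitionTimeline:
    def test_identical_tracks_single_black(self):
        a, b = pair([(1000, 4000)], [(1000, 4000)])
        p = partition_timeline(a, b)
        assert seg_tuples(p) == [
            (0, 1000, "white", "not-applicable"),
            (1000, 4000, "black", "not-applicable"),
            (4000, 10_000, "white", "not-applicable"),
        ]

    def test_leading_gray_preceding(self):
        a, b = pair([(1000, 4000)], [(1500, 4000)])
        p = partition_timeline(a, b)
        assert (1000, 1500, "gray", "preceding") in seg_tuples(p)
        assert (1500, 4000, "black", "not-applicable") in seg_tuples(p)

    def test_lone_rater_episode_isolated(self):
        a, b = pair([(1000, 2000)], [])
        p = partition_timeline(a, b)
        assert (1000, 2000, "gray", "isolated") in seg_tuples(p)

    def test_partition_covers_trial_and_alternates(self):
        a, b = pair([(0, 2000), (5000, 6000)], [(1000, 3000)])
        p = partition_timeline(a, b)
        assert p.segments[0].begin_ms == 0
        assert p.segments[-1].end_ms == 10_000
        for cur, nxt in zip(p.segments, p.segments[1:]):
            assert cur.end_ms == nxt.begin_ms
            assert cur.color != nxt.color

    def test_mismatched_metadata_rejected(self):
        a = make_track([(0, 1000)], rater_id="rater1", trial_id="t1", trial_duration_ms=5000)
        b = make_track([(0, 1000)], rater_id="rater2", trial_id="t2", trial_duration_ms=5000)
        with pytest.raises(ValueError, match="trial_id"):
            partition_timeline(a, b)
        b2 = make_track([(0, 1000)], rater_id="rater2", trial_id="t1", trial_duration_ms=6000)
        with pytest.raises(ValueError, match="duration"):
            partition_timeline(a, b2)

    def test_unnormalized_track_rejected(self):
        a = make_track([(0, 1000), (500, 2000)], trial_duration_ms=5000)
        b = make_track([], trial_duration_ms=5000)
        with pytest.raises(ValueError, match="normalize"):
            partition_timeline(a, b)

    def test_mixed_gray_coverage_recorded(self):
        # a's episode abuts b's: one maximal gray with split coverage
        a, b = pair([(1000, 2000)], [(2000, 3000)])
        p = partition_timeline(a, b)
        grays = [s for s in p.segments if s.color is Color.GRAY]
        assert len(grays) == 1
        g = grays[0]
        assert (g.begin_ms, g.end_ms) == (1000, 3000)
        assert g.a_cover_ms == 1000 and g.b_cover_ms == 1000


class TestClassifyGray:
    def test_gray_before_black_is_preceding(self):
        a, b = pair([(1000, 4000)], [(2000, 4000)])
        p = partition_timeline(a, b)
        assert (1000, 2000, "gray", "preceding") in seg_tuples(p)

    def test_gray_after_black_is_following(self):
        a, b = pair([(1000, 4000)], [(1000, 5000)])
        p = partition_timeline(a, b)
        assert (4000, 5000, "gray", "following") in seg_tuples(p)

    def test_gray_between_blacks_is_enclosed(self):
        a, b = pair([(1000, 2000), (2500, 4000)], [(1000, 4000)])
        p = partition_timeline(a, b)
        assert (2000, 2500, "gray", "enclosed") in seg_tuples(p)

    def test_gray_between_whites_is_isolated(self):
        a, b = pair([(3000, 4000)], [])
        p = partition_timeline(a, b)
        assert (3000, 4000, "gray", "isolated") in seg_tuples(p)


def outcomes(resolved):
    return [(s.begin_ms, s.end_ms, s.outcome.value) for s in resolved]


class TestResolve:
    def test_short_gray_include(self):
        a, b = pair([(1000, 4000)], [(1500, 4000)])
        res = resolve(partition_timeline(a, b), INCLUDE)
        assert (1000, 1500, "FOG") in outcomes(res)

    def test_short_gray_exclude(self):
        a, b = pair([(1000, 4000)], [(1500, 4000)])
        res = resolve(partition_timeline(a, b), EXCLUDE)
        assert (1000, 1500, "no_FOG") in outcomes(res)

    @pytest.mark.parametrize("cfg", [INCLUDE, EXCLUDE])
    def test_long_gray_discussion_either_correction(self, cfg):
        a, b = pair([(1000, 7000)], [(4000, 7000)])
        res = resolve(partition_timeline(a, b), cfg)
        assert (1000, 4000, "discussion") in outcomes(res)

    @pytest.mark.parametrize("cfg", [INCLUDE, EXCLUDE])
    def test_isolated_always_discussion_even_if_short(self, cfg):
        a, b = pair([(1000, 1100)], [])
        res = resolve(partition_timeline(a, b), cfg)
        assert (1000, 1100, "discussion") in outcomes(res)
        assert res[1].provenance is Provenance.GRAY_ISOLATED

    def test_tolerance_tie_resolves(self):
        # exactly 2000 ms is still "not longer than" the tolerance
        a, b = pair([(1000, 6000)], [(3000, 6000)])
        res = resolve(partition_timeline(a, b), INCLUDE)
        assert (1000, 3000, "FOG") in outcomes(res)

    def test_tolerance_boundary_plus_one_discussed(self):
        a, b = pair([(999, 6000)], [(3000, 6000)])  # 2001 ms gray
        res = resolve(partition_timeline(a, b), INCLUDE)
        assert (999, 3000, "discussion") in outcomes(res)

    def test_zero_tolerance_all_nonisolated_gray_discussed(self):
        a, b = pair([(1000, 4000)], [(1500, 4000)])
        res = resolve(partition_timeline(a, b), CombineConfig(0, Correction.INCLUDE))
        assert (1000, 1500, "discussion") in outcomes(res)

    def test_infinite_tolerance_resolves_all_nonisolated(self):
        a, b = pair([(1000, 7000)], [(4000, 7000)])
        res = resolve(
            partition_timeline(a, b), CombineConfig(math.inf, Correction.INCLUDE)
        )
        assert (1000, 4000, "FOG") in outcomes(res)

    def test_included_gray_inherits_labels_from_black(self):
        a, b = pair(
            [(1000, 4000, "trembling", "FOG_Target")],
            [(1500, 4000, "trembling", "FOG_Target")],
        )
        res = resolve(partition_timeline(a, b), INCLUDE)
        gray = next(s for s in res if s.provenance is Provenance.GRAY_INCLUDED)
        assert gray.phenotype is Phenotype.TREMBLING
        assert gray.trigger == "FOG_Target"

    def test_enclosed_gray_inherits_from_earlier_black(self):
        a = make_track(
            [(1000, 2000, "trembling"), (2500, 4000, "akinesia")],
            rater_id="rater1", trial_duration_ms=10_000,
        )
        b = make_track([(1000, 4000, "trembling")], rater_id="rater2", trial_duration_ms=10_000)
        res = resolve(partition_timeline(a, b), INCLUDE)
        gray = next(s for s in res if s.provenance is Provenance.GRAY_INCLUDED)
        # earlier black is [1000,2000): both raters say trembling there
        assert gray.phenotype is Phenotype.TREMBLING

    def test_resolution_is_segmentwise_aligned(self):
        a, b = pair([(1000, 4000)], [(1500, 5000)])
        p = partition_timeline(a, b)
        res = resolve(p, EXCLUDE)
        assert [(s.begin_ms, s.end_ms) for s in res] == [
            (s.begin_ms, s.end_ms) for s in p.segments
        ]


class TestMergeEpisodes:
    def test_enclosed_gray_included_fuses_neighbors(self):
        a, b = pair([(0, 2000), (2500, 5000)], [(0, 5000)], duration=6000)
        res = resolve(partition_timeline(a, b), INCLUDE)
        eps = merge_episodes(res)
        assert [(e.begin_ms, e.end_ms) for e in eps] == [(0, 5000)]

    def test_enclosed_gray_excluded_leaves_two(self):
        a, b = pair([(0, 2000), (2500, 5000)], [(0, 5000)], duration=6000)
        res = resolve(partition_timeline(a, b), EXCLUDE)
        eps = merge_episodes(res)
        assert [(e.begin_ms, e.end_ms) for e in eps] == [(0, 2000), (2500, 5000)]

    def test_no_fog_empty_list(self):
        a, b = pair([], [], duration=5000)
        assert merge_episodes(resolve(partition_timeline(a, b), INCLUDE)) == []

    def test_conflicting_segment_labels_flag_check_type(self):
        # constructed directly: two FOG segments with different agreed labels
        from fogcombine import ResolvedSegment

        segs = [
            ResolvedSegment(0, 2000, Outcome.FOG, Provenance.BLACK,
                            phenotype=Phenotype.TREMBLING, trigger="FOG_Target"),
            ResolvedSegment(2000, 2500, Outcome.FOG, Provenance.GRAY_INCLUDED,
                            phenotype=Phenotype.TREMBLING),
            ResolvedSegment(2500, 5000, Outcome.FOG, Provenance.BLACK,
                            phenotype=Phenotype.AKINESIA, trigger="FOG_Doorway"),
        ]
        eps = merge_episodes(segs)
        assert len(eps) == 1
        assert CHECK_TYPE in eps[0].flags
        assert CHECK_TRIGGER in eps[0].flags
        assert eps[0].phenotype is Phenotype.UNSPECIFIED
        assert eps[0].trigger is None

    def test_fused_episode_inherits_rater_disagreement_flag(self):
        # a splits what b sees as one episode with a different phenotype tail
        a = make_track(
            [(0, 2000, "trembling"), (2500, 5000, "akinesia")],
            rater_id="rater1", trial_duration_ms=6000,
        )
        b = make_track([(0, 5000, "trembling")], rater_id="rater2", trial_duration_ms=6000)
        res = resolve(partition_timeline(a, b), INCLUDE)
        eps = flag_label_disagreements(a, b, merge_episodes(res))
        assert [(e.begin_ms, e.end_ms) for e in eps] == [(0, 5000)]
        assert CHECK_TYPE in eps[0].flags


class TestFlagLabelDisagreements:
    def _episodes(self, a, b, cfg=EXCLUDE):
        res = resolve(partition_timeline(a, b), cfg)
        return flag_label_disagreements(a, b, merge_episodes(res))

    def test_agreeing_labels_no_flags(self):
        a, b = pair(
            [(1000, 4000, "trembling", "FOG_Target")],
            [(1000, 4000, "trembling", "FOG_Target")],
        )
        eps = self._episodes(a, b)
        assert eps[0].flags == frozenset()
        assert eps[0].phenotype is Phenotype.TREMBLING
        assert eps[0].trigger == "FOG_Target"

    def test_phenotype_disagreement_flags_check_type(self):
        a, b = pair([(1000, 4000, "trembling")], [(1000, 4000, "akinesia")])
        eps = self._episodes(a, b)
        assert CHECK_TYPE in eps[0].flags
        assert CHECK_TRIGGER not in eps[0].flags

    def test_trigger_disagreement_flags_check_trigger(self):
        a, b = pair(
            [(1000, 4000, "trembling", "FOG_Doorway")],
            [(1000, 4000, "trembling", "FOG_Target")],
        )
        eps = self._episodes(a, b)
        assert CHECK_TRIGGER in eps[0].flags
        assert CHECK_TYPE not in eps[0].flags


class TestDiscussionItems:
    def test_items_listed_with_reason(self):
        a, b = pair([(1000, 2000)], [(5000, 9000)])
        res = resolve(partition_timeline(a, b), EXCLUDE)
        items = discussion_items(res, "trial")
        assert len(items) == 2
        assert all(i["reason"] == "gray-isolated->discussion" for i in items)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_fixture_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = oracle.random_tracks(rng)
        tol = int(rng.integers(0, 2500))
        corr = rng.choice(["include", "exclude"])
        p = partition_timeline(a, b)

        expected = oracle.oracle_segments(a, b)
        assert [(s.begin_ms, s.end_ms, s.color.value, s.gray_class.value)
                for s in p.segments] == [
            (s["begin"], s["end"], s["color"], s["gray_class"]) for s in expected
        ]
        assert [(s.a_cover_ms, s.b_cover_ms) for s in p.segments] == [
            (s["a_cover"], s["b_cover"]) for s in expected
        ]

        res = resolve(p, CombineConfig(tol, Correction(corr)))
        got = oracle.resolved_to_array(res, a.trial_duration_ms)
        want = oracle.oracle_resolve(a, b, tol, corr)
        assert (got == want).all()

        eps = merge_episodes(res)
        assert [(e.begin_ms, e.end_ms) for e in eps] == oracle.oracle_episodes(want)


class TestProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_conservation_and_symmetry(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a, b = oracle.random_tracks(rng)
        p = partition_timeline(a, b)
        assert sum(s.duration_ms for s in p.segments) == a.trial_duration_ms

        q = partition_timeline(b, a)
        assert [(s.begin_ms, s.end_ms, s.color, s.gray_class) for s in p.segments] == [
            (s.begin_ms, s.end_ms, s.color, s.gray_class) for s in q.segments
        ]
        for cfg in (INCLUDE, EXCLUDE):
            assert outcomes(resolve(p, cfg)) == outcomes(resolve(q, cfg))
            assert [(e.begin_ms, e.end_ms) for e in merge_episodes(resolve(p, cfg))] == [
                (e.begin_ms, e.end_ms) for e in merge_episodes(resolve(q, cfg))
            ]

    @pytest.mark.parametrize("seed", range(25))
    def test_correction_monotonicity(self, seed):
        rng = np.random.default_rng(2000 + seed)
        a, b = oracle.random_tracks(rng)
        p = partition_timeline(a, b)
        tol = int(rng.integers(0, 3000))
        inc = oracle.resolved_to_array(
            resolve(p, CombineConfig(tol, Correction.INCLUDE)), a.trial_duration_ms
        )
        exc = oracle.resolved_to_array(
            resolve(p, CombineConfig(tol, Correction.EXCLUDE)), a.trial_duration_ms
        )
        assert ((exc == oracle.OUT_FOG) <= (inc == oracle.OUT_FOG)).all()

    @pytest.mark.parametrize("seed", range(25))
    def test_tolerance_monotonicity(self, seed):
        rng = np.random.default_rng(3000 + seed)
        a, b = oracle.random_tracks(rng)
        p = partition_timeline(a, b)
        prev = None
        for tol in (0, 500, 1000, 2000, 5000, math.inf):
            res = resolve(p, CombineConfig(tol, Correction.EXCLUDE))
            disc = sum(s.duration_ms for s in res if s.outcome is Outcome.DISCUSSION)
            if prev is not None:
                assert disc <= prev
            prev = disc
        # at infinite tolerance only isolated grays remain in discussion
        res = resolve(p, CombineConfig(math.inf, Correction.EXCLUDE))
        assert all(
            s.provenance is Provenance.GRAY_ISOLATED
            for s in res if s.outcome is Outcome.DISCUSSION
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_identity(self, seed):
        rng = np.random.default_rng(4000 + seed)
        a, _ = oracle.random_tracks(rng)
        b = make_track(
            [(e.begin_ms, e.end_ms) for e in a.episodes],
            rater_id="rater2", trial_id="t", trial_duration_ms=a.trial_duration_ms,
        )
        p = partition_timeline(a, b)
        assert all(s.color is not Color.GRAY for s in p.segments)
        res = resolve(p, EXCLUDE)
        assert all(s.outcome is not Outcome.DISCUSSION for s in res)
        eps = merge_episodes(res)
        assert [(e.begin_ms, e.end_ms) for e in eps] == [
            (e.begin_ms, e.end_ms) for e in a.episodes
        ]


class TestCombineConfig:
    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            CombineConfig(-1)

    def test_correction_coerced_from_string(self):
        assert CombineConfig(2000, "include").correction is Correction.INCLUDE
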