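import math
from collections import Counter

import numpy as np
import pytest

from touchtask.agents import FeatureRLAgent, FeatureRLParams, OmniscientAgent
from touchtask.stimulus_space import build_feature_space
from touchtask.task_engine import (
    GridConfig,
    LearningConfig,
    SearchConfig,
    TaskConfigError,
    ThrLadderConfig,
    ThrLevel,
    ThrState,
    TrialResult,
    TrialSpec,
    TrialTiming,
    classify_touch,
    default_thr_ladder,
    generate_block_defs,
    generate_learning_session,
    generate_search_session,
    grid_intersections,
    place_on_grid,
    run_session,
    run_trial,
    thr_next_level,
)


def search_plan(space, seed=0, **kwargs):
    return generate_search_session(
        space, SearchConfig(**kwargs), np.random.default_rng(seed)
    )


class TestSearchSessionGeneration:
    def test_default_run_structure(self, space):
        plan = search_plan(space)
        for run in (0, 1):
            kinds = Counter(t.task_kind for t in plan.trials if t.block_id == run)
            assert kinds["search_init"] == 10
            assert kinds["search_test"] == 100

    def test_stratified_policy_exact_counts(self, space):
        plan = search_plan(space)
        for run in (0, 1):
            sizes = Counter(
                t.set_size
                for t in plan.trials
                if t.block_id == run and t.task_kind == "search_test"
            )
            assert sizes == {3: 25, 6: 25, 9: 25, 12: 25}

    def test_one_fixed_target_per_run(self, space):
        plan = search_plan(space)
        for run in (0, 1):
            targets = {
                t.stimuli[t.target_index][0]
                for t in plan.trials
                if t.block_id == run
            }
            assert len(targets) == 1

    def test_init_trials_show_target_alone(self, space):
        plan = search_plan(space)
        for t in plan.trials:
            if t.task_kind == "search_init":
                assert t.n_stimuli == 1
                assert t.set_size == 0

    def test_determinism(self, space):
        assert search_plan(space, seed=42).trials == search_plan(space, seed=42).trials

    def test_different_seeds_differ(self, space):
        assert search_plan(space, seed=1).trials != search_plan(space, seed=2).trials

    def test_iid_policy(self, space):
        plan = search_plan(space, set_size_policy="iid", n_runs=1)
        sizes = {t.set_size for t in plan.trials if t.task_kind == "search_test"}
        assert sizes <= {3, 6, 9, 12}

    def test_delays_within_configured_range(self, space):
        plan = search_plan(space, n_runs=1)
        for t in plan.trials:
            assert 0.3 <= t.timing.delay_s <= 0.5

    def test_invalid_set_size_menu(self):
        with pytest.raises(TaskConfigError):
            SearchConfig(set_sizes=(3, 7))

    def test_invalid_policy(self):
        with pytest.raises(TaskConfigError):
            SearchConfig(set_size_policy="bogus")

    def test_distractors_share_configured_count(self, space):
        plan = search_plan(space, n_runs=1, n_shared=2)
        for t in plan.trials:
            if t.task_kind != "search_test" or t.set_size == 0:
                continue
            target = t.stimuli[t.target_index][0]
            for i, (desc, _) in enumerate(t.stimuli):
                if i != t.target_index:
                    assert sum(a == b for a, b in zip(desc, target)) == 2


class TestLearningSessionGeneration:
    def test_default_block_structure(self, space):
        plan = generate_learning_session(
            space, LearningConfig(), np.random.default_rng(3)
        )
        assert len(plan.blocks) == 40
        for b in plan.blocks:
            assert 45 <= b.n_trials <= 60
        assert len(plan.trials) == sum(b.n_trials for b in plan.blocks)

    def test_every_trial_has_exactly_one_rewarded_object(self, space):
        plan = generate_learning_session(
            space, LearningConfig(), np.random.default_rng(4)
        )
        for t in plan.trials:
            dim, value = t.rewarded_feature
            i = space.index(dim)
            assert sum(desc[i] == value for desc, _ in t.stimuli) == 1

    def test_no_consecutive_blocks_repeat_rewarded_feature(self, space):
        cfg = LearningConfig()
        for seed in range(1000):
            blocks = generate_block_defs(space, cfg, np.random.default_rng(seed))
            pairs = [(b.rewarded_dim, b.rewarded_value) for b in blocks]
            assert all(a != b for a, b in zip(pairs, pairs[1:]))

    def test_two_feature_space_strictly_alternates(self):
        sp = build_feature_space(
            [{"name": "color", "values": ["gray", "red", "blue"], "neutral": "gray"}]
        )
        blocks = generate_block_defs(sp, LearningConfig(), np.random.default_rng(5))
        values = [b.rewarded_value for b in blocks]
        assert all(a != b for a, b in zip(values, values[1:]))
        assert set(values) == {"red", "blue"}

    def test_inverted_block_range_rejected(self):
        with pytest.raises(TaskConfigError):
            LearningConfig(block_len_range=(60, 45))

    def test_single_candidate_feature_rejected(self):
        sp = build_feature_space(
            [{"name": "color", "values": ["gray", "red"], "neutral": "gray"}]
        )
        with pytest.raises(TaskConfigError):
            generate_block_defs(sp, LearningConfig(), np.random.default_rng(0))

    def test_random_varied_dims_policy(self, space):
        blocks = generate_block_defs(
            space,
            LearningConfig(n_varied_dims="random"),
            np.random.default_rng(8),
        )
        ks = {len(b.varied_dims) for b in blocks}
        assert ks <= {1, 2, 3} and len(ks) > 1
        for b in blocks:
            assert b.rewarded_dim in b.varied_dims

    def test_determinism(self, space):
        a = generate_learning_session(space, LearningConfig(), np.random.default_rng(6))
        b = generate_learning_session(space, LearningConfig(), np.random.default_rng(6))
        assert a.trials == b.trials and a.blocks == b.blocks


class _FixedAgent:
    """Test double returning a canned (index, RT) response."""

    def __init__(self, index, rt=1.0):
        self.index = index
        self.rt = rt

    def respond(self, spec, rng):
        return self.index, self.rt


def make_learning_spec(space, include_neutral=False):
    dim = space.index("color")
    objs = []
    for j, color in enumerate(["red", "blue", "green"]):
        desc = list(space.neutral_descriptor)
        desc[dim] = color
        objs.append((tuple(desc), (float(j), 0.0)))
    if include_neutral:
        objs.append((space.neutral_descriptor, (9.0, 0.0)))
    return TrialSpec(
        task_kind="learning",
        block_id=0,
        trial_index=1,
        stimuli=tuple(objs),
        rewarded_feature=("color", "red"),
    )


def make_search_spec(space):
    target = list(space.neutral_descriptor)
    target[space.index("color")] = "red"
    distractor = list(space.neutral_descriptor)
    distractor[space.index("color")] = "blue"
    return TrialSpec(
        task_kind="search_test",
        block_id=0,
        trial_index=1,
        stimuli=((tuple(target), (0.0, 0.0)), (tuple(distractor), (1.0, 0.0))),
        target_index=0,
        set_size=1,
    )


class TestRunTrial:
    def test_correct_choice_is_rewarded(self, space, rng):
        spec = make_search_spec(space)
        res = run_trial(spec, _FixedAgent(0, rt=1.0), rng, space)
        assert res.outcome == "correct" and res.rewarded
        assert res.reaction_time_s == 1.0

    def test_wrong_choice_incorrect(self, space, rng):
        res = run_trial(make_search_spec(space), _FixedAgent(1), rng, space)
        assert res.outcome == "incorrect" and not res.rewarded

    def test_no_response_is_timeout_at_window(self, space, rng):
        res = run_trial(make_search_spec(space), _FixedAgent(None), rng, space)
        assert res.outcome == "timeout"
        assert res.chosen_index is None
        assert res.reaction_time_s == 5.0

    def test_rt_past_window_is_timeout(self, space, rng):
        res = run_trial(make_search_spec(space), _FixedAgent(0, rt=7.0), rng, space)
        assert res.outcome == "timeout"

    def test_neutral_object_choice_aborts(self, space, rng):
        spec = make_learning_spec(space, include_neutral=True)
        res = run_trial(spec, _FixedAgent(3), rng, space)
        assert res.outcome == "abort_neutral" and not res.rewarded

    def test_abort_rule_can_be_disabled(self, space, rng):
        spec = make_learning_spec(space, include_neutral=True)
        res = run_trial(spec, _FixedAgent(3), rng, space, abort_on_neutral=False)
        assert res.outcome == "incorrect"

    def test_rewarded_feature_choice_correct(self, space, rng):
        spec = make_learning_spec(space)
        res = run_trial(spec, _FixedAgent(0), rng, space)
        assert res.outcome == "correct" and res.rewarded

    def test_out_of_range_index_rejected(self, space, rng):
        with pytest.raises(ValueError, match="out of range"):
            run_trial(make_search_spec(space), _FixedAgent(5), rng, space)

    def test_negative_rt_rejected(self, space, rng):
        with pytest.raises(ValueError, match="negative"):
            run_trial(make_search_spec(space), _FixedAgent(0, rt=-0.5), rng, space)

    def test_result_invariant_reward_implies_correct(self):
        with pytest.raises(ValueError):
            TrialResult(
                outcome="incorrect", chosen_index=0, reaction_time_s=1.0,
                rewarded=True, delay_s=0.4,
            )


class _ExplodingSink:
    """Raises after k successful writes; records are proxied to a real sink."""

    def __init__(self, inner, k):
        self.inner = inner
        self.k = k
        self.written = 0

    def __call__(self, spec, result):
        if self.written >= self.k:
            raise IOError("disk full")
        self.inner(spec, result)
        self.written += 1


class TestRunSession:
    def test_omniscient_agent_is_always_rewarded(self, space):
        plan = generate_learning_session(
            space, LearningConfig(n_blocks=3), np.random.default_rng(0)
        )
        results = run_session(
            plan, OmniscientAgent(space), np.random.default_rng(1), space=space
        )
        assert len(results) == len(plan.trials)
        assert all(r.outcome == "correct" and r.rewarded for r in results)

    def test_conservation_one_result_per_trial(self, space):
        plan = search_plan(space, n_runs=1)
        agent = _FixedAgent(0)
        results = run_session(plan, agent, np.random.default_rng(0), space=space)
        counts = Counter(r.outcome for r in results)
        assert sum(counts.values()) == len(plan.trials)

    def test_deterministic_given_seed(self, space):
        plan = generate_learning_session(
            space, LearningConfig(n_blocks=2), np.random.default_rng(0)
        )

        def go():
            agent = FeatureRLAgent(FeatureRLParams(), space)
            return run_session(plan, agent, np.random.default_rng(5), space=space)

        assert go() == go()

    def test_interrupted_sink_has_exactly_k_records(self, space):
        plan = search_plan(space, n_runs=1)
        collected = []
        sink = _ExplodingSink(lambda s, r: collected.append((s, r)), k=17)
        with pytest.raises(IOError):
            run_session(plan, _FixedAgent(0), np.random.default_rng(0),
                        sink=sink, space=space)
        assert len(collected) == 17


class TestGridPlacement:
    def test_positions_distinct_and_within_bounds(self, rng):
        cfg = GridConfig()
        pts = place_on_grid(10, cfg, rng)
        assert len(set(pts)) == 10
        for x, y in pts:
            assert abs(x) <= cfg.width_in / 2 and abs(y) <= cfg.height_in / 2

    def test_exhaustive_draw_returns_every_intersection(self, rng):
        cfg = GridConfig()
        pts = place_on_grid(15, cfg, rng)
        assert sorted(pts) == sorted(grid_intersections(cfg))

    def test_too_many_items_rejected(self, rng):
        with pytest.raises(TaskConfigError):
            place_on_grid(16, GridConfig(), rng)

    def test_ring_mode_distance(self, rng):
        pts = place_on_grid(3, GridConfig(), rng, mode="ring")
        for x, y in pts:
            assert math.hypot(x, y) == pytest.approx(4.1, abs=0.01)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(TaskConfigError):
            place_on_grid(1, GridConfig(), rng, mode="spiral")


class TestThrLadder:
    def test_perfect_accuracy_promotes_with_smaller_square(self):
        cfg = default_thr_ladder()
        s0 = ThrState(level=1)
        s1 = thr_next_level(s0, [1] * 10, cfg)
        assert s1.level == 2
        assert (
            cfg.levels[s1.level].square_size_in < cfg.levels[s0.level].square_size_in
        )

    def test_top_level_clamps_and_sets_touch_ready(self):
        cfg = default_thr_ladder()
        top = len(cfg.levels) - 1
        s = thr_next_level(ThrState(level=top), [1] * 10, cfg)
        assert s.level == top and s.touch_ready

    def test_zero_accuracy_at_floor_stays(self):
        s = thr_next_level(ThrState(level=0), [0] * 10, default_thr_ladder())
        assert s.level == 0 and not s.touch_ready

    def test_middling_accuracy_holds_level(self):
        s = thr_next_level(ThrState(level=2), [1, 0] * 5, default_thr_ladder())
        assert s.level == 2

    def test_short_history_is_a_no_op(self):
        s = thr_next_level(ThrState(level=2), [1, 1], default_thr_ladder())
        assert s.level == 2

    def test_level_moves_at_most_one_step(self):
        cfg = default_thr_ladder()
        rng = np.random.default_rng(0)
        state = ThrState()
        for _ in range(200):
            outcomes = rng.integers(0, 2, size=10).tolist()
            nxt = thr_next_level(state, outcomes, cfg)
            assert abs(nxt.level - state.level) <= 1
            state = nxt

    def test_increasing_square_sizes_rejected(self):
        with pytest.raises(TaskConfigError):
            ThrLadderConfig(levels=(ThrLevel(1.0), ThrLevel(2.0)))

    def test_empty_ladder_rejected(self):
        with pytest.raises(TaskConfigError):
            ThrLadderConfig(levels=())


BOUNDS = (-1.0, -1.0, 1.0, 1.0)


def trace(*events):
    return list(events)


class TestClassifyTouch:
    def test_stationary_hold_is_valid(self):
        t = trace((0, 0, 0, "down"), (250, 0, 0, "up"))
        assert classify_touch(t, BOUNDS) == "valid"

    def test_brief_tap(self):
        t = trace((0, 0, 0, "down"), (50, 0, 0, "up"))
        assert classify_touch(t, BOUNDS) == "tap_too_short"

    def test_hold_too_long(self):
        t = trace((0, 0, 0, "down"), (400, 0, 0, "up"))
        assert classify_touch(t, BOUNDS) == "hold_too_long"

    def test_late_release(self):
        t = trace((0, 0, 0, "down"), (700, 0, 0, "up"))
        assert classify_touch(t, BOUNDS) == "late_release"

    def test_never_released(self):
        t = trace((0, 0, 0, "down"), (250, 0, 0, "move"))
        assert classify_touch(t, BOUNDS) == "late_release"

    def test_swipe_leaves_bounds(self):
        t = trace((0, 0, 0, "down"), (100, 2.0, 0, "move"), (250, 2.5, 0, "up"))
        assert classify_touch(t, BOUNDS) == "swipe"

    def test_drift_within_tolerance_is_not_a_swipe(self):
        t = trace((0, 0.9, 0, "down"), (100, 1.1, 0, "move"), (250, 0.9, 0, "up"))
        assert classify_touch(t, BOUNDS) == "valid"

    def test_off_target_start(self):
        t = trace((0, 5.0, 5.0, "down"), (250, 5.0, 5.0, "up"))
        assert classify_touch(t, BOUNDS) == "off_target"

    def test_unordered_timestamps_rejected(self):
        t = trace((100, 0, 0, "down"), (50, 0, 0, "up"))
        with pytest.raises(ValueError, match="ordered"):
            classify_touch(t, BOUNDS)

    def test_geometric_containment_oracle(self):
        # random traces: classification 'swipe' iff some contact point exits
        # the tolerance-expanded box before release (given an in-bounds down)
        rng = np.random.default_rng(11)
        tol = 0.25
        for _ in range(200):
            xs = rng.uniform(-1.5, 1.5, size=5)
            ys = rng.uniform(-1.5, 1.5, size=5)
            if not (abs(xs[0]) <= 1 and abs(ys[0]) <= 1):
                continue
            events = [(0.0, xs[0], ys[0], "down")]
            events += [
                (50.0 * (i + 1), xs[i + 1], ys[i + 1], "move") for i in range(3)
            ]
            events.append((250.0, xs[4], ys[4], "up"))
            got = classify_touch(events, BOUNDS, swipe_tolerance_in=tol)
            exits = any(
                not (-1 - tol <= x <= 1 + tol and -1 - tol <= y <= 1 + tol)
                for _, x, y, _ in events
            )
            assert (got == "swipe") == exits
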