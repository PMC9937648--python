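"""Simulator: strategy semantics, action-time models, visibility and
parameter recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from bosgame.choice_metrics import average_reward, fco
from bosgame.mutual_information import mi_significance, naive_mi
from bosgame.action_time import visibility_correlation
from bosgame.game_core import LEFT, OWN, OTHER, RIGHT
from bosgame.synthetic_data import (
    ActionTimeModel,
    StrategySpec,
    confederate_schedule,
    parse_strategy,
    simulate_session,
)

from conftest import FOLLOWER_AT, LEADER_AT, follower_strategy


def test_both_fixed_own_never_coordinate():
    s = simulate_session(
        StrategySpec(kind="fixed_color", color="own"),
        StrategySpec(kind="fixed_color", color="own"),
        n_trials=200,
        seed=1,
    )
    assert fco(s, "A").scalar == 1.0
    assert fco(s, "B").scalar == 1.0
    assert not s.coordinated().any()
    assert average_reward(s, "pair") == 2.0


def test_both_fixed_left_fully_coordinate():
    s = simulate_session(
        StrategySpec(kind="fixed_side", side=LEFT),
        StrategySpec(kind="fixed_side", side=LEFT),
        n_trials=198,  # 11 complete balanced layout blocks
        seed=2,
    )
    assert s.coordinated().all()
    assert fco(s, "A").scalar == 0.5  # balanced schedule puts own color left half the time
    assert fco(s, "B").scalar == 0.5
    assert average_reward(s, "pair") == 3.5


def test_trial_turn_taking_perfect_coordination():
    s = simulate_session(
        StrategySpec(kind="trial_turn_taking"),
        StrategySpec(kind="trial_turn_taking"),
        n_trials=200,
        seed=3,
    )
    assert s.coordinated().all()
    assert average_reward(s, "pair") == 3.5
    assert fco(s, "A").scalar == 0.5


def test_simulation_deterministic_for_seed():
    kw = dict(
        strategy_A=StrategySpec(kind="random", p_own=0.6),
        strategy_B=follower_strategy(0.7),
        n_trials=150,
    )
    a = simulate_session(seed=99, **kw)
    b = simulate_session(seed=99, **kw)
    c = simulate_session(seed=100, **kw)
    assert a.trials == b.trials
    assert a.trials != c.trials


def test_trial_record_invariants_hold():
    s = simulate_session(
        follower_strategy(0.5),
        StrategySpec(kind="confederate_blocks", block_len=20),
        n_trials=120,
        seed=5,
    )
    for t in s:
        assert t.t_release_A < t.t_acquisition_A
        assert t.t_release_B < t.t_acquisition_B
        assert t.t_release_A > 0 and t.t_release_B > 0
        assert t.coordinated == (t.side_A == t.side_B)
        assert t.reward_A + t.reward_B in {7, 4, 2}


def test_action_time_model_validation():
    with pytest.raises(ValueError):
        ActionTimeModel(mean_action_ms=-5)
    with pytest.raises(ValueError):
        StrategySpec(kind="leader_follower", follow_fidelity=1.5)
    with pytest.raises(ValueError):
        StrategySpec(kind="nonsense")
    with pytest.raises(ValueError):
        simulate_session(
            StrategySpec(kind="random"), StrategySpec(kind="random"), n_trials=0
        )


def test_confederate_schedule_blocks():
    plan = confederate_schedule(60, block_len=20, seed=1, start=OWN)
    assert list(plan[:20]) == [OWN] * 20
    assert list(plan[20:40]) == [OTHER] * 20
    assert list(plan[40:]) == [OWN] * 20
    plan2 = confederate_schedule(40, block_len=20, seed=2, start=OTHER)
    assert len(set(plan2[:20])) == 1 and len(set(plan2[20:])) == 1
    assert plan2[0] != plan2[20]
    with pytest.raises(ValueError):
        confederate_schedule(40, block_len=0)


def test_confederate_jitter_keeps_alternation():
    plan = confederate_schedule(200, block_len=20, seed=3, jitter=3, start=OWN)
    # block lengths vary but stay within the jitter band
    lengths = []
    run = 1
    for a, b in zip(plan, plan[1:]):
        if a == b:
            run += 1
        else:
            lengths.append(run)
            run = 1
    assert all(17 <= ln <= 23 for ln in lengths)


def test_follower_tracks_confederate_plan():
    """With the confederate far faster and fidelity 1, the follower's
    physical color equals the plan's color wherever the confederate
    acted first."""
    fast = ActionTimeModel(mean_action_ms=300, sd_action_ms=40, mean_movement_ms=150, sd_movement_ms=40)
    slow = ActionTimeModel(mean_action_ms=700, sd_action_ms=40, mean_movement_ms=250, sd_movement_ms=40)
    s = simulate_session(
        StrategySpec(kind="confederate_blocks", block_len=20, start=OWN),
        StrategySpec(kind="leader_follower", follow_fidelity=1.0),
        fast,
        slow,
        n_trials=200,
        seed=11,
    )
    at_a = s.action_times("A")
    at_b = s.action_times("B")
    colors_a = s.colors("A")
    colors_b = s.colors("B")
    confederate_first = at_a < at_b
    assert confederate_first.mean() > 0.95
    assert (colors_b[confederate_first] == colors_a[confederate_first]).all()


def test_following_rate_approaches_one_with_fast_leader():
    fast = ActionTimeModel(mean_action_ms=300, sd_action_ms=40, mean_movement_ms=150, sd_movement_ms=40)
    slow = ActionTimeModel(mean_action_ms=700, sd_action_ms=40, mean_movement_ms=250, sd_movement_ms=40)
    s = simulate_session(
        StrategySpec(kind="fixed_color", color="own"),
        StrategySpec(kind="leader_follower", follow_fidelity=1.0),
        fast,
        slow,
        n_trials=300,
        seed=13,
    )
    # B follows A's red target -> B chooses other's color
    assert (~s.choices("B")).mean() > 0.98


def test_opaque_segment_abolishes_following():
    """Behind the barrier the follower's colors carry no information
    about the confederate's plan (below the surrogate threshold)."""
    vis = np.full(450, True)
    vis[150:300] = False
    s = simulate_session(
        StrategySpec(kind="confederate_blocks", block_len=20, start=OWN),
        follower_strategy(1.0, noise=0.05),
        LEADER_AT,
        FOLLOWER_AT,
        n_trials=450,
        seed=17,
    )
    s_vis = simulate_session(
        StrategySpec(kind="confederate_blocks", block_len=20, start=OWN),
        follower_strategy(1.0, noise=0.05),
        LEADER_AT,
        FOLLOWER_AT,
        n_trials=450,
        visibility=vis,
        seed=17,
    )
    plan_colors = s_vis.colors("A")
    follower = s_vis.colors("B")
    opaque = slice(150, 300)
    res_opaque = mi_significance(
        plan_colors[opaque], follower[opaque], n_surrogates=300, seed=1
    )
    assert not res_opaque.significant
    res_clear = mi_significance(plan_colors[:150], follower[:150], n_surrogates=300, seed=1)
    assert res_clear.significant
    # behind the barrier the follower reverts to its own color; in the
    # transparent control the plan's blocks keep pulling it to red
    assert s_vis.choices("B")[opaque].mean() > 0.85
    assert s.choices("B")[opaque].mean() < s_vis.choices("B")[opaque].mean() - 0.15


def test_fidelity_recovery_monotone():
    """Mean visibility correlation increases monotonically in the
    generating follow fidelity (rank correlation 1 over 20 seeds)."""
    fidelities = [0.0, 0.25, 0.5, 0.75, 1.0]
    means = []
    for f in fidelities:
        rs = []
        for seed in range(20):
            s = simulate_session(
                StrategySpec(kind="fixed_color", color="own", noise=0.05),
                follower_strategy(f),
                LEADER_AT,
                FOLLOWER_AT,
                n_trials=300,
                seed=300 + seed,
            )
            rs.append(visibility_correlation(s)["B"].r_raw)
        means.append(float(np.nanmean(rs)))
    rho = spearmanr(fidelities, means).statistic
    assert rho == pytest.approx(1.0)


def test_parse_strategy_round_trips():
    s = parse_strategy("leader_follower:fixed_color:own,fidelity=0.8,noise=0.1")
    assert s.kind == "leader_follower"
    assert s.follow_fidelity == 0.8
    assert s.baseline.kind == "fixed_color"
    assert parse_strategy("fixed_side:left").side == LEFT
    assert parse_strategy("random:0.3").p_own == 0.3
    assert parse_strategy("block_turn_taking:15").block_len == 15
    with pytest.raises(ValueError):
        parse_strategy("fixed_side:up")
    with pytest.raises(ValueError):
        parse_strategy("quantum")
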