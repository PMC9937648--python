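"""Choice probabilities, RPR, DCR and strategy classification."""

import numpy as np
import pytest

from bosgame.choice_metrics import average_reward, last_n
from bosgame.dynamic_coordination import (
    ChoiceProbabilities,
    choice_probs,
    classify_strategy,
    dcr,
    rpr,
)
from bosgame.game_core import LEFT, RIGHT, SessionData, evaluate_trial, replace_trials
from bosgame.synthetic_data import StrategySpec, simulate_session

from conftest import (
    anti_coordination_rows,
    build_session,
    fixed_left_rows,
    turn_taking_rows,
)


def make_probs(pa, pb, q_left=0.5):
    return ChoiceProbabilities(p={"A": pa, "B": pb}, q_left=q_left, q_right=1 - q_left)


UNIFORM = {(2, "L"): 0.25, (2, "R"): 0.25, (1, "L"): 0.25, (1, "R"): 0.25}


def test_choice_probs_both_always_own():
    s = build_session(
        [(LEFT, LEFT, RIGHT), (RIGHT, RIGHT, LEFT)] * 50  # own-own, balanced sides
    )
    probs = choice_probs(s)
    for agent in ("A", "B"):
        assert probs.p[agent][(2, "L")] == pytest.approx(0.5)
        assert probs.p[agent][(2, "R")] == pytest.approx(0.5)
        assert probs.p[agent][(1, "L")] == 0.0
        assert probs.p[agent][(1, "R")] == 0.0


def test_choice_probs_turn_taking_quarters(turn_taking_session):
    probs = choice_probs(turn_taking_session)
    for agent in ("A", "B"):
        for key, val in probs.p[agent].items():
            assert val == pytest.approx(0.25), (agent, key)
    assert probs.q_left == pytest.approx(0.5)


def test_choice_probs_fixed_left(fixed_left_session):
    probs = choice_probs(fixed_left_session)
    for agent in ("A", "B"):
        assert probs.p[agent][(2, "L")] == pytest.approx(0.5)
        assert probs.p[agent][(1, "L")] == pytest.approx(0.5)
        assert probs.p[agent][(2, "R")] == 0.0
        assert probs.p[agent][(1, "R")] == 0.0


def test_choice_probs_marginal_constraints(turn_taking_session):
    """Eq-style ties: the four P sum to 1 and link to Q_left/Q_right."""
    probs = choice_probs(turn_taking_session)
    for agent in ("A", "B"):
        assert sum(probs.p[agent].values()) == pytest.approx(1.0)
    a, b = probs.p["A"], probs.p["B"]
    assert a[(2, "L")] + a[(1, "R")] == pytest.approx(probs.q_left)
    assert b[(1, "L")] + b[(2, "R")] == pytest.approx(probs.q_left)
    assert a[(1, "L")] + a[(2, "R")] == pytest.approx(probs.q_right)


def test_rpr_uniform_random_play_is_2_5():
    assert rpr(make_probs(dict(UNIFORM), dict(UNIFORM))) == pytest.approx(2.5)


def test_rpr_both_always_own_is_2():
    own = {(2, "L"): 0.5, (2, "R"): 0.5, (1, "L"): 0.0, (1, "R"): 0.0}
    assert rpr(make_probs(dict(own), dict(own))) == pytest.approx(2.0)


def test_rpr_static_unfair_coordination_is_3_5():
    own = {(2, "L"): 0.5, (2, "R"): 0.5, (1, "L"): 0.0, (1, "R"): 0.0}
    other = {(2, "L"): 0.0, (2, "R"): 0.0, (1, "L"): 0.5, (1, "R"): 0.5}
    assert rpr(make_probs(dict(own), dict(other))) == pytest.approx(3.5)


def test_rpr_rejects_degenerate_layout_frequencies():
    with pytest.raises(ValueError):
        rpr(make_probs(dict(UNIFORM), dict(UNIFORM), q_left=0.0))


def test_rpr_monte_carlo_oracle():
    """Closed-form RPR equals a 1e5-trial stratified permutation draw.

    Random play keeps each agent's observed choice frequencies per
    layout side but resamples them independently: sample a layout side
    from Q, then each agent's choice from its empirical conditional on
    that side, and average the joint reward.
    """
    rng = np.random.default_rng(71)
    s = simulate_session(
        StrategySpec(kind="random", p_own=0.7),
        StrategySpec(kind="leader_follower", follow_fidelity=0.5),
        n_trials=400,
        seed=19,
    )
    probs = choice_probs(s)
    closed = rpr(probs)

    n_mc = 100_000
    red_left = rng.random(n_mc) < probs.q_left
    chose = {}
    for agent, label in (("A", "A"), ("B", "B")):
        own = s.choices(label)
        left = s.sides(label)
        layout_left = np.array([t.layout.red_side == LEFT for t in s])
        p_own_given = {
            True: own[layout_left].mean(),
            False: own[~layout_left].mean(),
        }
        u = rng.random(n_mc)
        chose[agent] = np.where(red_left, u < p_own_given[True], u < p_own_given[False])
    joint = np.where(
        chose["A"] != chose["B"], 3.5, np.where(chose["A"], 2.0, 1.0)
    )
    assert abs(joint.mean() - closed) < 0.01


def test_dcr_perfect_turn_taking_is_one(turn_taking_session):
    res = dcr(turn_taking_session)
    assert res.r_actual == pytest.approx(3.5)
    assert res.rpr == pytest.approx(2.5)
    assert res.dcr == pytest.approx(1.0)
    assert res.significant
    assert res.ci_low <= res.dcr <= res.ci_high


def test_dcr_anti_coordination_is_minus_one(anti_coordination_session):
    res = dcr(anti_coordination_session)
    assert res.r_actual == pytest.approx(1.5)
    assert res.dcr == pytest.approx(-1.0)
    assert res.significant


def test_dcr_static_side_coordination_is_zero(fixed_left_session):
    res = dcr(fixed_left_session)
    assert res.r_actual == pytest.approx(3.5)
    assert res.dcr == pytest.approx(0.0)
    assert not res.significant


def test_dcr_range_on_arbitrary_sessions():
    for seed in range(10):
        s = simulate_session(
            StrategySpec(kind="random", p_own=0.2 + 0.06 * seed),
            StrategySpec(kind="random", p_own=0.9 - 0.07 * seed),
            n_trials=250,
            seed=seed,
        )
        res = dcr(s)
        assert -1.0 <= res.dcr <= 1.0
        assert res.ci_low <= res.dcr <= res.ci_high


def _shuffle_choices(session: SessionData, rng) -> SessionData:
    """Independently permute each agent's side sequence within layout-
    side strata (preserves the eight selection probabilities)."""
    red_left = np.array([t.layout.red_side == LEFT for t in session])
    sides = {
        "A": np.array([t.side_A for t in session]),
        "B": np.array([t.side_B for t in session]),
    }
    for agent in ("A", "B"):
        for stratum in (red_left, ~red_left):
            vals = sides[agent][stratum]
            sides[agent][stratum] = vals[rng.permutation(len(vals))]
    trials = [
        evaluate_trial(t.layout, sa, sb, trial_index=t.trial_index)
        for t, sa, sb in zip(session, sides["A"], sides["B"])
    ]
    return replace_trials(session, trials)


def test_dcr_permutation_null_coverage():
    """After destroying cross-agent dependence the DCR's own CI covers 0
    in at least 95% of replicates."""
    rng = np.random.default_rng(101)
    base = simulate_session(
        StrategySpec(kind="random", p_own=0.65),
        StrategySpec(kind="random", p_own=0.4),
        n_trials=300,
        seed=23,
    )
    covered = 0
    reps = 200
    for _ in range(reps):
        null = _shuffle_choices(base, rng)
        res = dcr(null)
        covered += res.ci_low <= 0.0 <= res.ci_high
    assert covered / reps >= 0.95, f"coverage {covered / reps:.3f}"


NOISY_TT = StrategySpec(kind="trial_turn_taking", noise=0.05)


def test_classify_turn_taking_pair():
    s = simulate_session(NOISY_TT, NOISY_TT, n_trials=400, seed=31)
    res = classify_strategy(last_n(s, 200), n_surrogates=300)
    assert res.label == "dynamic_turn_taking"
    assert res.dcr_result.dcr > 0.2


def test_classify_static_side_pair():
    fs = StrategySpec(kind="fixed_side", side=LEFT, noise=0.03)
    s = simulate_session(fs, fs, n_trials=400, seed=37)
    res = classify_strategy(last_n(s, 200), n_surrogates=300)
    assert res.label == "static_side"


def test_classify_static_color_pair():
    s = simulate_session(
        StrategySpec(kind="fixed_color", color="own", noise=0.03),
        StrategySpec(kind="fixed_color", color="other", noise=0.03),
        n_trials=400,
        seed=41,
    )
    res = classify_strategy(last_n(s, 200), n_surrogates=300)
    assert res.label == "static_color"


def test_classify_own_insistence_as_uncoordinated():
    s = simulate_session(
        StrategySpec(kind="fixed_color", color="own"),
        StrategySpec(kind="fixed_color", color="own"),
        n_trials=300,
        seed=43,
    )
    res = classify_strategy(last_n(s, 200), n_surrogates=300)
    assert res.label == "uncoordinated"
    assert res.coordination_fraction == 0.0


@pytest.mark.parametrize("strategy", [NOISY_TT, StrategySpec(kind="fixed_side", side=LEFT, noise=0.03)])
def test_classification_robust_to_window_length(strategy):
    """Stationary sessions classify identically over the last 150, 200
    and 250 trials."""
    s = simulate_session(strategy, strategy, n_trials=400, seed=47)
    labels = {
        n: classify_strategy(last_n(s, n), n_surrogates=300).label
        for n in (150, 200, 250)
    }
    assert len(set(labels.values())) == 1, labels


def test_classify_rejects_short_sessions():
    s = simulate_session(NOISY_TT, NOISY_TT, n_trials=30, seed=3)
    with pytest.raises(ValueError):
        classify_strategy(s)
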