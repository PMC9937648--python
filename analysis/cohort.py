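"""Shared simulated cohort for the analysis scripts.

Deterministic (fixed seeds): a set of dyads spanning the strategy
repertoire the species displayed — turn-taking and static human-style
pairs, side- and color-coordinating macaque-style pairs, a confederate
training session with an opaque-barrier segment, and a competitive
turn-taking pair driven by action-time differences.
"""

from __future__ import annotations

import numpy as np

from bosgame.synthetic_data import ActionTimeModel, StrategySpec, simulate_session

HUMAN_AT = ActionTimeModel(
    mean_action_ms=520, sd_action_ms=90, mean_movement_ms=314, sd_movement_ms=104
)
MACAQUE_FAST_AT = ActionTimeModel(
    mean_action_ms=450, sd_action_ms=80, mean_movement_ms=171, sd_movement_ms=77
)
MACAQUE_SLOW_AT = ActionTimeModel(
    mean_action_ms=550, sd_action_ms=80, mean_movement_ms=180, sd_movement_ms=64
)


def _follower(fidelity=1.0, noise=0.05):
    return StrategySpec(
        kind="leader_follower",
        baseline=StrategySpec(kind="fixed_color", color="own", noise=noise),
        follow_fidelity=fidelity,
    )


def build_cohort() -> dict[str, dict]:
    """name -> {session, species, description}."""
    tt = StrategySpec(kind="trial_turn_taking", noise=0.05)
    btt = StrategySpec(kind="block_turn_taking", block_len=15, noise=0.05)
    cohort = {
        "human_trial_turn_taking": dict(
            species="human",
            description="trial-by-trial turn-taking pair",
            session=simulate_session(tt, tt, HUMAN_AT, HUMAN_AT, n_trials=400, seed=101),
        ),
        "human_block_turn_taking": dict(
            species="human",
            description="block-wise turn-taking pair (15-trial blocks)",
            session=simulate_session(btt, btt, HUMAN_AT, HUMAN_AT, n_trials=400, seed=102),
        ),
        "human_static_color": dict(
            species="human",
            description="pair statically coordinating on A's color",
            session=simulate_session(
                StrategySpec(kind="fixed_color", color="own", noise=0.03),
                StrategySpec(kind="fixed_color", color="other", noise=0.03),
                HUMAN_AT, HUMAN_AT, n_trials=400, seed=103,
            ),
        ),
        "human_uncoordinated": dict(
            species="human",
            description="both agents insist on their own color",
            session=simulate_session(
                StrategySpec(kind="fixed_color", color="own", noise=0.02),
                StrategySpec(kind="fixed_color", color="own", noise=0.02),
                HUMAN_AT, HUMAN_AT, n_trials=400, seed=104,
            ),
        ),
        "macaque_static_side": dict(
            species="macaque",
            description="side-coordinating macaque pair (objective left)",
            session=simulate_session(
                StrategySpec(kind="fixed_side", side="L", noise=0.03),
                StrategySpec(kind="fixed_side", side="L", noise=0.03),
                MACAQUE_FAST_AT, MACAQUE_SLOW_AT, n_trials=400, seed=105,
            ),
        ),
        "macaque_static_color": dict(
            species="macaque",
            description="pair converged on the faster monkey's color",
            session=simulate_session(
                StrategySpec(kind="fixed_color", color="own", noise=0.03),
                _follower(1.0, noise=0.05),
                MACAQUE_FAST_AT, MACAQUE_SLOW_AT, n_trials=400, seed=106,
            ),
        ),
        "confederate_training_opaque": dict(
            species="macaque",
            description="confederate block alternation; opaque barrier over the middle third",
            session=simulate_session(
                StrategySpec(kind="confederate_blocks", block_len=20, start="own"),
                _follower(1.0, noise=0.05),
                MACAQUE_FAST_AT, MACAQUE_SLOW_AT, n_trials=450,
                visibility=np.r_[np.full(150, True), np.full(150, False), np.full(150, True)],
                seed=107,
            ),
        ),
        "macaque_competitive_turn_taking": dict(
            species="macaque",
            description="confederate-trained pair, both follow whoever acts first",
            session=simulate_session(
                _follower(1.0, noise=0.05), _follower(1.0, noise=0.05),
                MACAQUE_SLOW_AT, MACAQUE_SLOW_AT, n_trials=400, seed=108,
            ),
        ),
    }
    return cohort
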