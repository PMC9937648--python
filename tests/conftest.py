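"""Shared fixtures: deterministic counterbalanced sessions and realistic
simulated study conditions."""

from __future__ import annotations

import numpy as np
import pytest

from bosgame.game_core import LEFT, RIGHT, SessionData, TrialLayout, evaluate_trial
from bosgame.synthetic_data import ActionTimeModel, StrategySpec


def build_session(rows, **session_kwargs) -> SessionData:
    """Session from (red_side, side_A, side_B[, t_rel_A, t_acq_A, t_rel_B, t_acq_B]) rows."""
    trials = []
    for i, row in enumerate(rows):
        red_side, side_a, side_b = row[:3]
        times = {}
        if len(row) > 3:
            ra, aa, rb, ab = row[3:7]
            times = dict(
                t_release_A=ra, t_acquisition_A=aa, t_release_B=rb, t_acquisition_B=ab
            )
        layout = TrialLayout(1 if red_side == LEFT else 4)
        trials.append(
            evaluate_trial(layout, side_a, side_b, trial_index=i + 1, **times)
        )
    return SessionData(trials=trials, **session_kwargs)


def turn_taking_rows(n: int):
    """Strict trial-by-trial turn-taking, sides exactly counterbalanced.

    Both agents jointly select A's color on even trials and B's color on
    odd trials; the red side cycles with period 4 so each agent chooses
    the objective left in exactly half the trials (n divisible by 4).
    """
    rows = []
    for t in range(n):
        red = LEFT if (t // 2) % 2 == 0 else RIGHT
        blue = RIGHT if red == LEFT else LEFT
        target = red if t % 2 == 0 else blue  # jointly chosen physical target
        rows.append((red, target, target))
    return rows


def anti_coordination_rows(n: int):
    """Alternating own-own / other-other play, sides counterbalanced."""
    rows = []
    for t in range(n):
        red = LEFT if (t // 2) % 2 == 0 else RIGHT
        blue = RIGHT if red == LEFT else LEFT
        if t % 2 == 0:  # own-own: A on red, B on blue
            rows.append((red, red, blue))
        else:  # other-other: A on blue, B on red
            rows.append((red, blue, red))
    return rows


def fixed_left_rows(n: int):
    """Both agents always on the objective left, red side balanced."""
    return [((LEFT if t % 2 == 0 else RIGHT), LEFT, LEFT) for t in range(n)]


@pytest.fixture
def turn_taking_session() -> SessionData:
    return build_session(turn_taking_rows(200))


@pytest.fixture
def anti_coordination_session() -> SessionData:
    return build_session(anti_coordination_rows(200))


@pytest.fixture
def fixed_left_session() -> SessionData:
    return build_session(fixed_left_rows(200))


# -- study-condition action-time models (see docs/methods.md) ------------

LEADER_AT = ActionTimeModel(
    mean_action_ms=450, sd_action_ms=80, mean_movement_ms=180, sd_movement_ms=60
)
FOLLOWER_AT = ActionTimeModel(
    mean_action_ms=550, sd_action_ms=80, mean_movement_ms=250, sd_movement_ms=60
)


def follower_strategy(fidelity: float, noise: float = 0.1) -> StrategySpec:
    return StrategySpec(
        kind="leader_follower",
        baseline=StrategySpec(kind="fixed_color", color="own", noise=noise),
        follow_fidelity=fidelity,
    )
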