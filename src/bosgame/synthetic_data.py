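"""Dyadic session simulator: parametrized agent strategies plus action-
time models reproducing the strategic structure of transparent
coordination-game sessions.

Strategy repertoire
-------------------
fixed_color     always pick the own (or other's) preferred color.
fixed_side      always pick one objective side; the color then follows
                the layout randomization.
block_turn_taking / trial_turn_taking
                the pair's beneficiary alternates on a fixed block
                schedule (trial_turn_taking is block length 1); the
                agent picks its own color exactly in its own blocks.
                Two turn-takers with equal block length and phase are
                perfectly coordinated.
confederate_blocks
                scripted block alternation between the two colors in
                blocks of ~20 trials, as used to train animals to
                monitor a partner.
leader_follower baseline strategy plus trial-by-trial following: when
                the partner's provisional action time is earlier and
                the display is transparent, the agent copies the
                partner's physical target with probability
                psee(dt) * follow_fidelity, and its realized action
                time becomes max(own draw, leader's time + lag).
random          i.i.d. own-color choices with probability p_own.

Every strategy accepts a ``noise`` lapse probability: with that
probability per trial the policy's target is replaced by a fair coin
flip over sides, emulating the exploratory deviations real pairs show.

Within a trial the single seeded RNG stream is consumed in a fixed
order: A's baseline draw then lapse draw(s), the same for B, A's
action-time draw, B's action-time draw, a tie-break coin flip (only on
exact provisional-time ties), then the slower agent's follow draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .action_time import PseeParams, psee
from .game_core import (
    COLOR_A,
    COLOR_B,
    LEFT,
    OWN,
    OTHER,
    RIGHT,
    SessionData,
    TrialLayout,
    evaluate_trial,
    make_layout_schedule,
)

__all__ = [
    "StrategySpec",
    "ActionTimeModel",
    "simulate_session",
    "confederate_schedule",
    "parse_strategy",
]

KINDS = {
    "fixed_color",
    "fixed_side",
    "block_turn_taking",
    "trial_turn_taking",
    "confederate_blocks",
    "leader_follower",
    "random",
}

#: reaction lag added to the leader's action time when a copy occurs (ms)
DEFAULT_FOLLOW_LAG_MS = 150.0


@dataclass(frozen=True)
class StrategySpec:
    """A parametrized agent policy.

    Parameters by kind: fixed_color(color: own|other);
    fixed_side(side: L|R); block_turn_taking(block_len, phase);
    confederate_blocks(block_len, jitter, start);
    leader_follower(baseline: StrategySpec, follow_fidelity);
    random(p_own).
    """

    kind: str
    color: str = OWN                      # fixed_color
    side: str = LEFT                      # fixed_side
    block_len: int = 20                   # block_turn_taking / confederate_blocks
    phase: int = 0                        # block_turn_taking
    jitter: int = 0                       # confederate_blocks
    start: Optional[str] = None           # confederate_blocks: own/other
    baseline: Optional["StrategySpec"] = None  # leader_follower
    follow_fidelity: float = 1.0          # leader_follower
    p_own: float = 0.5                    # random
    noise: float = 0.0                    # per-trial lapse probability (any kind)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if self.kind not in KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if not 0.0 <= self.follow_fidelity <= 1.0:
            raise ValueError("follow_fidelity must be in [0, 1]")
        if not 0.0 <= self.p_own <= 1.0:
            raise ValueError("p_own must be in [0, 1]")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.color not in (OWN, OTHER):
            raise ValueError("color must be 'own' or 'other'")
        if self.side not in (LEFT, RIGHT):
            raise ValueError("side must be 'L' or 'R'")
        if self.kind == "leader_follower":
            if self.baseline is None:
                object.__setattr__(
                    self, "baseline", StrategySpec(kind="fixed_color", color=OWN)
                )
            if self.baseline.kind == "leader_follower":
                raise ValueError("leader_follower baseline cannot itself follow")


@dataclass(frozen=True)
class ActionTimeModel:
    """Truncated-normal action/movement time generator (ms).

    ``mean_action_ms``/``sd_action_ms`` parametrize the reach midpoint,
    ``mean_movement_ms``/``sd_movement_ms`` the release-to-acquisition
    duration; draws are truncated from below at ``floor_ms`` (and the
    action time additionally at half the movement, keeping the release
    strictly positive).
    """

    mean_action_ms: float = 500.0
    sd_action_ms: float = 100.0
    mean_movement_ms: float = 250.0
    sd_movement_ms: float = 80.0
    floor_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in ("mean_action_ms", "sd_action_ms", "mean_movement_ms", "sd_movement_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return float(lo)


def _draw_times(rng: np.random.Generator, model: ActionTimeModel) -> tuple[float, float]:
    """(t_action, t_movement) honoring the truncation floor."""
    movement = _trunc_normal(rng, model.mean_movement_ms, model.sd_movement_ms, model.floor_ms)
    action = _trunc_normal(
        rng, model.mean_action_ms, model.sd_action_ms, max(model.floor_ms, movement / 2.0 + 1.0)
    )
    return action, movement


def confederate_schedule(
    n_trials: int, block_len: int = 20, seed: int = 0, jitter: int = 0,
    start: Optional[str] = None,
) -> np.ndarray:
    """Scripted block-alternating color plan ('own'/'other' per trial).

    Blocks of ``block_len`` trials (optionally jittered by up to
    +/- ``jitter``) alternate between the two colors; the starting color
    is drawn from the seeded RNG unless given.
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    current = start if start is not None else (OWN if rng.random() < 0.5 else OTHER)
    plan: list[str] = []
    while len(plan) < n_trials:
        ln = block_len if jitter == 0 else max(1, block_len + int(rng.integers(-jitter, jitter + 1)))
        plan.extend([current] * ln)
        current = OTHER if current == OWN else OWN
    return np.array(plan[:n_trials])


def _own_color_side(agent: str, layout: TrialLayout) -> str:
    """Objective side of the agent's preferred color under the layout."""
    own_color = COLOR_A if agent == "A" else COLOR_B
    return layout.red_side if own_color == COLOR_A else (LEFT if layout.red_side == RIGHT else RIGHT)


def _baseline_side(
    strategy: StrategySpec,
    agent: str,
    t: int,
    layout: TrialLayout,
    rng: np.random.Generator,
    plan: Optional[np.ndarray],
) -> str:
    """Provisional (pre-following) objective side for trial t (0-based).

    Applies the strategy's lapse noise after the policy choice; for
    leader_follower the baseline's own noise applies inside the
    recursion.
    """
    side = _policy_side(strategy, agent, t, layout, rng, plan)
    if strategy.noise > 0.0 and rng.random() < strategy.noise:
        side = LEFT if rng.random() < 0.5 else RIGHT
    return side


def _policy_side(
    strategy: StrategySpec,
    agent: str,
    t: int,
    layout: TrialLayout,
    rng: np.random.Generator,
    plan: Optional[np.ndarray],
) -> str:
    kind = strategy.kind
    if kind == "fixed_color":
        choice = strategy.color
    elif kind == "fixed_side":
        return strategy.side
    elif kind in ("block_turn_taking", "trial_turn_taking"):
        block_len = 1 if kind == "trial_turn_taking" else strategy.block_len
        beneficiary = "A" if (t // block_len + strategy.phase) % 2 == 0 else "B"
        choice = OWN if beneficiary == agent else OTHER
    elif kind == "confederate_blocks":
        choice = plan[t]
    elif kind == "random":
        choice = OWN if rng.random() < strategy.p_own else OTHER
    else:  # leader_follower: provisional choice comes from the baseline
        return _baseline_side(strategy.baseline, agent, t, layout, rng, plan)
    own_side = _own_color_side(agent, layout)
    if choice == OWN:
        return own_side
    return LEFT if own_side == RIGHT else RIGHT


def simulate_session(
    strategy_A: StrategySpec,
    strategy_B: StrategySpec,
    at_A: ActionTimeModel = ActionTimeModel(),
    at_B: ActionTimeModel = ActionTimeModel(),
    n_trials: int = 400,
    visibility: Union[bool, Sequence[bool]] = True,
    psee_params: PseeParams = PseeParams(),
    seed: int = 0,
    follow_lag_ms: float = DEFAULT_FOLLOW_LAG_MS,
    species: str = "synthetic",
) -> SessionData:
    """Simulate one dyadic session under two agent strategies.

    Each trial both agents draw a provisional target and action time;
    if the slower agent plays leader_follower and the trial is visible,
    it copies the faster agent's physical target with probability
    psee(dt) * follow_fidelity (dt = slower minus faster provisional
    action time) and is delayed to max(own draw, leader + lag).
    Deterministic for a fixed seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isinstance(visibility, (bool, np.bool_)):
        vis = np.full(n_trials, bool(visibility))
    else:
        vis = np.asarray(visibility, dtype=bool)
        if len(vis) != n_trials:
            raise ValueError("visibility schedule length must equal n_trials")
    rng = np.random.default_rng(seed)
    layouts = make_layout_schedule(n_trials, seed=int(rng.integers(2**31 - 1)))
    plans = {}
    for agent, strat in (("A", strategy_A), ("B", strategy_B)):
        base = strat.baseline if strat.kind == "leader_follower" else strat
        if base.kind == "confederate_blocks":
            plans[agent] = confederate_schedule(
                n_trials, base.block_len, seed=int(rng.integers(2**31 - 1)),
                jitter=base.jitter, start=base.start,
            )
        else:
            plans[agent] = None

    trials = []
    for t in range(n_trials):
        layout = layouts[t]
        side = {
            "A": _baseline_side(strategy_A, "A", t, layout, rng, plans["A"]),
            "B": _baseline_side(strategy_B, "B", t, layout, rng, plans["B"]),
        }
        act_a, mov_a = _draw_times(rng, at_A)
        act_b, mov_b = _draw_times(rng, at_B)
        action = {"A": act_a, "B": act_b}
        movement = {"A": mov_a, "B": mov_b}
        if action["A"] == action["B"]:
            faster = "A" if rng.random() < 0.5 else "B"
        else:
            faster = "A" if action["A"] < action["B"] else "B"
        slower = "B" if faster == "A" else "A"
        slower_strat = strategy_A if slower == "A" else strategy_B
        if slower_strat.kind == "leader_follower" and vis[t]:
            dt = action[slower] - action[faster]
            p_follow = psee(dt, psee_params) * slower_strat.follow_fidelity
            if rng.random() < p_follow:
                side[slower] = side[faster]
                action[slower] = max(action[slower], action[faster] + follow_lag_ms)
        rec = evaluate_trial(
            layout,
            side["A"],
            side["B"],
            trial_index=t + 1,
            t_release_A=action["A"] - movement["A"] / 2.0,
            t_acquisition_A=action["A"] + movement["A"] / 2.0,
            t_release_B=action["B"] - movement["B"] / 2.0,
            t_acquisition_B=action["B"] + movement["B"] / 2.0,
            visible=bool(vis[t]),
        )
        trials.append(rec)
    return SessionData(trials=trials, species=species, condition=None)


def parse_strategy(text: str) -> StrategySpec:
    """Parse a CLI strategy spec like ``leader_follower:fixed_color:own,fidelity=0.8``.

    Grammar: ``kind[:arg][,key=value...]``; leader_follower takes a
    nested baseline spec as its positional argument.
    """
    head, _, kv = text.partition(",")
    kwargs: dict = {}
    for part in kv.split(",") if kv else []:
        if not part:
            continue
        key, _, value = part.partition("=")
        key = key.strip()
        if key in ("fidelity", "follow_fidelity"):
            kwargs["follow_fidelity"] = float(value)
        elif key in ("p_own", "noise"):
            kwargs[key] = float(value)
        elif key in ("block_len", "phase", "jitter"):
            kwargs[key] = int(value)
        elif key == "start":
            kwargs["start"] = value
        else:
            raise ValueError(f"unknown strategy parameter {key!r}")
    kind, _, arg = head.partition(":")
    kind = kind.strip()
    if kind == "fixed_color":
        return StrategySpec(kind=kind, color=arg or OWN, **kwargs)
    if kind == "fixed_side":
        side = {"left": LEFT, "right": RIGHT, LEFT: LEFT, RIGHT: RIGHT}.get(arg or "left")
        if side is None:
            raise ValueError(f"bad side {arg!r}")
        return StrategySpec(kind=kind, side=side, **kwargs)
    if kind in ("block_turn_taking", "confederate_blocks"):
        if arg:
            kwargs["block_len"] = int(arg)
        return StrategySpec(kind=kind, **kwargs)
    if kind in ("trial_turn_taking",):
        return StrategySpec(kind=kind, **kwargs)
    if kind == "random":
        if arg:
            kwargs["p_own"] = float(arg)
        return StrategySpec(kind=kind, **kwargs)
    if kind == "leader_follower":
        baseline = parse_strategy(arg) if arg else None
        return StrategySpec(kind=kind, baseline=baseline, **kwargs)
    raise ValueError(f"unknown strategy kind {kind!r}")
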