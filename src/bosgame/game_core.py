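"""Payoff structure, target-layout randomization and trial evaluation.

The game is a transparent Bach-or-Stravinsky (Battle of the Sexes)
coordination game played on a shared display.  Two differently colored
targets appear left and right; agent A's individually preferred color is
*red*, agent B's is *blue*.  Selecting the own preferred color is worth 2
reward units, the partner's color 1 unit, and when both agents touch the
same physical target a coordination bonus of 2 units is added for each.
Coordinated outcomes are therefore worth (4, 3) or (3, 4), the
uncoordinated ones (2, 2) (both insist on their own color) or (1, 1)
(both yield).

All sides are expressed in the *objective* frame, i.e. agent A's frame:
"L" is A's left.  Readers and writers never store subjective sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OWN",
    "OTHER",
    "LEFT",
    "RIGHT",
    "PayoffMatrix",
    "TrialLayout",
    "TrialRecord",
    "SessionData",
    "payoff",
    "make_layout_schedule",
    "evaluate_trial",
]

OWN = "own"
OTHER = "other"
LEFT = "L"
RIGHT = "R"

#: physical target colors; A prefers red, B prefers blue
COLOR_A = "red"
COLOR_B = "blue"

#: positions 1..3 are the three heights on the left, 4..6 on the right
N_POSITIONS = 6
BLOCK_LEN = 18  # layout randomization balance block


@dataclass(frozen=True)
class PayoffMatrix:
    """Reward schedule of the coordination game.

    ``base_own``/``base_other`` are the guaranteed payoffs for choosing
    the individually preferred / non-preferred color; ``bonus`` is added
    to both agents' payoffs on coordinated trials.
    """

    base_own: int = 2
    base_other: int = 1
    bonus: int = 2

    def reward(self, choice: str, coordinated: bool) -> int:
        base = self.base_own if choice == OWN else self.base_other
        return base + (self.bonus if coordinated else 0)


DEFAULT_PAYOFF = PayoffMatrix()


@dataclass(frozen=True)
class TrialLayout:
    """Position of agent A's preferred (red) target on one trial.

    ``red_position`` indexes the six target slots (three heights x two
    sides); 1-3 lie on the objective left, 4-6 on the objective right.
    The blue target occupies the vertically mirrored opposite slot.
    """

    red_position: int

    def __post_init__(self) -> None:
        if not 1 <= self.red_position <= N_POSITIONS:
            raise ValueError(f"red_position must be in 1..6, got {self.red_position}")

    @property
    def red_side(self) -> str:
        return LEFT if self.red_position <= 3 else RIGHT

    def color_on(self, side: str) -> str:
        return COLOR_A if side == self.red_side else COLOR_B


@dataclass(frozen=True)
class TrialRecord:
    """One dyadic trial with choices, outcome and (optional) timing."""

    trial_index: int  # 1-based
    layout: TrialLayout
    side_A: str
    side_B: str
    choice_A: str
    choice_B: str
    coordinated: bool
    reward_A: int
    reward_B: int
    t_release_A: Optional[float] = None
    t_acquisition_A: Optional[float] = None
    t_release_B: Optional[float] = None
    t_acquisition_B: Optional[float] = None
    visible: bool = True

    def __post_init__(self) -> None:
        for rel, acq, label in (
            (self.t_release_A, self.t_acquisition_A, "A"),
            (self.t_release_B, self.t_acquisition_B, "B"),
        ):
            if rel is not None and acq is not None and not rel < acq:
                raise ValueError(
                    f"trial {self.trial_index}: t_release_{label} must precede "
                    f"t_acquisition_{label} ({rel} >= {acq})"
                )

    @property
    def coordination_color(self) -> Optional[str]:
        """Physical color jointly selected, or None if uncoordinated."""
        if not self.coordinated:
            return None
        return self.layout.color_on(self.side_A)


@dataclass
class SessionData:
    """An ordered dyadic session plus pair metadata."""

    trials: list[TrialRecord]
    agent_labels: tuple[str, str] = ("A", "B")
    species: str = "human"
    condition: Optional[str] = None
    short_session: bool = False  # set by last_n when fewer trials were available

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("trial indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def __getitem__(self, key):
        if isinstance(key, slice):
            return replace_trials(self, self.trials[key])
        return self.trials[key]

    # -- vectorized views -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Per-trial DataFrame in the session TSV column layout."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "trial": t.trial_index,
                    "red_side": t.layout.red_side,
                    "red_pos": t.layout.red_position,
                    "side_A": t.side_A,
                    "side_B": t.side_B,
                    "choice_A": t.choice_A,
                    "choice_B": t.choice_B,
                    "reward_A": t.reward_A,
                    "reward_B": t.reward_B,
                    "t_rel_A_ms": t.t_release_A,
                    "t_acq_A_ms": t.t_acquisition_A,
                    "t_rel_B_ms": t.t_release_B,
                    "t_acq_B_ms": t.t_acquisition_B,
                    "visible": int(t.visible),
                }
            )
        return pd.DataFrame(rows)

    def choices(self, agent: str) -> np.ndarray:
        """Boolean array: agent chose its own preferred color."""
        attr = "choice_A" if agent == self.agent_labels[0] else "choice_B"
        if agent not in self.agent_labels:
            raise KeyError(f"unknown agent label {agent!r}")
        return np.array([getattr(t, attr) == OWN for t in self.trials])

    def sides(self, agent: str) -> np.ndarray:
        """Boolean array: agent chose the objective left side."""
        attr = "side_A" if agent == self.agent_labels[0] else "side_B"
        if agent not in self.agent_labels:
            raise KeyError(f"unknown agent label {agent!r}")
        return np.array([getattr(t, attr) == LEFT for t in self.trials])

    def colors(self, agent: str) -> np.ndarray:
        """Physical color selected by the agent per trial ('red'/'blue')."""
        own_color = COLOR_A if agent == self.agent_labels[0] else COLOR_B
        other_color = COLOR_B if own_color == COLOR_A else COLOR_A
        chose_own = self.choices(agent)
        return np.where(chose_own, own_color, other_color)

    def rewards(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([t.reward_A for t in self.trials], dtype=float)
        b = np.array([t.reward_B for t in self.trials], dtype=float)
        return a, b

    def coordinated(self) -> np.ndarray:
        return np.array([t.coordinated for t in self.trials])

    def visible(self) -> np.ndarray:
        return np.array([t.visible for t in self.trials])

    def action_times(self, agent: str) -> np.ndarray:
        """Per-trial action time (midpoint of the reach), NaN if missing."""
        if agent == self.agent_labels[0]:
            pairs = [(t.t_release_A, t.t_acquisition_A) for t in self.trials]
        elif agent == self.agent_labels[1]:
            pairs = [(t.t_release_B, t.t_acquisition_B) for t in self.trials]
        else:
            raise KeyError(f"unknown agent label {agent!r}")
        out = np.full(len(pairs), np.nan)
        for i, (rel, acq) in enumerate(pairs):
            if rel is not None and acq is not None:
                out[i] = rel + (acq - rel) / 2.0
        return out


def replace_trials(session: SessionData, trials: Sequence[TrialRecord]) -> SessionData:
    return SessionData(
        trials=list(trials),
        agent_labels=session.agent_labels,
        species=session.species,
        condition=session.condition,
        short_session=session.short_session,
    )


def payoff(
    choice_A: str,
    choice_B: str,
    layout: Optional[TrialLayout] = None,
    matrix: PayoffMatrix = DEFAULT_PAYOFF,
) -> tuple[int, int]:
    """Rewards for one trial given the two color-category choices.

    Coordination means both agents touched the same physical target:
    A choosing own (red) and B choosing other (red), or vice versa, so
    the trial is coordinated exactly when the choice labels differ.  The
    layout does not alter the payoff and may be omitted.
    """
    for c in (choice_A, choice_B):
        if c not in (OWN, OTHER):
            raise ValueError(f"choice must be 'own' or 'other', got {c!r}")
    coordinated = choice_A != choice_B
    return (
        matrix.reward(choice_A, coordinated),
        matrix.reward(choice_B, coordinated),
    )


def make_layout_schedule(n_trials: int, seed: int) -> list[TrialLayout]:
    """Balanced random layout schedule.

    Within every complete block of 18 trials each of the six red
    positions occurs exactly three times; a final partial block is a
    truncated freshly shuffled balanced block.  Deterministic for a
    fixed seed.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be positive, got {n_trials}")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(1, N_POSITIONS + 1), BLOCK_LEN // N_POSITIONS)
    positions: list[int] = []
    while len(positions) < n_trials:
        block = rng.permutation(base)
        positions.extend(block.tolist())
    return [TrialLayout(int(p)) for p in positions[:n_trials]]


def evaluate_trial(
    layout: TrialLayout,
    side_A: str,
    side_B: str,
    trial_index: int = 1,
    *,
    t_release_A: Optional[float] = None,
    t_acquisition_A: Optional[float] = None,
    t_release_B: Optional[float] = None,
    t_acquisition_B: Optional[float] = None,
    visible: bool = True,
    matrix: PayoffMatrix = DEFAULT_PAYOFF,
) -> TrialRecord:
    """Fill in choices, coordination and rewards from objective sides.

    Agent A chose its own color iff red was on ``side_A``; agent B chose
    its own color iff blue was on ``side_B``.  The trial is coordinated
    iff both sides (hence physical targets) agree.
    """
    for s in (side_A, side_B):
        if s not in (LEFT, RIGHT):
            raise ValueError(f"side must be 'L' or 'R', got {s!r}")
    choice_A = OWN if layout.color_on(side_A) == COLOR_A else OTHER
    choice_B = OWN if layout.color_on(side_B) == COLOR_B else OTHER
    coordinated = side_A == side_B
    reward_A = matrix.reward(choice_A, coordinated)
    reward_B = matrix.reward(choice_B, coordinated)
    return TrialRecord(
        trial_index=trial_index,
        layout=layout,
        side_A=side_A,
        side_B=side_B,
        choice_A=choice_A,
        choice_B=choice_B,
        coordinated=coordinated,
        reward_A=reward_A,
        reward_B=reward_B,
        t_release_A=t_release_A,
        t_acquisition_A=t_acquisition_A,
        t_release_B=t_release_B,
        t_acquisition_B=t_acquisition_B,
        visible=visible,
    )
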