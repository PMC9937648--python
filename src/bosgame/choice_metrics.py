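"""Fractions of choosing own/left, reward averages and session windows.

FCO (fraction of choosing own) is the fraction of trials in which an
agent selected its individually preferred color; FCL (fraction of
choosing left) the fraction in which it selected the objective-left
target.  Both come with a trailing running-window series (default w=8),
so windowed values live on the grid 0, 1/8, ..., 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .game_core import SessionData, replace_trials

__all__ = [
    "MetricSeries",
    "fco",
    "fcl",
    "average_reward",
    "last_n",
    "coordination_change_test",
    "trailing_mean",
]

DEFAULT_WINDOW = 8


@dataclass
class MetricSeries:
    """A session scalar plus its trailing running-window series.

    ``series[t]`` averages trials t-w+1..t (0-based); the first w-1
    entries are NaN because no full window is available there.
    """

    scalar: float
    series: np.ndarray
    window: int


def trailing_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Trailing w-point mean; NaN where fewer than w points precede."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    if len(x) >= w:
        c = np.cumsum(np.insert(x, 0, 0.0))
        out[w - 1 :] = (c[w:] - c[:-w]) / w
    return out


def fco(session: SessionData, agent: str, w: int = DEFAULT_WINDOW) -> MetricSeries:
    """Fraction of choosing the individually preferred color."""
    if len(session) == 0:
        raise ValueError("empty session")
    own = session.choices(agent).astype(float)
    return MetricSeries(scalar=float(own.mean()), series=trailing_mean(own, w), window=w)


def fcl(session: SessionData, agent: str, w: int = DEFAULT_WINDOW) -> MetricSeries:
    """Fraction of choosing the objective-left target."""
    if len(session) == 0:
        raise ValueError("empty session")
    left = session.sides(agent).astype(float)
    return MetricSeries(scalar=float(left.mean()), series=trailing_mean(left, w), window=w)


def average_reward(session: SessionData, who: str = "pair") -> float:
    """Mean payoff of one agent, or the pair's mean joint reward.

    ``who`` is an agent label or "pair"; the joint reward of a trial is
    (reward_A + reward_B) / 2 and cannot exceed 3.5.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    ra, rb = session.rewards()
    if who == "pair":
        return float((ra + rb).mean() / 2.0)
    if who == session.agent_labels[0]:
        return float(ra.mean())
    if who == session.agent_labels[1]:
        return float(rb.mean())
    raise KeyError(f"unknown agent label {who!r}")


def last_n(session: SessionData, n: int = 200) -> SessionData:
    """Final n trials of the session (steady-state window).

    Sessions shorter than n are returned whole with ``short_session``
    set, rather than rejected.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    out = replace_trials(session, session.trials[-n:])
    out.short_session = len(session) < n
    return out


@dataclass
class CoordinationChangeResult:
    odds_ratio: float
    p_value: float
    p_adjusted: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def coordination_change_test(
    early: SessionData, late: SessionData, bonferroni_factor: int = 1
) -> CoordinationChangeResult:
    """Fisher's exact test for a change in the coordinated-trial rate.

    The 2x2 table crosses coordinated/uncoordinated with early/late; the
    reported odds ratio is odds(coordinated | late) / odds(coordinated |
    early), so values > 1 mean coordination increased.  A degenerate
    table (some margin entirely one category) yields p = 1, flagged.
    """
    if len(early) == 0 or len(late) == 0:
        raise ValueError("both sessions must be non-empty")
    ce = int(early.coordinated().sum())
    ue = len(early) - ce
    cl = int(late.coordinated().sum())
    ul = len(late) - cl
    table = ((ce, ue), (cl, ul))
    degenerate = (ce + cl == 0) or (ue + ul == 0)
    if degenerate:
        p = 1.0
        oratio = float("nan")
    else:
        _, p = stats.fisher_exact([[ce, ue], [cl, ul]])
        if ul == 0 or ce == 0:
            oratio = float("inf")
        else:
            oratio = (cl * ue) / (ul * ce)
    return CoordinationChangeResult(
        odds_ratio=float(oratio),
        p_value=float(p),
        p_adjusted=float(min(1.0, p * bonferroni_factor)),
        table=table,
        degenerate=degenerate,
    )
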