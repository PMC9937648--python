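"""Coordination segments, seamless switches and uncoordinated-trial
classes.

A session partitions into maximal runs of one trial mode: coordination
on A's color, coordination on B's color, own-own (both insist) or
other-other (both yield).  A *seamless switch* is a pair of consecutive
coordinated trials whose coordination color differs - a change of
coordination mode with no intervening uncoordinated trial.  On the
switch trial the faster agent (smaller action time) either took its own
preferred color (selfish) or its non-preferred one (benevolent); the
balance of these counts against a fair coin separates egalitarian
turn-taking from temporal competition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binomtest

from .game_core import OWN, SessionData

__all__ = [
    "CoordinationSegment",
    "SwitchTally",
    "segment_coordination",
    "seamless_switches",
    "uncoordinated_classes",
    "transition_at_profile",
]

MODE_COORD_A = "coord_on_A_color"
MODE_COORD_B = "coord_on_B_color"
MODE_OWN_OWN = "own_own"
MODE_OTHER_OTHER = "other_other"
COORD_MODES = (MODE_COORD_A, MODE_COORD_B)


@dataclass(frozen=True)
class CoordinationSegment:
    start: int  # 0-based position of first trial in segment
    end: int    # inclusive
    mode: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def _trial_modes(session: SessionData) -> list[str]:
    modes = []
    for t in session:
        if t.coordinated:
            modes.append(MODE_COORD_A if t.coordination_color == "red" else MODE_COORD_B)
        elif t.choice_A == OWN:
            modes.append(MODE_OWN_OWN)
        else:
            modes.append(MODE_OTHER_OTHER)
    return modes


def segment_coordination(session: SessionData) -> list[CoordinationSegment]:
    """Partition the session into maximal constant-mode segments."""
    modes = _trial_modes(session)
    segments: list[CoordinationSegment] = []
    start = 0
    for i in range(1, len(modes) + 1):
        if i == len(modes) or modes[i] != modes[start]:
            segments.append(CoordinationSegment(start=start, end=i - 1, mode=modes[start]))
            start = i
    return segments


@dataclass
class SwitchTally:
    n_selfish: int
    n_benevolent: int
    n_unattributed: int
    ci_low: float
    ci_high: float
    verdict: str  # balanced / selfish / benevolent / not_applicable
    switches: list[dict] = field(default_factory=list)


def _balance_verdict(n_benevolent: int, n_total: int) -> tuple[float, float, str]:
    """Exact binomial 95% CI on the benevolent proportion vs. 0.5."""
    if n_total == 0:
        return float("nan"), float("nan"), "not_applicable"
    ci = binomtest(n_benevolent, n_total, 0.5).proportion_ci(confidence_level=0.95)
    if ci.low <= 0.5 <= ci.high:
        verdict = "balanced"
    elif ci.high < 0.5:
        verdict = "selfish"
    else:
        verdict = "benevolent"
    return float(ci.low), float(ci.high), verdict


def seamless_switches(session: SessionData) -> SwitchTally:
    """Tally the faster agent's behavior at seamless coordination switches.

    Per switch trial the agent with the smaller action time is the
    faster one; selfish if it chose its own color there, benevolent
    otherwise.  Switches with missing or tied action times are counted
    but left unattributed.
    """
    modes = _trial_modes(session)
    a_label, b_label = session.agent_labels
    at_a = session.action_times(a_label)
    at_b = session.action_times(b_label)
    records: list[dict] = []
    n_selfish = n_benevolent = n_unattributed = 0
    for i in range(1, len(modes)):
        if modes[i] in COORD_MODES and modes[i - 1] in COORD_MODES and modes[i] != modes[i - 1]:
            rec = {"trial": session.trials[i].trial_index, "to_mode": modes[i]}
            ta, tb = at_a[i], at_b[i]
            if np.isnan(ta) or np.isnan(tb) or ta == tb:
                n_unattributed += 1
                rec["faster"] = None
                rec["kind"] = "unattributed"
            else:
                faster_is_a = ta < tb
                rec["faster"] = a_label if faster_is_a else b_label
                choice = session.trials[i].choice_A if faster_is_a else session.trials[i].choice_B
                if choice == OWN:
                    n_selfish += 1
                    rec["kind"] = "selfish"
                else:
                    n_benevolent += 1
                    rec["kind"] = "benevolent"
            records.append(rec)
    lo, hi, verdict = _balance_verdict(n_benevolent, n_selfish + n_benevolent)
    return SwitchTally(
        n_selfish=n_selfish,
        n_benevolent=n_benevolent,
        n_unattributed=n_unattributed,
        ci_low=lo,
        ci_high=hi,
        verdict=verdict,
        switches=records,
    )


@dataclass
class UncoordinatedClasses:
    n_own_own: int
    n_other_other: int
    ci_low: float
    ci_high: float
    verdict: str


def uncoordinated_classes(session: SessionData) -> UncoordinatedClasses:
    """Counts of own-own vs other-other uncoordinated trials.

    The verdict tests the other-other (benevolent) proportion against
    0.5 with an exact binomial CI: "selfish" pairs sit below the
    diagonal (own-own excess), "benevolent" above.
    """
    modes = _trial_modes(session)
    n_oo = sum(m == MODE_OWN_OWN for m in modes)
    n_tt = sum(m == MODE_OTHER_OTHER for m in modes)
    lo, hi, verdict = _balance_verdict(n_tt, n_oo + n_tt)
    return UncoordinatedClasses(
        n_own_own=n_oo, n_other_other=n_tt, ci_low=lo, ci_high=hi, verdict=verdict
    )


def transition_at_profile(
    session: SessionData, halfwidth: int = 3
) -> dict[str, dict[int, dict[str, float]]]:
    """Mean action times around coordination transitions.

    For each transition type ("to_coordination", "from_coordination",
    "coordination_color_switch"), averages each agent's action time at
    trial offsets -halfwidth..+halfwidth relative to the first trial of
    the new segment.  Transitions closer than halfwidth to a session
    edge are excluded.  Empty when the session has no transitions.
    """
    modes = _trial_modes(session)
    a_label, b_label = session.agent_labels
    at_a = session.action_times(a_label)
    at_b = session.action_times(b_label)
    n = len(modes)
    buckets: dict[str, dict[int, list[tuple[float, float]]]] = {}
    for i in range(1, n):
        if modes[i] == modes[i - 1]:
            continue
        was_coord = modes[i - 1] in COORD_MODES
        is_coord = modes[i] in COORD_MODES
        if was_coord and is_coord:
            kind = "coordination_color_switch"
        elif is_coord:
            kind = "to_coordination"
        else:
            kind = "from_coordination"
        if i - halfwidth < 0 or i + halfwidth >= n:
            continue
        for off in range(-halfwidth, halfwidth + 1):
            buckets.setdefault(kind, {}).setdefault(off, []).append(
                (at_a[i + off], at_b[i + off])
            )
    profile: dict[str, dict[int, dict[str, float]]] = {}
    for kind, offsets in buckets.items():
        profile[kind] = {}
        for off, pairs in sorted(offsets.items()):
            arr = np.array(pairs, dtype=float)
            with np.errstate(invalid="ignore"):
                profile[kind][off] = {
                    a_label: float(np.nanmean(arr[:, 0])),
                    b_label: float(np.nanmean(arr[:, 1])),
                    "n": int(arr.shape[0]),
                }
    return profile
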