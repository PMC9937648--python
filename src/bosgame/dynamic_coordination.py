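"""Random-play reward baseline, the dynamic coordination reward (DCR)
and MI-plane strategy classification.

The DCR asks how much of a pair's joint reward exceeds what the same two
agents would earn by "playing randomly": keeping each agent's marginal
color-choice probabilities but permuting its choices independently over
trials.  That baseline, the reward for playing randomly (RPR), has a
closed form in the eight per-agent selection probabilities
P(agent, preferred/non-preferred, objective side).  DCR = R_actual - RPR
lies in [-1, 1] for this payoff matrix: +1 for perfect turn-taking, -1
for alternating anti-coordination, and 0 for static same-side
coordination (which earns 3.5 but no more than its own marginals already
guarantee).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import mutual_information as mi_mod
from .game_core import SessionData
from .choice_metrics import average_reward

__all__ = [
    "ChoiceProbabilities",
    "DCRResult",
    "choice_probs",
    "rpr",
    "dcr",
    "classify_strategy",
]


@dataclass
class ChoiceProbabilities:
    """The eight per-agent selection probabilities and layout frequencies.

    ``p[i][(c, side)]`` with i in {"A","B"}, c in {1 (non-preferred),
    2 (preferred)} and side in {"L","R"} (objective frame).  The four
    values of each agent sum to 1, and they are tied to the layout
    frequencies: P_A,2,L + P_A,1,R = P_B,1,L + P_B,2,R = Q_left.
    """

    p: dict
    q_left: float
    q_right: float

    def fco(self, agent: str) -> float:
        return self.p[agent][(2, "L")] + self.p[agent][(2, "R")]

    def fcl(self, agent: str) -> float:
        return self.p[agent][(1, "L")] + self.p[agent][(2, "L")]


def choice_probs(session: SessionData) -> ChoiceProbabilities:
    """Empirical selection probabilities (relative frequencies)."""
    if len(session) == 0:
        raise ValueError("empty session")
    n = len(session)
    p: dict = {}
    for agent_key, label in zip(("A", "B"), session.agent_labels):
        own = session.choices(label)
        left = session.sides(label)
        p[agent_key] = {
            (2, "L"): float(np.sum(own & left)) / n,
            (2, "R"): float(np.sum(own & ~left)) / n,
            (1, "L"): float(np.sum(~own & left)) / n,
            (1, "R"): float(np.sum(~own & ~left)) / n,
        }
    red_left = np.array([t.layout.red_side == "L" for t in session])
    q_left = float(red_left.mean())
    return ChoiceProbabilities(p=p, q_left=q_left, q_right=1.0 - q_left)


def rpr(probs: ChoiceProbabilities) -> float:
    """Expected joint reward under independent random play.

    Combines the outcome probabilities p_{a,b} (agent A earns a, B earns
    b) conditioned on where A's preferred color appears:

        p11 = P_A1R.P_B1L/Q_L + P_A1L.P_B1R/Q_R      (both yield)
        p22 = P_A2L.P_B2R/Q_L + P_A2R.P_B2L/Q_R      (both insist)
        p43 = P_A2L.P_B1L/Q_L + P_A2R.P_B1R/Q_R      (coordinate on A's)
        p34 = P_A1R.P_B2R/Q_L + P_A1L.P_B2L/Q_R      (coordinate on B's)

    and returns 3.5(p43+p34) + 2 p22 + p11, in [1, 3.5].
    """
    if probs.q_left <= 0.0 or probs.q_right <= 0.0:
        raise ValueError("layout frequencies must be strictly positive")
    a, b = probs.p["A"], probs.p["B"]
    ql, qr = probs.q_left, probs.q_right
    p11 = a[(1, "R")] * b[(1, "L")] / ql + a[(1, "L")] * b[(1, "R")] / qr
    p22 = a[(2, "L")] * b[(2, "R")] / ql + a[(2, "R")] * b[(2, "L")] / qr
    p43 = a[(2, "L")] * b[(1, "L")] / ql + a[(2, "R")] * b[(1, "R")] / qr
    p34 = a[(1, "R")] * b[(2, "R")] / ql + a[(1, "L")] * b[(2, "L")] / qr
    return 3.5 * (p43 + p34) + 2.0 * p22 + 1.0 * p11


def _probs_from_fco_fcl(fco_a: float, fcl_a: float, fco_b: float, fcl_b: float) -> ChoiceProbabilities:
    """Reconstruct the eight probabilities from FCO/FCL with Q = 0.5.

    With Q fixed at 0.5 the four per-agent probabilities are determined
    by FCO and FCL: P_i,2,L = (FCO_i + FCL_i - 0.5) / 2, the rest follow
    from the marginals.  Values are clipped to [0, 1] (degenerate
    corners of the confidence box can step outside).
    """
    p: dict = {}
    for key, (fco_i, fcl_i) in (("A", (fco_a, fcl_a)), ("B", (fco_b, fcl_b))):
        p2l = (fco_i + fcl_i - 0.5) / 2.0
        vals = {
            (2, "L"): p2l,
            (1, "L"): fcl_i - p2l,
            (2, "R"): fco_i - p2l,
            (1, "R"): 0.5 - p2l if key == "A" else (1.0 - fco_i) - (fcl_i - p2l),
        }
        p[key] = {k: float(np.clip(v, 0.0, 1.0)) for k, v in vals.items()}
    return ChoiceProbabilities(p=p, q_left=0.5, q_right=0.5)


@dataclass
class DCRResult:
    r_actual: float
    rpr: float
    dcr: float
    ci_low: float
    ci_high: float
    significant: bool
    n_trials: int


def dcr(session: SessionData, ci_z: float = 1.96) -> DCRResult:
    """Dynamic coordination reward with a corner-evaluated CI.

    R_actual is the session's mean joint reward; RPR is computed from
    the empirical FCO/FCL of both agents with the layout frequencies
    fixed at 0.5 (their design value).  The CI propagates normal-
    approximation binomial intervals (half-width z*sqrt(p(1-p)/n)) on
    the four marginals FCO_A, FCL_A, FCO_B, FCL_B through the RPR
    formula; because RPR is multilinear in the two agents' parameters
    its extrema over the 4-D box sit at the 16 corners.  The corner
    interval is then widened by z standard errors of the mean joint
    reward, since the actual reward carries sampling noise of its own
    beyond what the marginals determine (without this the interval
    under-covers under a permutation null).  The pair is significantly
    dynamically coordinated when 0 lies outside the CI.
    """
    n = len(session)
    if n == 0:
        raise ValueError("empty session")
    r_actual = average_reward(session, "pair")
    marginals = []
    for label in session.agent_labels:
        fco_i = float(session.choices(label).mean())
        fcl_i = float(session.sides(label).mean())
        marginals.extend([fco_i, fcl_i])
    fco_a, fcl_a, fco_b, fcl_b = marginals
    point_rpr = rpr(_probs_from_fco_fcl(fco_a, fcl_a, fco_b, fcl_b))
    value = r_actual - point_rpr

    deltas = [ci_z * np.sqrt(m * (1.0 - m) / n) for m in marginals]
    corner_dcrs = []
    for s in range(16):
        corner = [
            float(np.clip(m + (1 if (s >> k) & 1 else -1) * d, 0.0, 1.0))
            for k, (m, d) in enumerate(zip(marginals, deltas))
        ]
        corner_dcrs.append(r_actual - rpr(_probs_from_fco_fcl(*corner)))
    ra, rb = session.rewards()
    joint = (ra + rb) / 2.0
    se_r = float(joint.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    ci_low = min(min(corner_dcrs), value) - ci_z * se_r
    ci_high = max(max(corner_dcrs), value) + ci_z * se_r
    return DCRResult(
        r_actual=r_actual,
        rpr=point_rpr,
        dcr=value,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=not (ci_low <= 0.0 <= ci_high),
        n_trials=n,
    )


@dataclass
class StrategyClassification:
    label: str
    dcr_result: DCRResult
    mi_color: mi_mod.MIResult
    mi_side: mi_mod.MIResult
    coordination_fraction: float
    expected_coordination_fraction: float
    dominant_color_share: Optional[float] = None
    dominant_side_share: Optional[float] = None


def classify_strategy(
    session: SessionData,
    *,
    dcr_threshold: float = 0.2,
    mi_alpha: float = 0.01,
    n_surrogates: int = 1000,
    min_length: int = 50,
    dominance: float = 0.9,
    min_coord_fraction: float = 0.1,
    seed: int = 0,
    ci_z: float = 1.96,
) -> StrategyClassification:
    """MI-plane strategy classification of a dyadic session.

    dynamic_turn_taking: significant DCR above ``dcr_threshold`` with
    both MI side and MI color significant (the diagonal of the MI
    plane).  static_color: MI side significant, MI color not, and one
    physical color dominates the coordinated trials (near the MI-side
    axis).  static_side: the symmetric case.  uncoordinated: the
    coordination fraction does not exceed its random-play expectation.
    Anything else is unclassified.
    """
    if len(session) < min_length:
        raise ValueError(f"session shorter than min_length={min_length}")
    a_label, b_label = session.agent_labels
    colors_a = session.colors(a_label)
    colors_b = session.colors(b_label)
    sides_a = session.sides(a_label)
    sides_b = session.sides(b_label)
    mi_color = mi_mod.mi_significance(
        colors_a, colors_b, alpha=mi_alpha, n_surrogates=n_surrogates, seed=seed
    )
    mi_side = mi_mod.mi_significance(
        sides_a, sides_b, alpha=mi_alpha, n_surrogates=n_surrogates, seed=seed + 2
    )
    dcr_res = dcr(session, ci_z=ci_z)

    coord = session.coordinated()
    coord_frac = float(coord.mean())
    probs = choice_probs(session)
    probs_q = _probs_from_fco_fcl(
        probs.fco("A"), probs.fcl("A"), probs.fco("B"), probs.fcl("B")
    )
    # expected coordination probability under random play (p43 + p34)
    a, b = probs_q.p["A"], probs_q.p["B"]
    p43 = a[(2, "L")] * b[(1, "L")] / 0.5 + a[(2, "R")] * b[(1, "R")] / 0.5
    p34 = a[(1, "R")] * b[(2, "R")] / 0.5 + a[(1, "L")] * b[(2, "L")] / 0.5
    expected_coord = p43 + p34

    # dominance of a color/side among coordinated trials is meaningful
    # only when a non-trivial share of trials is coordinated at all
    dom_color = dom_side = None
    if coord.sum() >= max(10, int(round(min_coord_fraction * len(session)))):
        coord_colors = session.colors(a_label)[coord]
        dom_color = float(
            max(np.mean(coord_colors == "red"), np.mean(coord_colors == "blue"))
        )
        coord_sides = sides_a[coord]
        dom_side = float(max(np.mean(coord_sides), np.mean(~coord_sides)))

    n = len(session)
    se = float(np.sqrt(max(expected_coord * (1 - expected_coord), 1e-12) / n))
    above_chance = coord_frac > expected_coord + 1.96 * se

    if (
        dcr_res.significant
        and dcr_res.dcr > dcr_threshold
        and mi_color.significant
        and mi_side.significant
    ):
        label = "dynamic_turn_taking"
    elif (
        mi_side.significant
        and not mi_color.significant
        and dom_color is not None
        and dom_color >= dominance
    ):
        label = "static_color"
    elif (
        mi_color.significant
        and not mi_side.significant
        and dom_side is not None
        and dom_side >= dominance
    ):
        label = "static_side"
    elif not above_chance:
        label = "uncoordinated"
    else:
        label = "unclassified"
    return StrategyClassification(
        label=label,
        dcr_result=dcr_res,
        mi_color=mi_color,
        mi_side=mi_side,
        coordination_fraction=coord_frac,
        expected_coordination_fraction=float(expected_coord),
        dominant_color_share=dom_color,
        dominant_side_share=dom_side,
    )
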