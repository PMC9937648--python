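"""Action times, Welch action-time comparisons, the logistic action-
visibility model and its correlation with following behavior.

The action time of a reach is the midpoint between leaving the home
position (release) and touching the chosen target (acquisition) - a
proxy for when the movement becomes readable by the partner.  When one
agent acts later than the other it has a chance to see the partner's
choice first; that chance is modeled as a logistic function of the
action-time difference, psee(dt) = 1 / (1 + exp(-k (dt - dT0))), with
defaults k = 0.04 /ms and dT0 = 50 ms (so psee(50) = 0.5 and
psee(150) ~ 0.98).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .choice_metrics import trailing_mean, DEFAULT_WINDOW
from .game_core import SessionData

__all__ = [
    "ActionTimes",
    "PseeParams",
    "action_time",
    "at_tests",
    "psee",
    "visibility_correlation",
    "psee_robustness",
]

DEFAULT_DT0_GRID = (12.5, 25.0, 50.0, 75.0, 100.0, 200.0)
DEFAULT_K_GRID = (0.01, 0.02, 0.04, 0.08, 0.16)


@dataclass(frozen=True)
class ActionTimes:
    t_release: float
    t_acquisition: float
    t_movement: float
    t_action: float


@dataclass(frozen=True)
class PseeParams:
    """Logistic visibility model: slope k (1/ms), inflection dT0 (ms)."""

    k: float = 0.04
    dt0: float = 50.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


def action_time(t_release: float, t_acquisition: float) -> ActionTimes:
    """Movement time and its midpoint (the action time)."""
    if t_release > t_acquisition:
        raise ValueError(
            f"t_release ({t_release}) must not exceed t_acquisition ({t_acquisition})"
        )
    movement = t_acquisition - t_release
    return ActionTimes(
        t_release=t_release,
        t_acquisition=t_acquisition,
        t_movement=movement,
        t_action=t_release + movement / 2.0,
    )


@dataclass
class WelchResult:
    """Two-sample t-test with Satterthwaite's df approximation."""

    t: float
    df: float
    p_value: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int
    computable: bool = True
    description: str = ""


def _welch(g1: np.ndarray, g2: np.ndarray, description: str) -> WelchResult:
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    g1 = g1[~np.isnan(g1)]
    g2 = g2[~np.isnan(g2)]
    if len(g1) < 2 or len(g2) < 2:
        return WelchResult(
            t=float("nan"), df=float("nan"), p_value=float("nan"),
            mean_1=float(g1.mean()) if len(g1) else float("nan"),
            mean_2=float(g2.mean()) if len(g2) else float("nan"),
            sd_1=float("nan"), sd_2=float("nan"),
            n_1=len(g1), n_2=len(g2), computable=False, description=description,
        )
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    n1, n2 = len(g1), len(g2)
    if v1 == 0 and v2 == 0:
        # degenerate: identical-variance-free groups; equal means => t=0
        t_val = 0.0 if g1.mean() == g2.mean() else float("inf")
        p_val = 1.0 if t_val == 0.0 else 0.0
        df = float(n1 + n2 - 2)
    else:
        res = stats.ttest_ind(g1, g2, equal_var=False)
        t_val, p_val = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return WelchResult(
        t=t_val, df=df, p_value=p_val,
        mean_1=float(g1.mean()), mean_2=float(g2.mean()),
        sd_1=float(g1.std(ddof=1)), sd_2=float(g2.std(ddof=1)),
        n_1=n1, n_2=n2, computable=True, description=description,
    )


@dataclass
class ATTestResults:
    overall: WelchResult       # AT_A vs AT_B over all trials
    coordination_color: WelchResult  # dAT on A-color vs B-color coordinated trials
    coordination: WelchResult  # |dAT| on coordinated vs uncoordinated trials
    n_dropped: int = 0


def at_tests(session: SessionData) -> ATTestResults:
    """The three action-time difference comparisons of a dyadic session.

    (1) both agents' action times over all trials (stable leader-
    follower offsets); (2) the per-trial difference AT_A - AT_B between
    coordinated trials on A's color and on B's color (who waits for
    whom in which coordination mode); (3) the absolute per-trial
    difference between coordinated and uncoordinated trials.  All use
    Welch's t-test with Satterthwaite's approximation; trials with a
    missing action time on either side are dropped pairwise.
    """
    a_label, b_label = session.agent_labels
    at_a = session.action_times(a_label)
    at_b = session.action_times(b_label)
    ok = ~np.isnan(at_a) & ~np.isnan(at_b)
    n_dropped = int(np.sum(~ok))
    at_a, at_b = at_a[ok], at_b[ok]
    coord = session.coordinated()[ok]
    colors_a = session.colors(a_label)[ok]
    datt = at_a - at_b

    overall = _welch(at_a, at_b, "AT_A vs AT_B, all trials")
    on_a = coord & (colors_a == "red")
    on_b = coord & (colors_a == "blue")
    color_test = _welch(
        datt[on_a], datt[on_b], "AT_A - AT_B: coordination on A's vs B's color"
    )
    coord_test = _welch(
        np.abs(datt[coord]), np.abs(datt[~coord]),
        "|AT_A - AT_B|: coordinated vs uncoordinated trials",
    )
    return ATTestResults(
        overall=overall,
        coordination_color=color_test,
        coordination=coord_test,
        n_dropped=n_dropped,
    )


def psee(dt, params: PseeParams = PseeParams()):
    """Probability that the slower agent sees the partner's choice.

    ``dt`` is the action-time difference in ms (positive when the
    partner acted earlier); strictly increasing logistic with range
    (0, 1) and psee(dT0) = 0.5.
    """
    dt = np.asarray(dt, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates to psee=0
        out = 1.0 / (1.0 + np.exp(-params.k * (dt - params.dt0)))
    return float(out) if out.ndim == 0 else out


@dataclass
class VisibilityCorrelation:
    r_raw: float
    p_raw: float
    r_smoothed: float
    p_smoothed: float
    p_raw_shuffle: Optional[float] = None
    defined: bool = True


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), True


def visibility_correlation(
    session: SessionData,
    w: int = DEFAULT_WINDOW,
    params: PseeParams = PseeParams(),
    n_shuffles: int = 0,
    seed: int = 0,
) -> dict[str, VisibilityCorrelation]:
    """Correlation between modeled action visibility and following.

    For agent i the visibility argument is dt = AT_i - AT_partner
    (positive when i is slower and can thus see the partner move
    first).  The psee series is correlated (Pearson) with agent i's
    fraction-of-choosing-other's indicator (1 - own), both trial-by-
    trial (raw) and after trailing w-trial smoothing of both series.
    Optionally a shuffle null for the raw correlation is computed, since
    smoothing inflates autocorrelation.  Trials missing either agent's
    timestamps are dropped.
    """
    rng = np.random.default_rng(seed)
    a_label, b_label = session.agent_labels
    at = {a_label: session.action_times(a_label), b_label: session.action_times(b_label)}
    ok = ~np.isnan(at[a_label]) & ~np.isnan(at[b_label])
    out: dict[str, VisibilityCorrelation] = {}
    for me, other in ((a_label, b_label), (b_label, a_label)):
        dt = at[me][ok] - at[other][ok]
        ps = psee(dt, params)
        following = (~session.choices(me)[ok]).astype(float)
        r_raw, p_raw, defined_raw = _pearson(ps, following)
        ps_s = trailing_mean(ps, w)
        fo_s = trailing_mean(following, w)
        valid = ~np.isnan(ps_s)
        if valid.sum() >= 3:
            r_sm, p_sm, defined_sm = _pearson(ps_s[valid], fo_s[valid])
        else:
            r_sm, p_sm, defined_sm = float("nan"), float("nan"), False
        p_shuffle = None
        if n_shuffles > 0 and defined_raw:
            null = np.empty(n_shuffles)
            for j in range(n_shuffles):
                perm = rng.permutation(len(following))
                null[j] = np.corrcoef(ps, following[perm])[0, 1]
            p_shuffle = float((np.sum(np.abs(null) >= abs(r_raw)) + 1) / (n_shuffles + 1))
        out[me] = VisibilityCorrelation(
            r_raw=r_raw,
            p_raw=p_raw,
            r_smoothed=r_sm,
            p_smoothed=p_sm,
            p_raw_shuffle=p_shuffle,
            defined=defined_raw and defined_sm,
        )
    return out


def psee_robustness(
    session: SessionData,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    dt0_grid: Sequence[float] = DEFAULT_DT0_GRID,
    w: int = DEFAULT_WINDOW,
    default_k: float = 0.04,
    default_dt0: float = 50.0,
) -> list[dict]:
    """Sweep the visibility-model parameters and re-run the correlation.

    One grid varies dT0 at fixed k, the other varies k at fixed dT0
    (the defaults reproduce the 6 + 5 settings used for the robustness
    check).  Returns one row per setting with each agent's smoothed r.
    """
    rows: list[dict] = []
    settings = [("dt0", default_k, v) for v in dt0_grid]
    settings += [("k", v, default_dt0) for v in k_grid]
    for varied, k, dt0 in settings:
        res = visibility_correlation(session, w=w, params=PseeParams(k=k, dt0=dt0))
        row = {"varied": varied, "k": k, "dt0": dt0}
        for agent, vc in res.items():
            row[f"r_smoothed_{agent}"] = vc.r_smoothed
            row[f"r_raw_{agent}"] = vc.r_raw
            row[f"defined_{agent}"] = vc.defined
        rows.append(row)
    return rows
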