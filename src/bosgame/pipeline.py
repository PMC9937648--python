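"""Full-session analysis orchestration and byte-stable JSON reports."""

from __future__ import annotations

import json
import logging
from typing import Any, Optional

import numpy as np

from .action_time import PseeParams, WelchResult, at_tests, visibility_correlation
from . import choice_metrics as cm
from . import dynamic_coordination as dc
from . import transitions as tr
from .config import AnalysisConfig
from .game_core import SessionData

__all__ = ["analyze_session", "metrics_to_json"]

log = logging.getLogger("bosgame")


def _round6(x: Any) -> Any:
    """Recursively format floats to 6 significant digits."""
    if isinstance(x, float):
        if np.isnan(x):
            return None
        if np.isinf(x):
            return None  # JSON has no infinity; flagged fields carry the context
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    if isinstance(x, (np.floating,)):
        return _round6(float(x))
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def _welch_dict(w: WelchResult) -> dict:
    return {
        "description": w.description,
        "t": w.t,
        "df": w.df,
        "p_value": w.p_value,
        "mean_1": w.mean_1,
        "mean_2": w.mean_2,
        "sd_1": w.sd_1,
        "sd_2": w.sd_2,
        "n_1": w.n_1,
        "n_2": w.n_2,
        "computable": w.computable,
    }


def analyze_session(
    session: SessionData, config: Optional[AnalysisConfig] = None
) -> dict:
    """Compute the full metrics bundle on the steady-state window.

    Applies the last-n window, then assembles FCO/FCL, average and
    joint rewards, MI color/side with surrogate significance, the DCR
    with its confidence interval, the MI-plane strategy classification,
    the three action-time tests, the visibility correlations and the
    switch/uncoordinated-trial tallies.  Deterministic for a fixed
    config (the config is echoed into the bundle).
    """
    config = config or AnalysisConfig()
    labels = list(session.agent_labels)
    dyadic = len(labels) == 2
    win = cm.last_n(session, config.last_n)
    if win.short_session:
        log.warning("session shorter than last_n=%d (%d trials)", config.last_n, len(win))
    bundle: dict = {
        "config": config.to_dict(),
        "n_trials_total": len(session),
        "n_trials_analyzed": len(win),
        "short_session": win.short_session,
    }
    bundle["fco"] = {lbl: cm.fco(win, lbl, config.w).scalar for lbl in labels}
    bundle["fcl"] = {lbl: cm.fcl(win, lbl, config.w).scalar for lbl in labels}
    rewards = {lbl: cm.average_reward(win, lbl) for lbl in labels}
    if dyadic:
        rewards["pair"] = cm.average_reward(win, "pair")
    bundle["average_reward"] = rewards
    if not dyadic:
        bundle["dyadic_metrics"] = "not_applicable"
        log.info("solo session: dyadic metrics skipped")
        return _round6(bundle)
    a_label, b_label = labels
    bundle["coordination_fraction"] = float(win.coordinated().mean())

    mi_color = dc.mi_mod.mi_significance(
        win.colors(a_label), win.colors(b_label),
        alpha=config.mi_alpha, n_surrogates=config.n_surrogates, seed=config.seed,
    )
    mi_side = dc.mi_mod.mi_significance(
        win.sides(a_label), win.sides(b_label),
        alpha=config.mi_alpha, n_surrogates=config.n_surrogates, seed=config.seed + 2,
    )
    bundle["mi"] = {
        "color": {
            "mi_bits": mi_color.mi_bits,
            "threshold_bits": mi_color.surrogate_threshold_bits,
            "significant": mi_color.significant,
        },
        "side": {
            "mi_bits": mi_side.mi_bits,
            "threshold_bits": mi_side.surrogate_threshold_bits,
            "significant": mi_side.significant,
        },
    }
    dcr_res = dc.dcr(win, ci_z=config.dcr_z)
    bundle["dcr"] = {
        "r_actual": dcr_res.r_actual,
        "rpr": dcr_res.rpr,
        "dcr": dcr_res.dcr,
        "ci_low": dcr_res.ci_low,
        "ci_high": dcr_res.ci_high,
        "significant": dcr_res.significant,
        "n_trials": dcr_res.n_trials,
    }
    classification = dc.classify_strategy(
        win,
        dcr_threshold=config.dcr_threshold,
        mi_alpha=config.mi_alpha,
        n_surrogates=config.n_surrogates,
        min_length=min(config.min_length, len(win)),
        seed=config.seed,
        ci_z=config.dcr_z,
    )
    bundle["classification"] = {
        "label": classification.label,
        "coordination_fraction": classification.coordination_fraction,
        "expected_coordination_fraction": classification.expected_coordination_fraction,
        "dominant_color_share": classification.dominant_color_share,
        "dominant_side_share": classification.dominant_side_share,
    }

    tests = at_tests(win)
    if tests.n_dropped:
        log.info("dropped %d trials with missing action times", tests.n_dropped)
    bundle["at_tests"] = {
        "overall": _welch_dict(tests.overall),
        "coordination_color": _welch_dict(tests.coordination_color),
        "coordination": _welch_dict(tests.coordination),
        "n_dropped": tests.n_dropped,
    }
    params = PseeParams(k=config.psee_k, dt0=config.psee_dt0)
    vis = visibility_correlation(win, w=config.w, params=params, seed=config.seed)
    bundle["visibility_correlation"] = {
        lbl: {
            "r_raw": vc.r_raw,
            "p_raw": vc.p_raw,
            "r_smoothed": vc.r_smoothed,
            "p_smoothed": vc.p_smoothed,
            "defined": vc.defined,
        }
        for lbl, vc in vis.items()
    }
    switches = tr.seamless_switches(win)
    bundle["seamless_switches"] = {
        "n_selfish": switches.n_selfish,
        "n_benevolent": switches.n_benevolent,
        "n_unattributed": switches.n_unattributed,
        "ci_low": switches.ci_low,
        "ci_high": switches.ci_high,
        "verdict": switches.verdict,
    }
    uncoord = tr.uncoordinated_classes(win)
    bundle["uncoordinated_classes"] = {
        "n_own_own": uncoord.n_own_own,
        "n_other_other": uncoord.n_other_other,
        "ci_low": uncoord.ci_low,
        "ci_high": uncoord.ci_high,
        "verdict": uncoord.verdict,
    }
    return _round6(bundle)


def metrics_to_json(bundle: dict) -> str:
    """Serialize a metrics bundle with stable key order."""
    return json.dumps(bundle, indent=2, sort_keys=False, allow_nan=False)
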