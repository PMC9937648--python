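"""Session TSV reader/writer.

Dialect: tab-separated, UTF-8, header row, columns

    trial, red_side{L,R}, red_pos{1..6}, side_A{L,R}, side_B{L,R},
    choice_A{own,other}, choice_B{own,other}, reward_A, reward_B,
    t_rel_A_ms, t_acq_A_ms, t_rel_B_ms, t_acq_B_ms, visible{0,1}

Missing timestamps are empty fields.  The writer emits exactly this
dialect; the reader validates every derivable invariant (choices and
rewards against layout and sides, timestamp ordering, increasing trial
indices) and fails loudly with the offending row number.  Floats are
written with ``repr`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Optional, Union

from .game_core import SessionData, TrialLayout, TrialRecord, evaluate_trial

__all__ = ["read_session", "write_session", "COLUMNS"]

COLUMNS = [
    "trial", "red_side", "red_pos", "side_A", "side_B",
    "choice_A", "choice_B", "reward_A", "reward_B",
    "t_rel_A_ms", "t_acq_A_ms", "t_rel_B_ms", "t_acq_B_ms", "visible",
]


class SessionFormatError(ValueError):
    def __init__(self, row: Optional[int], message: str):
        self.row = row
        where = f"row {row}: " if row is not None else ""
        super().__init__(f"{where}{message}")


def _fmt_ts(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def write_session(session: SessionData, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for t in session:
            writer.writerow(
                [
                    t.trial_index,
                    t.layout.red_side,
                    t.layout.red_position,
                    t.side_A,
                    t.side_B,
                    t.choice_A,
                    t.choice_B,
                    t.reward_A,
                    t.reward_B,
                    _fmt_ts(t.t_release_A),
                    _fmt_ts(t.t_acquisition_A),
                    _fmt_ts(t.t_release_B),
                    _fmt_ts(t.t_acquisition_B),
                    int(t.visible),
                ]
            )


def _parse_ts(field: str) -> Optional[float]:
    return None if field == "" else float(field)


def read_session(path: Union[str, Path], **session_kwargs) -> SessionData:
    """Read and validate a session TSV (tolerates CRLF line endings)."""
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.reader(_io.StringIO(text, newline=""), delimiter="\t")
    rows = [r for r in reader if r]
    if not rows:
        raise SessionFormatError(None, "empty file")
    header = [h.strip() for h in rows[0]]
    if header != COLUMNS:
        raise SessionFormatError(1, f"bad header {header!r}, expected {COLUMNS!r}")
    trials: list[TrialRecord] = []
    prev_index = 0
    for rownum, row in enumerate(rows[1:], start=2):
        if len(row) != len(COLUMNS):
            raise SessionFormatError(rownum, f"expected {len(COLUMNS)} fields, got {len(row)}")
        try:
            rec = _parse_row(row)
        except (ValueError, KeyError) as exc:
            raise SessionFormatError(rownum, str(exc)) from exc
        if rec.trial_index <= prev_index:
            raise SessionFormatError(
                rownum, f"trial index {rec.trial_index} not increasing (previous {prev_index})"
            )
        prev_index = rec.trial_index
        trials.append(rec)
    return SessionData(trials=trials, **session_kwargs)


def _parse_row(row: list[str]) -> TrialRecord:
    d = dict(zip(COLUMNS, (f.strip() for f in row)))
    layout = TrialLayout(int(d["red_pos"]))
    if d["red_side"] != layout.red_side:
        raise ValueError(
            f"red_side {d['red_side']!r} inconsistent with red_pos {d['red_pos']}"
        )
    expected = evaluate_trial(layout, d["side_A"], d["side_B"])
    for col, want in (
        ("choice_A", expected.choice_A),
        ("choice_B", expected.choice_B),
    ):
        if d[col] != want:
            raise ValueError(f"{col} {d[col]!r} inconsistent with layout/sides (expected {want})")
    for col, want in (("reward_A", expected.reward_A), ("reward_B", expected.reward_B)):
        if int(d[col]) != want:
            raise ValueError(f"{col} {d[col]} inconsistent with choices (expected {want})")
    if d["visible"] not in ("0", "1"):
        raise ValueError(f"visible must be 0 or 1, got {d['visible']!r}")
    return TrialRecord(
        trial_index=int(d["trial"]),
        layout=layout,
        side_A=d["side_A"],
        side_B=d["side_B"],
        choice_A=d["choice_A"],
        choice_B=d["choice_B"],
        coordinated=expected.coordinated,
        reward_A=expected.reward_A,
        reward_B=expected.reward_B,
        t_release_A=_parse_ts(d["t_rel_A_ms"]),
        t_acquisition_A=_parse_ts(d["t_acq_A_ms"]),
        t_release_B=_parse_ts(d["t_rel_B_ms"]),
        t_acquisition_B=_parse_ts(d["t_acq_B_ms"]),
        visible=d["visible"] == "1",
    )
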