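"""Session and configuration file formats.

Sessions are tidy comma-separated text: one trial per row with a header
row, UTF-8, "." decimal, label strings for islands/planes/conditions, and
1-indexed trial numbers (0-indexed in memory).  The first line is a
versioned format tag comment; the second carries session metadata as JSON.
Configs and run manifests are YAML.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .task_env import (CONDITIONS, ISLANDS, PLANES, SessionData, TaskRules,
                       TrialRecord, make_rules)

FORMAT_TAG = "# explorepredict-session v1"

COLUMNS = ["trial", "phase", "run", "block", "condition", "trial_type",
           "departure", "offered_1", "offered_2", "queried_plane", "choice",
           "outcome", "feedback", "diagnostic_chosen"]


def _label(value, labels) -> str:
    return "" if value is None else labels[value]


def _choice_label(rec: TrialRecord) -> str:
    if rec.trial_type == "explore":
        return PLANES[rec.choice]
    if rec.trial_type == "state_pred":
        return ISLANDS[rec.choice]
    return CONDITIONS[rec.choice]


def session_frame(session: SessionData) -> pd.DataFrame:
    """Tidy DataFrame view of a session (1-indexed, label strings)."""
    rows = []
    for r in session.records:
        rows.append({
            "trial": r.index + 1,
            "phase": r.phase,
            "run": r.run + 1,
            "block": r.block + 1,
            "condition": CONDITIONS[r.condition],
            "trial_type": r.trial_type,
            "departure": ISLANDS[r.departure],
            "offered_1": PLANES[r.offered[0]],
            "offered_2": PLANES[r.offered[1]],
            "queried_plane": _label(r.queried_plane, PLANES),
            "choice": _choice_label(r),
            "outcome": _label(r.outcome, ISLANDS),
            "feedback": "" if r.feedback is None else str(bool(r.feedback)),
            "diagnostic_chosen": ("" if r.diagnostic_chosen is None
                                  else str(bool(r.diagnostic_chosen))),
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_session(session: SessionData, path) -> None:
    path = Path(path)
    meta = {k: v for k, v in session.meta.items()
            if isinstance(v, (str, int, float, bool, type(None)))}
    meta["color_map"] = list(session.rules.color_map)
    meta["route"] = list(session.rules.route)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(FORMAT_TAG + "\n")
        fh.write("# meta=" + json.dumps(meta, sort_keys=True) + "\n")
        session_frame(session).to_csv(fh, index=False)


def _index(label: str, labels, column: str, row: int) -> Optional[int]:
    if label == "" or pd.isna(label):
        return None
    try:
        return labels.index(label)
    except ValueError:
        raise ValueError(f"row {row}: bad value {label!r} in column {column!r}")


def read_session(path) -> SessionData:
    """Read a session file; rejects unknown versions and missing columns."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        tag = fh.readline().strip()
        if tag != FORMAT_TAG:
            raise ValueError(f"{path}: unrecognized format tag {tag!r}")
        meta_line = fh.readline().strip()
        meta = json.loads(meta_line[len("# meta="):]) if meta_line.startswith("# meta=") else {}
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    rules = make_rules(color_map=meta.get("color_map"), route=meta.get("route"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ttype = row.trial_type
        if ttype == "explore":
            choice = _index(row.choice, PLANES, "choice", i)
        elif ttype == "state_pred":
            choice = _index(row.choice, ISLANDS, "choice", i)
        elif ttype == "condition_pred":
            choice = _index(row.choice, CONDITIONS, "choice", i)
        else:
            raise ValueError(f"row {i}: unknown trial_type {ttype!r}")
        records.append(TrialRecord(
            index=int(row.trial) - 1,
            phase=row.phase,
            run=int(row.run) - 1,
            block=int(row.block) - 1,
            condition=_index(row.condition, CONDITIONS, "condition", i),
            trial_type=ttype,
            departure=_index(row.departure, ISLANDS, "departure", i),
            offered=(_index(row.offered_1, PLANES, "offered_1", i),
                     _index(row.offered_2, PLANES, "offered_2", i)),
            queried_plane=_index(row.queried_plane, PLANES, "queried_plane", i),
            choice=choice,
            outcome=_index(row.outcome, ISLANDS, "outcome", i),
            feedback=None if row.feedback == "" else row.feedback == "True",
            diagnostic_chosen=(None if row.diagnostic_chosen == ""
                               else row.diagnostic_chosen == "True"),
        ))
    return SessionData(records=records, rules=rules, plan=None, meta=meta)


def write_yaml(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
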