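"""Readers and writers for score tables, traces, and run configs.

One CSV dialect throughout (comma, UTF-8, header required).  The score
table schema is::

    subject_id,task_1,...,task_14[,risk_label]

with blank cells parsing to the missing marker and ``risk_label`` in
{high, medium, low}.  If the label column is absent and a subject has all
scores present, the label is derived from the total-score risk bands.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .battery import (
    Battery,
    Cohort,
    RiskCategory,
    ScoreVector,
    classify_risk,
    standard_battery,
)
from .session import SessionStep, SessionTrace

__all__ = [
    "ScoreTableError",
    "read_score_table",
    "write_score_table",
    "write_trace_bundle",
    "read_trace_bundle",
    "load_config",
    "dump_config",
]


class ScoreTableError(ValueError):
    """Malformed score table; message carries the offending row number."""


def _parse_score(cell: str, row_no: int, col: str) -> float:
    cell = cell.strip()
    if cell == "":
        return np.nan
    try:
        val = int(cell)
    except ValueError:
        raise ScoreTableError(
            f"row {row_no}: task column {col!r} has non-integer score {cell!r}"
        ) from None
    if not 0 <= val <= 4:
        raise ScoreTableError(f"row {row_no}: score {val} in {col!r} outside 0..4")
    return float(val)


def read_score_table(path, battery: Battery | None = None) -> Cohort:
    """Parse a cohort CSV into a :class:`Cohort` (labels derived if absent)."""
    battery = battery or standard_battery()
    path = Path(path)
    task_cols = [f"task_{t}" for t in battery.task_ids]
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ScoreTableError("empty file: missing header") from None
        header = [h.strip() for h in header]
        expected = ["subject_id", *task_cols]
        has_label = header == expected + ["risk_label"]
        if not has_label and header != expected:
            raise ScoreTableError(
                f"malformed header {header}; expected {expected} (+ optional risk_label)"
            )
        rows, labels, sids = [], [], []
        for row_no, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            want = len(header)
            if len(row) != want:
                raise ScoreTableError(
                    f"row {row_no}: expected {want} fields, got {len(row)}"
                )
            sid = row[0].strip()
            scores = [
                _parse_score(c, row_no, col) for c, col in zip(row[1:], task_cols)
            ]
            if has_label and row[-1].strip() != "":
                try:
                    lab = int(RiskCategory.from_label(row[-1]))
                except ValueError as e:
                    raise ScoreTableError(f"row {row_no}: {e}") from None
            elif not any(np.isnan(s) for s in scores):
                lab = int(classify_risk(int(sum(scores))))
            else:
                lab = -1  # unlabeled and incomplete
            rows.append(scores)
            labels.append(lab)
            sids.append(sid)
    df = pd.DataFrame(rows, index=sids, columns=list(battery.task_ids), dtype=float)
    lab_arr = np.array(labels)
    return Cohort(df, None if (lab_arr < 0).any() else lab_arr, battery)


def write_score_table(cohort: Cohort, path) -> None:
    path = Path(path)
    task_cols = [f"task_{t}" for t in cohort.battery.task_ids]
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        header = ["subject_id", *task_cols]
        if cohort.labels is not None:
            header.append("risk_label")
        w.writerow(header)
        for i, sid in enumerate(cohort.subject_ids):
            row = [sid]
            for t in cohort.battery.task_ids:
                v = cohort.scores.iloc[i][t]
                row.append("" if np.isnan(v) else str(int(v)))
            if cohort.labels is not None:
                row.append(RiskCategory(int(cohort.labels[i])).label)
            w.writerow(row)


def _trace_to_dict(tr: SessionTrace) -> dict:
    return {
        "subject_id": tr.subject_id,
        "initial_subset": sorted(tr.initial_subset),
        "stop_reason": tr.stop_reason,
        "steps": [
            {
                "added_task": s.added_task,
                "subset": sorted(s.subset),
                "prediction": s.prediction.label,
                "confidence": s.confidence,
            }
            for s in tr.steps
        ],
    }


def _trace_from_dict(d: dict) -> SessionTrace:
    steps = [
        SessionStep(
            s["added_task"],
            frozenset(s["subset"]),
            RiskCategory.from_label(s["prediction"]),
            float(s["confidence"]),
        )
        for s in d["steps"]
    ]
    return SessionTrace(
        d["subject_id"], frozenset(d["initial_subset"]), steps, d["stop_reason"]
    )


def write_trace_bundle(traces: Iterable[SessionTrace], out_dir) -> tuple[Path, Path]:
    """Write full traces (JSON) plus a per-subject summary (CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traces = list(traces)
    json_path = out_dir / "traces.json"
    csv_path = out_dir / "summary.csv"
    json_path.write_text(
        json.dumps([_trace_to_dict(t) for t in traces], indent=1), encoding="utf-8"
    )
    with csv_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "n_tasks", "prediction", "confidence", "stop_reason"])
        for t in traces:
            w.writerow(
                [
                    t.subject_id,
                    t.n_tasks_used,
                    t.final_prediction.label,
                    f"{t.final_confidence:.6f}",
                    t.stop_reason,
                ]
            )
    return json_path, csv_path


def read_trace_bundle(out_dir) -> list[SessionTrace]:
    data = json.loads((Path(out_dir) / "traces.json").read_text(encoding="utf-8"))
    return [_trace_from_dict(d) for d in data]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(cfg, path) -> None:
    path = Path(path)
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(cfg, indent=1, default=str), encoding="utf-8")
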