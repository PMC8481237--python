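"""Trial-table and configuration I/O.

Trial tables are comma-separated UTF-8 text with one row per trial and
the header

    coherence,duration_ms,sure_shown,choice,correct,confidence,decision_ms

``coherence`` is a signed fraction, durations are in milliseconds and
must be multiples of the 10-ms step (they are converted to steps on
read), and ``choice``/``correct``/``confidence``/``decision_ms`` are
optional (stimulus-only tables omit them). Configurations and
provenance records are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["TrialTableError", "read_trials", "write_trials", "write_provenance"]

_REQUIRED = ("coherence", "duration_ms", "sure_shown")
_OPTIONAL = ("choice", "correct", "confidence", "decision_ms")
_CHOICES = {"left", "right", "sure"}


class TrialTableError(ValueError):
    """Raised for schema violations; carries row-level messages."""

    def __init__(self, message: str, row_errors: list | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


def read_trials(path, dt_ms: float = 10.0, strict: bool = True):
    """Read and validate a trial table.

    Returns ``(frame, row_errors)``; with ``strict=True`` any row-level
    problem raises :class:`TrialTableError` instead. Malformed rows are
    reported with their 1-based line number (header is line 1) and
    dropped from the returned frame. An empty file yields an empty frame
    and a warning entry rather than an error.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        empty = pd.DataFrame(columns=list(_REQUIRED) + ["duration_steps"])
        return empty, [f"{path}: empty file, no trials read"]
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required columns {missing}")

    errors = []
    keep = np.ones(len(raw), dtype=bool)

    def flag(mask, msg):
        for i in np.flatnonzero(mask):
            errors.append(f"{path}:{i + 2}: {msg}")
        keep[np.asarray(mask)] = False

    coh = pd.to_numeric(raw["coherence"], errors="coerce")
    flag(coh.isna().to_numpy(), "coherence is not a number")
    dur = pd.to_numeric(raw["duration_ms"], errors="coerce")
    flag(dur.isna().to_numpy(), "duration_ms is not a number")
    ok_dur = ~dur.isna()
    bad_step = ok_dur & ((dur <= 0) | ((dur % dt_ms) != 0))
    flag(bad_step.to_numpy(), f"duration_ms must be a positive multiple of {dt_ms}")
    sure = raw["sure_shown"]
    if sure.dtype != bool:
        sure = sure.astype(str).str.strip().str.lower()
        bad_sure = ~sure.isin(["true", "false", "0", "1"])
        flag(bad_sure.to_numpy(), "sure_shown must be boolean")
        sure = sure.isin(["true", "1"])
    if "choice" in raw.columns:
        ch = raw["choice"].astype(str).str.strip().str.lower()
        flag((~ch.isin(_CHOICES)).to_numpy(), f"choice must be one of {sorted(_CHOICES)}")
        flag(
            ((ch == "sure") & ~sure).to_numpy(),
            "choice is 'sure' but sure_shown is false",
        )
    if "confidence" in raw.columns:
        conf = pd.to_numeric(raw["confidence"], errors="coerce")
        flag(((conf < 0) | (conf > 1)).to_numpy(), "confidence outside [0, 1]")

    if errors and strict:
        raise TrialTableError(f"{path}: {len(errors)} invalid rows", errors)

    frame = raw.loc[keep].copy()
    frame["coherence"] = pd.to_numeric(frame["coherence"])
    frame["duration_steps"] = (
        pd.to_numeric(frame["duration_ms"]) / dt_ms
    ).astype(int)
    frame["sure_shown"] = np.asarray(sure)[keep]
    if "choice" in frame.columns:
        frame["choice"] = frame["choice"].astype(str).str.strip().str.lower()
    if "correct" in frame.columns:
        frame["correct"] = frame["correct"].astype(bool)
    return frame.reset_index(drop=True), errors


def write_trials(frame: pd.DataFrame, path, dt_ms: float = 10.0) -> None:
    """Write a trial table; internal step counts become milliseconds."""
    out = frame.copy()
    if "duration_ms" not in out.columns:
        out["duration_ms"] = out["duration_steps"] * dt_ms
    if "decision_ms" not in out.columns and "decision_step" in out.columns:
        out["decision_ms"] = out["decision_step"] * dt_ms
    cols = [c for c in ("coherence", "duration_ms", "sure_shown") if c in out.columns]
    cols += [c for c in _OPTIONAL if c in out.columns]
    out[cols].to_csv(path, index=False)


def write_provenance(path, command: str, config: dict, seed, version: str) -> None:
    """Record how an artifact was produced (YAML key-value)."""
    record = {
        "command": command,
        "seed": seed,
        "package_version": version,
        "config": _jsonable(config),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
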