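"""Tabular input/output.

All tables are tab-separated UTF-8 text with a single header row and "."
as the decimal mark, matching common eye-tracker exports.

Fixation tables carry one row per fixation event with the columns
``subject_id, phase, run, trial, condition, x_px, y_px, start_ms,
stop_ms, rank``.  Coordinates are 0-based pixels in the full-screen
frame; events outside the analysis crop are *flagged*, never dropped, so
that downstream stages decide what to exclude.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig

FIXATION_COLUMNS = [
    "subject_id", "phase", "run", "trial", "condition",
    "x_px", "y_px", "start_ms", "stop_ms", "rank",
]
SCR_COLUMNS = ["subject_id", "phase", "run", "trial", "condition", "phasic_amp"]
RATING_COLUMNS = ["subject_id", "phase", "condition", "rating"]

PHASES = ("baseline", "conditioning", "generalization")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowParseError(ValueError):
    """A row failed to parse; carries the 1-based data line number."""


@dataclass(frozen=True)
class FixationEvent:
    """One fixation with its trial labels, position and timing.

    ``rank`` is 1-based within the trial; rank 1 is the landing fixation
    on the face.  ``in_crop`` flags whether the event falls inside the
    centered analysis window.
    """

    subject_id: str
    phase: str
    run: int
    trial: int
    condition: str
    x: float
    y: float
    start: float
    stop: float
    rank: int
    in_crop: bool = True

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValueError(
                f"fixation stop ({self.stop}) must exceed start ({self.start})"
            )
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


def events_to_frame(events) -> pd.DataFrame:
    """Event collection -> table with the canonical fixation columns."""
    return pd.DataFrame(
        [
            {
                "subject_id": e.subject_id, "phase": e.phase, "run": e.run,
                "trial": e.trial, "condition": e.condition,
                "x_px": e.x, "y_px": e.y,
                "start_ms": e.start, "stop_ms": e.stop, "rank": e.rank,
            }
            for e in events
        ],
        columns=FIXATION_COLUMNS,
    )


def frame_to_events(df: pd.DataFrame, config: PipelineConfig) -> list:
    """Table -> sorted event list with in-crop flags."""
    events = [
        FixationEvent(
            subject_id=str(r.subject_id), phase=str(r.phase), run=int(r.run),
            trial=int(r.trial), condition=str(r.condition),
            x=float(r.x_px), y=float(r.y_px),
            start=float(r.start_ms), stop=float(r.stop_ms), rank=int(r.rank),
            in_crop=config.in_crop(float(r.x_px), float(r.y_px)),
        )
        for r in df.itertuples(index=False)
    ]
    events.sort(key=lambda e: (e.subject_id, e.phase, e.run, e.trial, e.rank))
    return events


def read_fixation_table(path, config: PipelineConfig | None = None) -> list:
    """Read a fixation TSV into a deterministically ordered event list.

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    RowParseError
        If a coordinate or timing field is non-numeric (the message
        carries the offending data line number).
    """
    if config is None:
        config = PipelineConfig()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    numeric = ["run", "trial", "x_px", "y_px", "start_ms", "stop_ms", "rank"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise RowParseError(
                f"{path.name}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = parsed
    return frame_to_events(df, config)


def write_fixation_table(events, path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_table(path, columns=None) -> pd.DataFrame:
    """Read a generic TSV, optionally validating required columns."""
    df = pd.read_csv(path, sep="\t")
    if columns:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{Path(path).name}: missing required column(s): {', '.join(missing)}"
            )
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict, out_dir, arrays: dict | None = None) -> pd.DataFrame:
    """Write named result tables (and optional arrays) to ``out_dir``.

    Tables go out as TSV; arrays additionally as ``.npz`` containers.
    Returns a manifest listing file name, row count and checksum; the
    manifest itself is also written as ``manifest.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        records.append({"file": p.name, "rows": len(df), "sha256": _sha256(p)})
    for name, arr in (arrays or {}).items():
        p = out_dir / f"{name}.npz"
        np.savez_compressed(p, **({"value": arr} if isinstance(arr, np.ndarray) else arr))
        records.append({"file": p.name, "rows": -1, "sha256": _sha256(p)})
    manifest = pd.DataFrame(records, columns=["file", "rows", "sha256"])
    if records:
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
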