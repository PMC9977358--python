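"""Tab-separated events tables (BIDS-style: onset and duration first).

One events table per block/run carries the schedule columns, and — once a
session has been simulated or collected — the behavioral columns
(response, rt_ms, pas, contrast at presentation).  Round-tripping through
``write_events``/``load_events`` is lossless on the documented columns and
preserves unknown extra columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ExperimentDesign, TrialSpec
from .observers import BehavioralRecord


class SchemaError(ValueError):
    """A mandatory events column is missing; the message names it."""


class EventsParseError(ValueError):
    """A numeric events field failed to parse; the message cites the line."""


MANDATORY_COLUMNS = [
    "onset",
    "duration",
    "trial_index",
    "block",
    "condition",
    "distractor_present",
    "cue_shape",
    "target_quadrant",
    "distractor_quadrant",
    "probe_type",
    "probe_quadrant",
    "delay",
    "contrast_rgb",
]

BEHAVIOR_COLUMNS = ["response", "rt_ms", "pas"]

_NUMERIC = {"onset", "duration", "trial_index", "block", "delay", "contrast_rgb", "rt_ms", "pas"}
_NA = "n/a"


def schedule_to_table(
    schedule: list[TrialSpec],
    design: ExperimentDesign,
    records: list[BehavioralRecord] | None = None,
) -> pd.DataFrame:
    """Schedule (plus optional behavior) as one events DataFrame."""
    rows = []
    by_index = {}
    if records is not None:
        by_index = {r.trial_index: r for r in records}
    for t in schedule:
        row = {
            "onset": t.onset_s,
            "duration": t.duration_s(design),
            "trial_index": t.trial_index,
            "block": t.block,
            "condition": t.condition,
            "distractor_present": t.distractor_present,
            "cue_shape": t.cue_shape,
            "target_quadrant": t.target_quadrant,
            "distractor_quadrant": t.distractor_quadrant,
            "probe_type": t.probe_type,
            "probe_quadrant": t.probe_quadrant,
            "delay": t.delay_s,
            "contrast_rgb": np.nan,
        }
        r = by_index.get(t.trial_index)
        if r is not None:
            row["contrast_rgb"] = r.contrast_rgb
            row["response"] = r.response
            row["rt_ms"] = r.rt_ms
            row["pas"] = r.pas
        rows.append(row)
    return pd.DataFrame(rows)


def write_events(table: pd.DataFrame, path) -> None:
    """Write a tab-separated events table (missing values as 'n/a')."""
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"events table is missing column {missing[0]!r}")
    ordered = MANDATORY_COLUMNS + [c for c in table.columns if c not in MANDATORY_COLUMNS]
    out = table[ordered].copy()
    for col in out.columns:
        if col in ("distractor_present",):
            out[col] = out[col].map(lambda v: str(bool(v)) if pd.notna(v) else _NA)
    out.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.4f")


def load_events(path) -> pd.DataFrame:
    """Load an events table, validating schema and numeric fields.

    Raises :class:`SchemaError` naming the first missing mandatory column,
    or :class:`EventsParseError` citing the 1-based file line of the first
    malformed numeric value.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"events file is missing column {missing[0]!r}")
    table = raw.copy()
    for col in table.columns:
        series = table[col].replace(_NA, np.nan)
        if col in _NUMERIC:
            converted = pd.to_numeric(series, errors="coerce")
            bad = converted.isna() & series.notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise EventsParseError(
                    f"column {col!r}: could not parse {series.iloc[i]!r} "
                    f"at line {i + 2}"  # +1 header, +1 one-based
                )
            table[col] = converted
        elif col == "distractor_present":
            table[col] = series.map(
                lambda v: v if pd.isna(v) else v in ("True", "true", "1")
            )
        else:
            table[col] = series
    return table


def table_to_records(table: pd.DataFrame) -> list[BehavioralRecord]:
    """Behavioral records from an events table carrying response columns."""
    for col in BEHAVIOR_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"events table is missing column {col!r}")
    records = []
    for _, row in table.iterrows():
        records.append(
            BehavioralRecord(
                trial_index=int(row["trial_index"]),
                condition=row["condition"],
                distractor_present=bool(row["distractor_present"]),
                probe_type=row["probe_type"],
                response=row["response"] if pd.notna(row["response"]) else "none",
                rt_ms=float(row["rt_ms"]) if pd.notna(row["rt_ms"]) else float("nan"),
                pas=int(row["pas"]) if pd.notna(row["pas"]) else 1,
                contrast_rgb=(
                    float(row["contrast_rgb"]) if pd.notna(row["contrast_rgb"]) else float("nan")
                ),
            )
        )
    return records
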