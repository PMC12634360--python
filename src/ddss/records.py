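"""Record I/O, imputation, duration normalization, and difficulty labeling.

Operative difficulty is a three-class label derived from raw operative time:
Class 1 under 600 s, Class 2 from 600 s to 1200 s inclusive, Class 3 above 1200 s
(both boundary points deliberately fall in the middle class).  The Lasso response,
by contrast, is the per-surgeon z-score of operative time, which removes each
surgeon's personal speed baseline before preference sequences are fitted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exceptions import RecordParseError, ValidationError
from .schema import Dataset, FeatureSchema, SurgicalRecord, default_schema

__all__ = [
    "read_records",
    "write_records",
    "impute_missing",
    "normalize_durations",
    "label_class",
    "label_dataset",
]

#: Raw-seconds boundaries between difficulty classes.
CLASS_BOUNDS_S = (600.0, 1200.0)

_META_COLUMNS = ("surgeon_id", "month_index", "duration_s")


def label_class(duration_s: float) -> int:
    """Map an operative duration in seconds onto difficulty class 1, 2 or 3."""
    if not duration_s > 0:
        raise ValidationError(f"duration_s must be > 0, got {duration_s}")
    lo, hi = CLASS_BOUNDS_S
    if duration_s < lo:
        return 1
    if duration_s <= hi:
        return 2
    return 3


def label_dataset(ds: Dataset) -> np.ndarray:
    """Difficulty class per record, in record order."""
    return np.array([label_class(r.duration_s) for r in ds.records], dtype=int)


def read_records(path, schema: FeatureSchema | None = None) -> Dataset:
    """Read a records CSV into a :class:`Dataset`.

    Expected columns: the 14 schema abbreviations (level names as text), plus
    ``surgeon_id``, ``month_index``, ``duration_s``; an optional ``record_id``
    column is honoured, otherwise ids ``r000001, ...`` are assigned by row order.
    Empty level cells are flagged missing.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [
        c for c in (*_META_COLUMNS, *schema.abbreviations) if c not in df.columns
    ]
    if missing_cols:
        raise RecordParseError(f"records CSV lacks columns: {missing_cols}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        rid = row.get("record_id") or f"r{i + 1:06d}"
        try:
            duration = float(row["duration_s"])
            month = int(row["month_index"])
        except ValueError as exc:
            raise RecordParseError(f"row {i + 1}: {exc}") from exc
        if duration <= 0:
            raise ValidationError(
                f"row {i + 1} (record {rid!r}): non-positive duration {duration}"
            )
        codes, mask = [], []
        for ind in schema.indicators:
            cell = row[ind.abbreviation].strip()
            if cell == "":
                codes.append(0)
                mask.append(True)
            elif cell not in ind.levels:
                raise RecordParseError(
                    f"row {i + 1}: unknown level {cell!r} for indicator "
                    f"{ind.abbreviation!r}"
                )
            else:
                codes.append(ind.code_of(cell))
                mask.append(False)
        records.append(
            SurgicalRecord(
                record_id=rid,
                surgeon_id=row["surgeon_id"],
                month_index=month,
                levels=tuple(codes),
                duration_s=duration,
                missing_mask=tuple(mask),
            )
        )
    return Dataset(schema, tuple(records))


def write_records(ds: Dataset, path) -> None:
    """Write a Dataset to CSV; inverse of :func:`read_records` (lossless round trip)."""
    rows = []
    for rec in ds.records:
        row = {
            "record_id": rec.record_id,
            "surgeon_id": rec.surgeon_id,
            "month_index": rec.month_index,
            "duration_s": rec.duration_s,
        }
        for ind, code, miss in zip(ds.schema.indicators, rec.levels, rec.missing_mask):
            row[ind.abbreviation] = "" if miss else ind.levels[code]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def impute_missing(ds: Dataset, global_fallback: bool = False) -> Dataset:
    """Fill missing ordinal codes with the within-surgeon mean code, rounded half-up.

    The imputation group is the operating surgeon.  When a surgeon has no observed
    value at all for an indicator, a :class:`ValidationError` is raised unless
    ``global_fallback`` is set, in which case the dataset-wide mean code is used.
    Non-missing values are never altered.
    """
    codes = ds.codes  # NaN at missing positions
    if not np.isnan(codes).any():
        return ds
    surgeons = np.asarray(ds.surgeon_of_record)
    fill = {}  # (surgeon, j) -> int code
    for sid in ds.surgeon_ids:
        sel = surgeons == sid
        block = codes[sel]
        for j in range(block.shape[1]):
            col = block[:, j]
            if not np.isnan(col).any():
                continue
            valid = col[~np.isnan(col)]
            if valid.size:
                fill[(sid, j)] = _round_half_up(float(valid.mean()))
            elif global_fallback:
                global_valid = codes[:, j][~np.isnan(codes[:, j])]
                if not global_valid.size:
                    raise ValidationError(
                        f"indicator {ds.schema.abbreviations[j]!r} is missing in "
                        "every record; cannot impute"
                    )
                fill[(sid, j)] = _round_half_up(float(global_valid.mean()))
            else:
                raise ValidationError(
                    f"surgeon {sid!r} has no observed value for indicator "
                    f"{ds.schema.abbreviations[j]!r}; rerun with "
                    "global_fallback=True to fall back to the global mean"
                )

    new_records = []
    for rec in ds.records:
        if not any(rec.missing_mask):
            new_records.append(rec)
            continue
        levels = list(rec.levels)
        for j, miss in enumerate(rec.missing_mask):
            if miss:
                levels[j] = fill[(rec.surgeon_id, j)]
        new_records.append(
            SurgicalRecord(
                record_id=rec.record_id,
                surgeon_id=rec.surgeon_id,
                month_index=rec.month_index,
                levels=tuple(levels),
                duration_s=rec.duration_s,
                missing_mask=(False,) * len(levels),
            )
        )
    return ds.with_records(new_records)


def normalize_durations(ds: Dataset) -> dict[str, float]:
    """Per-surgeon z-scores of operative time (population SD), keyed by record id.

    Every surgeon in the dataset must contribute at least two records with
    non-identical durations; within each surgeon the returned values have mean 0
    and population standard deviation 1.
    """
    out: dict[str, float] = {}
    for sid, sub in ds.by_surgeon().items():
        d = sub.durations
        if d.size < 2:
            raise ValidationError(
                f"surgeon {sid!r} has {d.size} record(s); need >=2 to normalize"
            )
        sd = float(d.std())  # population SD (ddof=0)
        if sd == 0:
            raise ValidationError(
                f"surgeon {sid!r} has constant durations; z-score undefined"
            )
        mean = float(d.mean())
        for rid, z in zip(sub.record_ids, (d - mean) / sd):
            out[rid] = float(z)
    return out
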