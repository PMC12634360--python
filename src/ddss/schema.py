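"""Data model for third-molar extraction records.

A :class:`FeatureSchema` lists the 14 primary difficulty indicators of an impacted
mandibular third-molar (M3M) extraction, each with an ordered set of categorical
secondary levels (e.g. the Winter angulation classes for ``Angle``, the Pell & Gregory
depth classes for ``Depth``).  Observed levels are stored as 0-based ordinal codes in
schema order, so that one Lasso coefficient corresponds to one indicator — the
one-trajectory-per-feature structure the preference-sequence method relies on.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .exceptions import SchemaError, ValidationError

N_INDICATORS = 14

__all__ = [
    "Indicator",
    "FeatureSchema",
    "SurgicalRecord",
    "Dataset",
    "default_schema",
    "load_schema",
]


@dataclass(frozen=True)
class Indicator:
    """One primary indicator: a name, a short column abbreviation, ordered levels.

    ``proportions`` optionally carries the baseline cohort frequency of each level
    (used as default marginals by the synthetic generator); rounded rows need not
    sum exactly to 1.
    """

    name: str
    abbreviation: str
    levels: tuple[str, ...]
    proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise SchemaError(f"indicator {self.abbreviation!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"indicator {self.abbreviation!r} has duplicate levels")
        if self.proportions is not None and len(self.proportions) != len(self.levels):
            raise SchemaError(
                f"indicator {self.abbreviation!r}: proportions/levels length mismatch"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def code_of(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise SchemaError(
                f"unknown level {level!r} for indicator {self.abbreviation!r}"
            ) from None


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of exactly 14 indicators."""

    indicators: tuple[Indicator, ...]

    def __post_init__(self) -> None:
        if len(self.indicators) != N_INDICATORS:
            raise SchemaError(
                f"schema must have exactly {N_INDICATORS} indicators, "
                f"got {len(self.indicators)}"
            )
        abbrevs = [ind.abbreviation for ind in self.indicators]
        if len(set(abbrevs)) != N_INDICATORS:
            raise SchemaError("indicator abbreviations must be unique")

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(ind.abbreviation for ind in self.indicators)

    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(ind.n_levels for ind in self.indicators)

    def __getitem__(self, key: int | str) -> Indicator:
        if isinstance(key, int):
            return self.indicators[key]
        for ind in self.indicators:
            if ind.abbreviation == key:
                return ind
        raise KeyError(key)

    def index_of(self, abbreviation: str) -> int:
        for j, ind in enumerate(self.indicators):
            if ind.abbreviation == abbreviation:
                return j
        raise KeyError(abbreviation)


@dataclass(frozen=True)
class SurgicalRecord:
    """One extraction: encoded indicator levels, operative duration, provenance.

    ``month_index`` counts months since the operating surgeon joined the department
    (1-based).  ``levels`` holds the 0-based ordinal code per indicator in schema
    order; codes at positions flagged in ``missing_mask`` are ignored.
    """

    record_id: str
    surgeon_id: str
    month_index: int
    levels: tuple[int, ...]
    duration_s: float
    missing_mask: tuple[bool, ...] = field(default=(False,) * N_INDICATORS)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(
                f"record {self.record_id!r}: duration_s must be > 0, "
                f"got {self.duration_s}"
            )
        if self.month_index < 1:
            raise ValidationError(
                f"record {self.record_id!r}: month_index must be >= 1"
            )
        if len(self.levels) != N_INDICATORS or len(self.missing_mask) != N_INDICATORS:
            raise ValidationError(
                f"record {self.record_id!r}: expected {N_INDICATORS} level codes"
            )
        if any(self.missing_mask):
            # canonicalize: codes under the missing mask are meaningless; pin them
            # to 0 so that equality and CSV round trips are exact
            object.__setattr__(
                self,
                "levels",
                tuple(
                    0 if miss else code
                    for code, miss in zip(self.levels, self.missing_mask)
                ),
            )


@dataclass(frozen=True)
class Dataset:
    """A feature schema plus a list of surgical records."""

    schema: FeatureSchema
    records: tuple[SurgicalRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("record_ids must be unique")
        for rec in self.records:
            for j, (code, miss) in enumerate(zip(rec.levels, rec.missing_mask)):
                if not miss and not 0 <= code < self.schema.indicators[j].n_levels:
                    raise ValidationError(
                        f"record {rec.record_id!r}: level code {code} out of range "
                        f"for indicator {self.schema.abbreviations[j]!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def codes(self) -> np.ndarray:
        """(n, 14) float array of ordinal codes, NaN where missing."""
        arr = np.array([r.levels for r in self.records], dtype=float)
        if len(self.records):
            mask = np.array([r.missing_mask for r in self.records], dtype=bool)
            arr[mask] = np.nan
        return arr

    @property
    def durations(self) -> np.ndarray:
        return np.array([r.duration_s for r in self.records], dtype=float)

    @property
    def record_ids(self) -> tuple[str, ...]:
        return tuple(r.record_id for r in self.records)

    @property
    def surgeon_of_record(self) -> tuple[str, ...]:
        return tuple(r.surgeon_id for r in self.records)

    @property
    def surgeon_ids(self) -> tuple[str, ...]:
        """Distinct surgeon ids, sorted."""
        return tuple(sorted({r.surgeon_id for r in self.records}))

    @property
    def month_indices(self) -> np.ndarray:
        return np.array([r.month_index for r in self.records], dtype=int)

    def subset(self, keep) -> "Dataset":
        """New Dataset restricted to records selected by a predicate or boolean mask."""
        if callable(keep):
            recs = tuple(r for r in self.records if keep(r))
        else:
            keep = np.asarray(keep, dtype=bool)
            recs = tuple(r for r, k in zip(self.records, keep) if k)
        return Dataset(self.schema, recs)

    def by_surgeon(self) -> dict[str, "Dataset"]:
        return {
            sid: self.subset(lambda r, s=sid: r.surgeon_id == s)
            for sid in self.surgeon_ids
        }

    def with_records(self, records) -> "Dataset":
        return replace(self, records=tuple(records))


def _schema_from_mapping(doc: dict) -> FeatureSchema:
    indicators = []
    for entry in doc["indicators"]:
        levels = tuple(str(lv["name"]) for lv in entry["levels"])
        props = tuple(float(lv["proportion"]) for lv in entry["levels"]) if all(
            "proportion" in lv for lv in entry["levels"]
        ) else None
        indicators.append(
            Indicator(
                name=str(entry["name"]),
                abbreviation=str(entry["abbreviation"]),
                levels=levels,
                proportions=props,
            )
        )
    return FeatureSchema(tuple(indicators))


def load_schema(path) -> FeatureSchema:
    """Load a feature schema from a YAML/JSON document."""
    with open(path, "r", encoding="utf-8") as fh:
        return _schema_from_mapping(yaml.safe_load(fh))


def default_schema() -> FeatureSchema:
    """The packaged 14-indicator M3M schema with baseline level proportions."""
    ref = importlib.resources.files("ddss.data").joinpath("default_schema.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return _schema_from_mapping(yaml.safe_load(fh))
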