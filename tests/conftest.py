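import numpy as np
import pytest

from ddss.schema import Dataset, SurgicalRecord, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def make_dataset(
    schema,
    durations,
    surgeons=None,
    months=None,
    codes=None,
    missing=None,
):
    """Build a small Dataset by hand; codes default to all-zero levels."""
    n = len(durations)
    surgeons = surgeons or ["S1"] * n
    months = months or [1] * n
    records = []
    for i in range(n):
        row = tuple(codes[i]) if codes is not None else (0,) * 14
        mask = tuple(missing[i]) if missing is not None else (False,) * 14
        records.append(
            SurgicalRecord(
                record_id=f"r{i + 1}",
                surgeon_id=surgeons[i],
                month_index=months[i],
                levels=row,
                duration_s=float(durations[i]),
                missing_mask=mask,
            )
        )
    return Dataset(schema, tuple(records))


def random_codes(schema, n, rng):
    """Uniformly random valid level codes, one row per record."""
    return np.column_stack(
        [rng.integers(0, ind.n_levels, size=n) for ind in schema.indicators]
    )
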