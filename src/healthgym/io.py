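"""CSV reading and writing for cohort datasets.

Files are plain RFC-4180 CSV with a header row: one column per clinical
variable plus the patient-ID and timestep columns, one row per
(patient, timestep).  Binary cells are written as ``True``/``False`` labels;
``0``/``1`` are accepted on read.  Numerics are written at a fixed decimal
precision (default 2, matching the published tables), so a write/read
round-trip is the identity on datasets holding values at that precision.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .schema import NUMERIC, CohortSchema, LongitudinalDataset, SchemaError


def read_csv(
    path,
    schema: CohortSchema,
    extra_columns: str = "error",
) -> LongitudinalDataset:
    """Read and validate a Health Gym-format CSV against a schema.

    Parameters
    ----------
    path : path-like
    schema : CohortSchema
    extra_columns : {"error", "ignore"}
        Whether columns beyond the schema's are rejected or dropped.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extras = [c for c in frame.columns if c not in schema.columns]
    if extras:
        if extra_columns == "error":
            raise SchemaError(f"{path}: unexpected columns {extras}")
        frame = frame.drop(columns=extras)
    return LongitudinalDataset(schema, frame)


def write_csv(
    dataset: LongitudinalDataset,
    path,
    decimals: Optional[int] = 2,
) -> None:
    """Write a dataset to CSV.

    ``decimals`` fixes the printed precision of numeric cells (None writes
    full ``repr`` precision).  An empty dataset produces a header-only file.
    """
    frame = dataset.frame.copy()
    for v in dataset.schema.variables:
        if v.kind == NUMERIC and decimals is not None:
            frame[v.name] = frame[v.name].map(lambda x: f"{x:.{decimals}f}")
    frame.to_csv(path, index=False)
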