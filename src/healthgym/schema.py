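"""Cohort schemas and the longitudinal dataset container.

A cohort is a rectangular panel: ``n_patients`` patients, each observed for a
fixed number of timesteps, with a mixed set of clinical variables per record
(numeric, binary, categorical).  Three schemas are bundled — intensive-care
acute hypotension (hourly, 48 steps), sepsis (4-hour windows, 20 steps) and
HIV antiretroviral therapy (monthly, 60 steps) — matching the published
Health Gym dataset layouts, including the binary "(M)" measurement-indicator
convention for informatively missing laboratory values.

Each bundled variable also carries the published descriptive statistics
(quartiles for numerics, class shares for categoricals); the cohort simulator
uses these to emulate realistic marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (NUMERIC, BINARY, CATEGORICAL)

BOOL_CLASSES = ("False", "True")


class SchemaError(ValueError):
    """Raised when a schema or dataset violates its declared structure."""


@dataclass(frozen=True)
class VariableSpec:
    """Declarative description of one clinical variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"numeric", "binary", "categorical"}
    unit : str
        Physical unit; may be empty (e.g. for ratios and flags).
    classes : tuple of str
        Ordered class labels.  Required (>= 2, unique) for categorical,
        exactly 2 for binary, empty for numeric.  The order is meaningful:
        ordinal statistics (KS on class codes, three-sigma) use it.
    measured_indicator_of : str, optional
        For binary "(M)" flags: the companion variable this flag annotates.
    is_quasi_identifier : bool
        Whether this variable participates in disclosure-risk equivalence
        classes (e.g. Age, Gender, Ethnicity).
    quartiles : tuple, optional
        Published (Q1, median, Q3) for numeric variables; used by the
        simulator to parameterise realistic right-skewed marginals.
    class_shares : tuple, optional
        Published class shares in percent, aligned with ``classes``.
    class_bounds : tuple, optional
        Interval bounds metadata for decile-coded variables, as
        ``((lo, hi), ...)`` aligned with ``classes``.
    """

    name: str
    kind: str
    unit: str = ""
    classes: tuple = ()
    measured_indicator_of: Optional[str] = None
    is_quasi_identifier: bool = False
    quartiles: Optional[tuple] = None
    class_shares: Optional[tuple] = None
    class_bounds: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == NUMERIC and self.classes:
            raise SchemaError(f"{self.name}: numeric variables take no classes")
        if self.kind == BINARY and len(self.classes) != 2:
            raise SchemaError(f"{self.name}: binary variables need exactly 2 classes")
        if self.kind == CATEGORICAL:
            if len(self.classes) < 2:
                raise SchemaError(f"{self.name}: categorical needs >= 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise SchemaError(f"{self.name}: duplicate class labels")
        if self.measured_indicator_of is not None and self.kind != BINARY:
            raise SchemaError(f"{self.name}: measurement indicators must be binary")
        if self.class_shares is not None and len(self.class_shares) != len(self.classes):
            raise SchemaError(f"{self.name}: class_shares misaligned with classes")

    @property
    def n_channels(self) -> int:
        """Channels this variable occupies in the encoded representation."""
        return 1 if self.kind == NUMERIC else len(self.classes)

    def code_of(self, label) -> int:
        """Ordered integer class code of a label (categorical/binary only)."""
        return self.classes.index(str(label))


@dataclass(frozen=True)
class CohortSchema:
    """An ordered collection of variables plus panel geometry."""

    name: str
    variables: tuple
    id_column: str
    time_column: str
    timesteps_per_patient: int
    time_unit: str = ""

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names")
        if self.id_column in names or self.time_column in names:
            raise SchemaError("id/time columns must not be clinical variables")
        if self.timesteps_per_patient <= 0:
            raise SchemaError("timesteps_per_patient must be positive")
        for v in self.variables:
            if v.measured_indicator_of is not None and v.measured_indicator_of not in names:
                raise SchemaError(
                    f"{v.name}: indicator target {v.measured_indicator_of!r} not in schema"
                )

    # -- lookups --------------------------------------------------------
    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def variable_names(self) -> list:
        return [v.name for v in self.variables]

    @property
    def columns(self) -> list:
        """Full CSV column order: clinical variables, then ID, then time."""
        return self.variable_names + [self.id_column, self.time_column]

    def by_kind(self, kind: str) -> list:
        return [v for v in self.variables if v.kind == kind]

    @property
    def quasi_identifiers(self) -> list:
        return [v.name for v in self.variables if v.is_quasi_identifier]

    @property
    def n_channels(self) -> int:
        return sum(v.n_channels for v in self.variables)


class LongitudinalDataset:
    """A validated patient x timestep x variable panel.

    Wraps a :class:`pandas.DataFrame` with one row per (patient, timestep),
    sorted patient-major.  Construction validates every container invariant:
    exactly ``timesteps_per_patient`` consecutive 0-based timesteps per
    patient, categorical cells inside their declared vocabulary, and finite
    numeric cells.
    """

    def __init__(self, schema: CohortSchema, frame: pd.DataFrame):
        self.schema = schema
        missing = [c for c in schema.columns if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        frame = frame.loc[:, schema.columns].copy()

        # normalise cell types: numerics to float, class-valued to str labels
        for v in schema.variables:
            col = frame[v.name]
            if v.kind == NUMERIC:
                vals = pd.to_numeric(col, errors="coerce").astype(float)
                bad = ~np.isfinite(vals.to_numpy())
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise SchemaError(
                        f"non-finite value in numeric column {v.name!r} at row {i}"
                    )
                frame[v.name] = vals
            else:
                labels = col.map(_normalise_label(v))
                bad = ~labels.isin(v.classes)
                if bad.any():
                    i = int(np.flatnonzero(bad.to_numpy())[0])
                    raise SchemaError(
                        f"value {col.iloc[i]!r} of column {v.name!r} at row {i} "
                        f"not in declared classes {list(v.classes)}"
                    )
                frame[v.name] = labels

        t = pd.to_numeric(frame[schema.time_column], errors="coerce")
        if t.isna().any():
            raise SchemaError("non-integer timestep values")
        t = t.astype(int)
        offset = int(t.min()) if len(t) else 0
        if offset not in (0, 1):
            raise SchemaError("timesteps must start at 0 (or 1)")
        frame[schema.time_column] = t - offset

        frame = frame.sort_values(
            [schema.id_column, schema.time_column], kind="stable"
        ).reset_index(drop=True)

        T = schema.timesteps_per_patient
        counts = frame.groupby(schema.id_column, sort=False).size()
        ragged = counts[counts != T]
        if len(ragged):
            pid = ragged.index[0]
            raise SchemaError(
                f"patient {pid!r} has {int(ragged.iloc[0])} rows, expected {T}"
            )
        if len(frame):
            steps = frame[schema.time_column].to_numpy().reshape(-1, T)
            if not (steps == np.arange(T)).all():
                pid = frame[schema.id_column].iloc[
                    int(np.argmax((steps != np.arange(T)).any(axis=1))) * T
                ]
                raise SchemaError(f"patient {pid!r}: timesteps not consecutive from 0")

        self.frame = frame
        self.n_patients = int(len(frame) // T) if len(frame) else 0
        assert len(frame) == self.n_patients * T

    # -- convenience ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> list:
        ids = self.frame[self.schema.id_column]
        T = self.schema.timesteps_per_patient
        return list(ids.iloc[::T]) if len(ids) else []

    def column(self, name: str) -> np.ndarray:
        """All values of a variable, pooled across patients and timesteps."""
        return self.frame[name].to_numpy()

    def coded_column(self, name: str) -> np.ndarray:
        """Variable as floats: numerics verbatim, classes as ordered codes."""
        v = self.schema[name]
        if v.kind == NUMERIC:
            return self.column(name).astype(float)
        lut = {c: i for i, c in enumerate(v.classes)}
        return np.array([lut[x] for x in self.column(name)], dtype=float)

    def panel(self, name: str) -> np.ndarray:
        """Variable reshaped to (n_patients, timesteps), coded as floats."""
        return self.coded_column(name).reshape(
            self.n_patients, self.schema.timesteps_per_patient
        )

    def first_row_per_patient(self) -> pd.DataFrame:
        T = self.schema.timesteps_per_patient
        return self.frame.iloc[::T] if len(self.frame) else self.frame

    def equals(self, other: "LongitudinalDataset") -> bool:
        return self.schema.name == other.schema.name and self.frame.equals(other.frame)


def _normalise_label(v: VariableSpec):
    """Cell -> declared label mapper; tolerant of 0/1 for False/True flags."""

    def convert(x):
        s = str(x)
        if s in v.classes:
            return s
        if v.classes == BOOL_CLASSES:
            if s in ("0", "0.0", "false", "FALSE"):
                return "False"
            if s in ("1", "1.0", "true", "TRUE"):
                return "True"
        # numeric-looking labels such as "15" arriving as "15.0"
        try:
            f = float(s)
            if f == int(f) and str(int(f)) in v.classes:
                return str(int(f))
        except ValueError:
            pass
        return s

    return convert


def descriptive_stats(dataset: LongitudinalDataset) -> dict:
    """Per-variable summaries in the style of the published data tables.

    Numeric variables: Q1 / median / Q3 and mean.  Categorical and binary
    variables: class shares in percent (summing to 100).
    """
    if len(dataset) == 0:
        raise SchemaError("descriptive_stats needs a non-empty dataset")
    out = {}
    for v in dataset.schema.variables:
        vals = dataset.column(v.name)
        if v.kind == NUMERIC:
            vals = vals.astype(float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[v.name] = {
                "kind": v.kind,
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "mean": float(vals.mean()),
            }
        else:
            n = len(vals)
            shares = {c: 100.0 * float((vals == c).sum()) / n for c in v.classes}
            out[v.name] = {"kind": v.kind, "shares": shares}
    return out


# ---------------------------------------------------------------------------
# Bundled schemas
# ---------------------------------------------------------------------------

def _m(name, target, share_true, qi=False):
    """A binary measurement-indicator variable with published True-share %."""
    return VariableSpec(
        name, BINARY, "", BOOL_CLASSES,
        measured_indicator_of=target, is_quasi_identifier=qi,
        class_shares=(100.0 - share_true, share_true),
    )


def _hypotension_schema() -> CohortSchema:
    variables = (
        VariableSpec("MAP", NUMERIC, "mmHg", quartiles=(59.30, 65.34, 71.19)),
        VariableSpec("Diastolic BP", NUMERIC, "mmHg", quartiles=(48.37, 54.33, 60.26)),
        VariableSpec("Systolic BP", NUMERIC, "mmHg", quartiles=(104.23, 113.21, 121.60)),
        VariableSpec("Urine", NUMERIC, "mL", quartiles=(68.92, 106.21, 164.23)),
        VariableSpec("ALT", NUMERIC, "IU/L", quartiles=(24.59, 32.55, 46.09)),
        VariableSpec("AST", NUMERIC, "IU/L", quartiles=(35.81, 46.82, 67.75)),
        VariableSpec("PaO2", NUMERIC, "mmHg", quartiles=(91.34, 103.02, 114.66)),
        VariableSpec("Lactic Acid", NUMERIC, "mmol/L", quartiles=(1.29, 1.50, 1.80)),
        VariableSpec("Serum Creatinine", NUMERIC, "mg/dL", quartiles=(0.83, 1.11, 1.62)),
        VariableSpec(
            "Fluid Boluses", CATEGORICAL, "mL",
            ("[0,250)", "[250,500)", "[500,1000)", ">=1000"),
            class_shares=(97.32, 0.28, 1.46, 0.94),
        ),
        VariableSpec(
            "Vasopressors", CATEGORICAL, "mcg/kg/min",
            ("0", "(0,8.4)", "[8.4,20.28)", ">=20.28"),
            class_shares=(84.14, 8.34, 3.68, 3.83),
        ),
        VariableSpec(
            "FiO2", CATEGORICAL, "fraction",
            ("<=0.2", "0.2", "0.3", "0.4", "0.5", "0.6", "0.7", "0.8", "0.9", "1.0"),
            class_shares=(0.0, 0.54, 2.84, 10.85, 63.30, 8.58, 1.32, 0.20, 2.63, 9.75),
        ),
        VariableSpec(
            "GCS", CATEGORICAL, "point",
            tuple(str(k) for k in range(3, 16)),
            class_shares=(6.61, 2.16, 0.0, 3.00, 4.77, 0.0, 2.22,
                          4.32, 2.46, 3.56, 1.00, 9.80, 60.09),
        ),
        _m("Urine (M)", "Urine", 36.93),
        _m("ALT/AST (M)", "ALT", 1.50),  # single flag covers ALT and AST
        _m("FiO2 (M)", "FiO2", 7.51),
        _m("GCS (M)", "GCS", 18.51),
        _m("PaO2 (M)", "PaO2", 2.44),
        _m("Lactic Acid (M)", "Lactic Acid", 3.02),
        _m("Serum Creatinine (M)", "Serum Creatinine", 4.74),
    )
    return CohortSchema(
        "hypotension", variables, "Patient ID", "Hour", 48, time_unit="hour"
    )


_SEPSIS_NUMERICS = (
    # name, unit, (Q1, median, Q3)
    ("Age", "year", (58.29, 65.40, 72.95)),
    ("HR", "bpm", (78.46, 89.09, 99.82)),
    ("Systolic BP", "mmHg", (114.43, 123.67, 133.03)),
    ("Mean BP", "mmHg", (75.18, 81.02, 86.91)),
    ("Diastolic BP", "mmHg", (50.40, 58.90, 66.95)),
    ("RR", "bpm", (18.69, 21.46, 24.28)),
    ("K", "meq/L", (3.78, 4.12, 4.45)),
    ("Na", "meq/L", (136.59, 140.01, 143.57)),
    ("Cl", "meq/L", (102.08, 105.23, 108.03)),
    ("Ca", "mg/dL", (7.37, 8.02, 8.66)),
    ("Ionised Ca", "mg/dL", (1.04, 1.11, 1.18)),
    ("CO2", "meq/L", (23.44, 25.27, 27.29)),
    ("Albumin", "g/dL", (2.68, 3.01, 3.32)),
    ("Hb", "g/dL", (9.17, 10.20, 11.23)),
    ("pH", "", (7.34, 7.39, 7.44)),
    ("BE", "meq/L", (-2.04, 0.16, 2.48)),
    ("HCO3", "meq/L", (22.63, 24.38, 26.13)),
    ("FiO2", "fraction", (0.38, 0.45, 0.55)),
    ("Glucose", "mg/dL", (108.21, 134.11, 167.06)),
    ("BUN", "mg/dL", (19.89, 25.38, 31.92)),
    ("Creatinine", "mg/dL", (0.90, 1.13, 1.44)),
    ("Mg", "mg/dL", (1.83, 2.04, 2.29)),
    ("SGOT", "u/L", (31.53, 50.78, 88.97)),
    ("SGPT", "u/L", (26.20, 39.99, 65.66)),
    ("Total Bili", "mg/dL", (0.66, 1.19, 2.32)),
    ("WBC", "E9/L", (7.99, 10.60, 13.92)),
    ("Platelets", "E9/L", (141.97, 184.44, 239.41)),
    ("PaO2", "mmHg", (84.22, 109.07, 139.63)),
    ("PaCO2", "mmHg", (34.92, 39.32, 44.97)),
    ("Lactate", "mmol/L", (1.41, 1.82, 2.40)),
    ("Input Total", "mL", (1887.84, 4867.46, 11155.76)),
    ("Input 4H", "mL", (13.83, 58.66, 229.01)),
    ("Max Vaso", "mcg/kg/min", (0.0, 0.0002, 0.0017)),
    ("Output Total", "mL", (585.47, 2505.54, 6733.69)),
    ("Output 4H", "mL", (44.74, 159.33, 361.69)),
)

_DECILES = tuple(f"C{k}" for k in range(1, 11))


def _sepsis_schema() -> CohortSchema:
    numerics = tuple(
        VariableSpec(n, NUMERIC, u, quartiles=q, is_quasi_identifier=(n == "Age"))
        for n, u, q in _SEPSIS_NUMERICS
    )
    non_numerics = (
        VariableSpec("Gender", BINARY, "", ("Male", "Female"),
                     is_quasi_identifier=True, class_shares=(73.41, 26.59)),
        VariableSpec("Readmission", BINARY, "", BOOL_CLASSES,
                     class_shares=(60.20, 39.80)),
        VariableSpec("Mech", BINARY, "", BOOL_CLASSES, class_shares=(56.89, 43.11)),
        VariableSpec(
            "GCS", CATEGORICAL, "point", tuple(str(k) for k in range(3, 16)),
            class_shares=(8.71, 0.38, 0.50, 6.30, 0.74, 2.27, 1.52,
                          9.31, 9.12, 6.31, 2.53, 15.45, 36.85),
        ),
        VariableSpec(
            "SpO2", CATEGORICAL, "%", _DECILES,
            class_shares=(13.38, 8.12, 4.48, 10.64, 12.61, 11.36,
                          11.52, 11.84, 8.39, 7.66),
            class_bounds=((0.00, 93.83), (93.83, 95.14), (95.14, 96.00),
                          (96.00, 96.70), (96.70, 97.33), (97.33, 98.00),
                          (98.00, 98.60), (98.60, 99.22), (99.22, 99.86),
                          (99.86, 100.0)),
        ),
        VariableSpec(
            "Temp", CATEGORICAL, "Celsius", _DECILES,
            class_shares=(7.83, 6.55, 12.87, 16.56, 4.21, 8.21,
                          7.10, 9.37, 10.96, 16.33),
            class_bounds=((15.11, 35.95), (35.95, 36.28), (36.28, 36.50),
                          (36.50, 36.69), (36.69, 36.88), (36.88, 37.06),
                          (37.06, 37.28), (37.28, 37.56), (37.56, 37.93),
                          (37.93, 40.52)),
        ),
        VariableSpec(
            "PTT", CATEGORICAL, "s", _DECILES,
            class_shares=(7.69, 6.71, 10.02, 12.44, 5.46, 9.27,
                          9.99, 11.47, 12.38, 14.58),
            class_bounds=((17.80, 24.53), (24.53, 26.63), (26.63, 28.20),
                          (28.20, 29.60), (29.60, 31.45), (31.45, 34.00),
                          (34.00, 37.10), (37.10, 42.80), (42.80, 57.90),
                          (57.90, 150.00)),
        ),
        VariableSpec(
            "PT", CATEGORICAL, "s", _DECILES,
            class_shares=(7.89, 8.2, 11.02, 9.84, 9.45, 6.59,
                          10.37, 10.51, 13.27, 12.85),
            class_bounds=((9.90, 12.20), (12.20, 12.90), (12.90, 13.30),
                          (13.30, 13.80), (13.80, 14.30), (14.30, 14.90),
                          (14.90, 15.90), (15.90, 17.51), (17.51, 22.00),
                          (22.00, 146.70)),
        ),
        VariableSpec(
            "INR", CATEGORICAL, "", _DECILES,
            class_shares=(0.19, 8.88, 23.35, 0.09, 15.64, 10.22,
                          7.53, 9.71, 10.67, 13.70),
        ),
    )
    return CohortSchema(
        "sepsis", numerics + non_numerics, "Patient ID", "Timestep", 20,
        time_unit="4-hour window",
    )


def _hiv_schema() -> CohortSchema:
    variables = (
        VariableSpec("VL", NUMERIC, "copies/mL", quartiles=(16.51, 54.77, 209.03)),
        VariableSpec("CD4", NUMERIC, "cells/uL", quartiles=(279.26, 465.81, 840.34)),
        VariableSpec("Rel CD4", NUMERIC, "cells/uL", quartiles=(18.20, 25.57, 35.72)),
        VariableSpec("Gender", BINARY, "", ("Male", "Female"),
                     is_quasi_identifier=True, class_shares=(93.42, 6.58)),
        VariableSpec(
            "Ethnicity", CATEGORICAL, "",
            ("Asian", "African", "Caucasian", "Other"),
            is_quasi_identifier=True, class_shares=(0.47, 2.55, 26.81, 70.17),
        ),
        VariableSpec(
            "Base Drug Combo", CATEGORICAL, "",
            ("FTC + TDF", "3TC + ABC", "FTC + TAF", "DRV + FTC + TDF",
             "FTC + RTVB + TDF", "Other"),
            class_shares=(73.66, 14.08, 0.98, 5.50, 2.30, 3.47),
        ),
        VariableSpec(
            "Comp. INI", CATEGORICAL, "", ("DTG", "RAL", "EVG", "Not Applied"),
            class_shares=(11.96, 0.49, 4.69, 82.86),
        ),
        VariableSpec(
            "Comp. NNRTI", CATEGORICAL, "", ("NVP", "EFV", "RPV", "Not Applied"),
            class_shares=(0.19, 9.27, 43.76, 46.78),
        ),
        VariableSpec(
            "Extra PI", CATEGORICAL, "",
            ("DRV", "RTVB", "LPV", "RTV", "ATV", "Not Applied"),
            class_shares=(0.69, 4.02, 1.08, 2.02, 4.26, 87.92),
        ),
        VariableSpec("Extra pk-En", BINARY, "", BOOL_CLASSES, class_shares=(96.70, 3.30)),
        _m("VL (M)", "VL", 20.65),
        _m("CD4 (M)", "CD4", 16.61),
        _m("Drug (M)", "Base Drug Combo", 84.44),
    )
    return CohortSchema("hiv", variables, "Patient ID", "Month", 60, time_unit="month")


_BUNDLED = {
    "hypotension": _hypotension_schema,
    "sepsis": _sepsis_schema,
    "hiv": _hiv_schema,
}


def bundled_schema(name: str) -> CohortSchema:
    """Return one of the bundled cohort schemas: hypotension, sepsis or hiv."""
    try:
        factory = _BUNDLED[name]
    except KeyError:
        raise SchemaError(
            f"unknown schema {name!r}; available: {sorted(_BUNDLED)}"
        ) from None
    return factory()
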