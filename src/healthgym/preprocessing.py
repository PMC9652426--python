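"""Mixed-type encoding for the generative model, and its inverse.

Numeric variables are optionally ``log1p``-transformed (chosen automatically
when the sample skewness exceeds a threshold, reflecting the heavy right
skew of clinical labs) and min-max scaled to [0, 1].  Categorical and binary
variables become blocks of class-probability channels: one-hot when encoding
real data, soft probability vectors when produced by the generator.  The
full channel layout is recorded in a :class:`ChannelMap` shared by the
encoder, the networks and the decoder.

Also provided: empirical decile binning, the route by which extremely
skewed numerics (e.g. coagulation times) are turned into ordinal
ten-class categoricals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .schema import (
    BINARY,
    CATEGORICAL,
    NUMERIC,
    CohortSchema,
    LongitudinalDataset,
    SchemaError,
    VariableSpec,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Channel:
    name: str
    kind: str
    start: int
    stop: int  # exclusive


class ChannelMap:
    """Ordered assignment of encoded-array channels to schema variables."""

    def __init__(self, schema: CohortSchema):
        self.schema = schema
        self.channels: List[Channel] = []
        pos = 0
        for v in schema.variables:
            width = v.n_channels
            self.channels.append(Channel(v.name, v.kind, pos, pos + width))
            pos += width
        self.n_channels = pos

    def __getitem__(self, name: str) -> Channel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(name)

    @property
    def categorical_blocks(self) -> List[Channel]:
        return [c for c in self.channels if c.kind != NUMERIC]

    @property
    def numeric_channels(self) -> List[Channel]:
        return [c for c in self.channels if c.kind == NUMERIC]

    def channel_labels(self) -> List[str]:
        labels = []
        for ch, v in zip(self.channels, self.schema.variables):
            if ch.kind == NUMERIC:
                labels.append(ch.name)
            else:
                labels.extend(f"{ch.name}={c}" for c in v.classes)
        return labels


@dataclass
class EncodedBatch:
    """Batch x timestep x channel view of a dataset (or generator output)."""

    values: np.ndarray
    channel_map: ChannelMap
    batch_ids: list

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != self.channel_map.n_channels:
            raise SchemaError(
                f"encoded array shape {self.values.shape} does not match "
                f"{self.channel_map.n_channels} channels"
            )

    def validate(self, atol: float = 1e-6) -> None:
        """Assert the encoded-representation invariants."""
        if self.values.size == 0:
            return
        for ch in self.channel_map.numeric_channels:
            block = self.values[:, :, ch.start]
            if block.min() < -atol or block.max() > 1 + atol:
                raise SchemaError(f"{ch.name}: numeric channel outside [0, 1]")
        for ch in self.channel_map.categorical_blocks:
            block = self.values[:, :, ch.start: ch.stop]
            if block.min() < -atol:
                raise SchemaError(f"{ch.name}: negative class probability")
            if np.abs(block.sum(axis=2) - 1.0).max() > atol:
                raise SchemaError(f"{ch.name}: class probabilities do not sum to 1")

    def pooled(self) -> np.ndarray:
        """Flatten batch and time: (batch*T, channels)."""
        return self.values.reshape(-1, self.values.shape[2])


@dataclass
class TransformSpec:
    """Fitted numeric transforms: per variable, transform name and bounds."""

    transforms: dict  # name -> {"transform": "identity"|"log1p", "min": .., "max": ..}
    skew_threshold: float = 2.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"skew_threshold": self.skew_threshold, "transforms": self.transforms},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "TransformSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(transforms=doc["transforms"], skew_threshold=doc["skew_threshold"])


def _forward(name: str, x: np.ndarray, how: str) -> np.ndarray:
    if how == "identity":
        return x
    if how == "log1p":
        return np.log1p(x)
    raise SchemaError(f"{name}: unknown transform {how!r}")


def _inverse(name: str, y: np.ndarray, how: str) -> np.ndarray:
    if how == "identity":
        return y
    if how == "log1p":
        return np.expm1(y)
    raise SchemaError(f"{name}: unknown transform {how!r}")


def fit_transforms(
    real: LongitudinalDataset, skew_threshold: float = 2.0
) -> TransformSpec:
    """Choose per-numeric-variable transforms and record scaling bounds.

    ``log1p`` is selected when the sample skewness exceeds ``skew_threshold``
    (and the variable's support permits it); otherwise identity.  Constant
    variables are rejected — they cannot be min-max scaled.
    """
    transforms = {}
    for v in real.schema.by_kind(NUMERIC):
        x = real.column(v.name).astype(float)
        if np.ptp(x) == 0:
            raise SchemaError(f"{v.name}: constant numeric variable (degenerate)")
        how = "identity"
        if stats.skew(x) > skew_threshold and x.min() > -1.0:
            how = "log1p"
        y = _forward(v.name, x, how)
        transforms[v.name] = {
            "transform": how,
            "min": float(y.min()),
            "max": float(y.max()),
        }
    return TransformSpec(transforms=transforms, skew_threshold=skew_threshold)


def encode(dataset: LongitudinalDataset, spec: TransformSpec) -> EncodedBatch:
    """Dataset -> (n_patients, T, channels) array in the GAN's representation."""
    schema = dataset.schema
    cmap = ChannelMap(schema)
    n, T = dataset.n_patients, schema.timesteps_per_patient
    out = np.zeros((n, T, cmap.n_channels))
    n_clipped = 0
    for v in schema.variables:
        ch = cmap[v.name]
        if v.kind == NUMERIC:
            tr = spec.transforms[v.name]
            y = _forward(v.name, dataset.column(v.name).astype(float), tr["transform"])
            lo, hi = tr["min"], tr["max"]
            scaled = (y - lo) / (hi - lo)
            clipped = np.clip(scaled, 0.0, 1.0)
            n_clipped += int((clipped != scaled).sum())
            out[:, :, ch.start] = clipped.reshape(n, T)
        else:
            codes = dataset.coded_column(v.name).astype(int).reshape(n, T)
            block = np.zeros((n, T, len(v.classes)))
            np.put_along_axis(block, codes[:, :, None], 1.0, axis=2)
            out[:, :, ch.start: ch.stop] = block
    if n_clipped:
        log.info("encode: clipped %d numeric cells to the fitted bounds", n_clipped)
    batch = EncodedBatch(out, cmap, dataset.patient_ids)
    batch.validate()
    return batch


def decode(
    batch: EncodedBatch,
    spec: TransformSpec,
    schema: CohortSchema,
    patient_ids: Optional[list] = None,
    round_decimals: int = 4,
) -> LongitudinalDataset:
    """Invert :func:`encode`; categorical blocks resolve by argmax.

    Argmax ties break to the lowest class index.  All-zero (or uniform)
    numeric channels map back through the fitted bounds.
    """
    cmap = batch.channel_map
    if cmap.n_channels != ChannelMap(schema).n_channels or [
        c.name for c in cmap.channels
    ] != schema.variable_names:
        raise SchemaError("channel map inconsistent with schema")
    n, T, _ = batch.values.shape
    if patient_ids is None:
        patient_ids = batch.batch_ids or [f"p_{i:05d}" for i in range(n)]
    columns = {}
    for v in schema.variables:
        ch = cmap[v.name]
        if v.kind == NUMERIC:
            tr = spec.transforms[v.name]
            y = batch.values[:, :, ch.start] * (tr["max"] - tr["min"]) + tr["min"]
            x = _inverse(v.name, y, tr["transform"])
            columns[v.name] = np.round(x, round_decimals).reshape(-1)
        else:
            block = batch.values[:, :, ch.start: ch.stop]
            codes = block.argmax(axis=2)  # ties -> lowest index
            columns[v.name] = np.array(v.classes)[codes].reshape(-1)
    frame = pd.DataFrame(columns)
    frame[schema.id_column] = np.repeat(list(patient_ids), T)
    frame[schema.time_column] = np.tile(np.arange(T), n)
    return LongitudinalDataset(schema, frame)


def bin_to_deciles(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical decile coding of a numeric column.

    Returns (labels, cuts): ten classes ``C1``..``C10`` delimited by the
    10th..90th percentiles, with half-open ``[lo, hi)`` intervals — a value
    equal to a cut joins the class whose interval starts there — and the
    last interval closed.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise SchemaError("decile binning needs at least 10 values")
    cuts = np.percentile(values, np.arange(10, 100, 10))
    codes = np.searchsorted(cuts, values, side="right")
    labels = np.array([f"C{k}" for k in range(1, 11)])[codes]
    return labels, cuts
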