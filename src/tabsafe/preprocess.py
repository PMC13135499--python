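"""Bidirectional preprocessing of mixed-type cohort tables.

The full pipeline (variant ``level3``) turns a cohort with arbitrary
missingness into a dense numeric matrix a generative model can train on,
and back:

* date columns are encoded as signed day counts from a fixed reference
  date;
* each continuous/date column is median-imputed, then mapped through a
  monotone empirical-quantile transform onto [0, 1] (optionally onto a
  standard-normal scale), with the imputation done *before* the quantile
  grid is fitted so imputed cells land exactly on the median's grid
  point;
* a binary missingness indicator accompanies each continuous/date column
  whose missing rate reaches ``indicator_threshold`` (default 0, i.e.
  always), so informative missingness is visible to the model;
* binary/categorical columns are one-hot encoded with an explicit
  placeholder level capturing originally missing cells.

The simpler ``level12`` variant imputes continuous/date columns with the
constant −1 and one-hot encodes categoricals, with no quantile transform
and no indicator columns; it suits tables with little missingness.

Every step is invertible: :func:`inverse_transform` restores column
names, order, calendar dates, category labels and missing cells.  The
quantile map is strictly monotone and bijective on its fitted grid, so
observed values round-trip exactly; values between grid points invert to
within one grid interpolation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Any, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .schema import StudyConfig

PLACEHOLDER = "Unknown"

__all__ = [
    "FittedTransform",
    "EncodedMatrix",
    "encode_dates",
    "decode_dates",
    "fit_quantile_grid",
    "quantile_transform",
    "inverse_quantile_transform",
    "fit_transform",
    "fit_transform_level12",
    "inverse_transform",
]


@dataclass
class NumericColumnState:
    """Invertible state of one continuous or date column."""

    median: float
    grid_values: np.ndarray
    grid_levels: np.ndarray
    has_flag: bool
    missing_rate: float
    lossy: bool = False  # level12 only: -1 collided with an observed value


@dataclass
class CategoricalColumnState:
    levels: list[str]  # declared categories + placeholder, in encoding order


@dataclass
class FittedTransform:
    """Per-column invertible transform state for one fitted cohort."""

    variant: str  # "level3" | "level12"
    reference_date: date
    indicator_threshold: float
    output_distribution: str  # "uniform" | "normal"
    numeric: dict[str, NumericColumnState] = field(default_factory=dict)
    categorical: dict[str, CategoricalColumnState] = field(default_factory=dict)
    identifier_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant": self.variant,
            "reference_date": self.reference_date.isoformat(),
            "indicator_threshold": self.indicator_threshold,
            "output_distribution": self.output_distribution,
            "identifier_columns": list(self.identifier_columns),
            "numeric": {
                name: {
                    "median": st.median,
                    "grid_values": st.grid_values.tolist(),
                    "grid_levels": st.grid_levels.tolist(),
                    "has_flag": st.has_flag,
                    "missing_rate": st.missing_rate,
                    "lossy": st.lossy,
                }
                for name, st in self.numeric.items()
            },
            "categorical": {
                name: {"levels": st.levels} for name, st in self.categorical.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "FittedTransform":
        tf = cls(
            variant=doc["variant"],
            reference_date=date.fromisoformat(doc["reference_date"]),
            indicator_threshold=doc["indicator_threshold"],
            output_distribution=doc["output_distribution"],
            identifier_columns=list(doc.get("identifier_columns", [])),
        )
        for name, st in doc["numeric"].items():
            tf.numeric[name] = NumericColumnState(
                median=st["median"],
                grid_values=np.asarray(st["grid_values"], float),
                grid_levels=np.asarray(st["grid_levels"], float),
                has_flag=st["has_flag"],
                missing_rate=st["missing_rate"],
                lossy=st.get("lossy", False),
            )
        for name, st in doc["categorical"].items():
            tf.categorical[name] = CategoricalColumnState(levels=list(st["levels"]))
        return tf


@dataclass
class EncodedMatrix:
    """Numeric model-ready matrix with per-column provenance.

    ``provenance`` maps each encoded column to ``(source column, kind)``
    with kind one of ``quantile_value``, ``missing_flag``, ``onehot_level``
    or ``passthrough``.
    """

    data: pd.DataFrame
    provenance: dict[str, tuple[str, str]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(float)


# ---------------------------------------------------------------------------
# dates


def encode_dates(column: pd.Series, reference_date: date) -> pd.Series:
    """Encode dates as signed day counts since the reference date (NaT → NaN)."""
    ref = pd.Timestamp(reference_date)
    col = pd.to_datetime(column)
    return (col - ref).dt.days.astype(float)


def decode_dates(days: pd.Series, reference_date: date) -> pd.Series:
    """Inverse of :func:`encode_dates`; fractional day counts round to nearest."""
    ref = pd.Timestamp(reference_date)
    out = ref + pd.to_timedelta(np.round(days.to_numpy(float)), unit="D")
    return pd.Series(out, index=days.index)


# ---------------------------------------------------------------------------
# empirical quantile machinery


def fit_quantile_grid(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit the empirical quantile grid of a fully observed sample.

    The i-th of the n sorted observations receives level (i − 0.5)/n;
    tied observations collapse to a single grid point at the mean of
    their levels.  Both returned arrays are strictly increasing, so the
    piecewise-linear map value ↔ level is bijective on the grid.
    """
    x = np.sort(np.asarray(values, float))
    if x.size == 0:
        raise ValueError("cannot fit a quantile grid on an empty sample")
    n = x.size
    levels = (np.arange(1, n + 1) - 0.5) / n
    grid_values, inverse = np.unique(x, return_inverse=True)
    grid_levels = np.bincount(inverse, weights=levels) / np.bincount(inverse)
    return grid_values, grid_levels


def quantile_transform(
    values: np.ndarray,
    grid_values: np.ndarray,
    grid_levels: np.ndarray,
    output_distribution: str = "uniform",
) -> np.ndarray:
    """Monotone map through the fitted empirical CDF; clamps outside the grid."""
    if len(grid_values) == 0:
        raise ValueError("empty quantile grid")
    q = np.interp(np.asarray(values, float), grid_values, grid_levels)
    if output_distribution == "normal":
        return stats.norm.ppf(q)
    return q


def inverse_quantile_transform(
    q: np.ndarray,
    grid_values: np.ndarray,
    grid_levels: np.ndarray,
    output_distribution: str = "uniform",
) -> np.ndarray:
    q = np.asarray(q, float)
    if output_distribution == "normal":
        q = stats.norm.cdf(q)
    return np.interp(q, grid_levels, grid_values)


# ---------------------------------------------------------------------------
# fitting


def _numeric_view(cohort: pd.DataFrame, name: str, role: str, ref: date) -> pd.Series:
    if role == "date":
        return encode_dates(cohort[name], ref)
    return cohort[name].astype(float)


def fit_transform(
    cohort: pd.DataFrame,
    config: StudyConfig,
    indicator_threshold: float = 0.0,
    output_distribution: str = "uniform",
) -> tuple[EncodedMatrix, FittedTransform]:
    """Fit the full (level-3) pipeline on a cohort and encode it."""
    return _fit(cohort, config, "level3", indicator_threshold, output_distribution)


def fit_transform_level12(
    cohort: pd.DataFrame, config: StudyConfig
) -> tuple[EncodedMatrix, FittedTransform]:
    """Fit the constant-imputation (level-1/2) variant: missing → −1, one-hot."""
    return _fit(cohort, config, "level12", 0.0, "uniform")


def _fit(
    cohort: pd.DataFrame,
    config: StudyConfig,
    variant: str,
    indicator_threshold: float,
    output_distribution: str,
) -> tuple[EncodedMatrix, FittedTransform]:
    if output_distribution not in ("uniform", "normal"):
        raise ValueError(f"unknown output distribution {output_distribution!r}")
    tf = FittedTransform(
        variant=variant,
        reference_date=config.reference_date,
        indicator_threshold=indicator_threshold,
        output_distribution=output_distribution,
    )
    encoded: dict[str, np.ndarray] = {}
    provenance: dict[str, tuple[str, str]] = {}

    for spec in config.columns:
        name = spec.name
        if spec.role == "identifier":
            tf.identifier_columns.append(name)
            continue
        if spec.role in ("continuous", "date"):
            x = _numeric_view(cohort, name, spec.role, config.reference_date)
            missing = x.isna().to_numpy()
            if missing.all():
                raise ValueError(f"column {name!r} has no observed values")
            rate = float(missing.mean())
            if variant == "level3":
                med = float(np.nanmedian(x.to_numpy(float)))
                imputed = x.fillna(med).to_numpy(float)
                gv, gl = fit_quantile_grid(imputed)
                st = NumericColumnState(
                    median=med,
                    grid_values=gv,
                    grid_levels=gl,
                    has_flag=rate >= indicator_threshold,
                    missing_rate=rate,
                )
                encoded[f"{name}_q"] = quantile_transform(
                    imputed, gv, gl, output_distribution
                )
                provenance[f"{name}_q"] = (name, "quantile_value")
                if st.has_flag:
                    encoded[f"{name}_q_m"] = missing.astype(float)
                    provenance[f"{name}_q_m"] = (name, "missing_flag")
            else:  # level12: constant −1, passthrough scale
                observed = x.to_numpy(float)[~missing]
                st = NumericColumnState(
                    median=-1.0,
                    grid_values=np.unique(observed),
                    grid_levels=np.array([]),
                    has_flag=False,
                    missing_rate=rate,
                    lossy=bool(np.any(observed == -1.0) and missing.any()),
                )
                encoded[name] = x.fillna(-1.0).to_numpy(float)
                provenance[name] = (name, "passthrough")
            tf.numeric[name] = st
        elif spec.role in ("binary", "categorical"):
            levels = list(spec.categories) + [PLACEHOLDER]
            tf.categorical[name] = CategoricalColumnState(levels=levels)
            col = cohort[name].astype(object).where(~cohort[name].isna(), PLACEHOLDER)
            for level in levels:
                enc_name = f"{name}={level}"
                encoded[enc_name] = (col == level).to_numpy(float)
                provenance[enc_name] = (name, "onehot_level")
        else:
            raise ValueError(f"unsupported role {spec.role!r}")

    data = pd.DataFrame(encoded, index=cohort.index)
    return EncodedMatrix(data=data, provenance=provenance), tf


# ---------------------------------------------------------------------------
# inversion


def inverse_transform(
    encoded: EncodedMatrix, transform: FittedTransform, config: StudyConfig
) -> pd.DataFrame:
    """Map an encoded matrix (real or generated) back to a typed cohort.

    Missingness flags ≥ 0.5 restore missing cells; a one-hot argmax at the
    placeholder level restores a missing categorical cell; day counts
    become calendar dates.  Identifier columns are regenerated as fresh
    sequential labels rather than reconstructed.
    """
    df = encoded.data
    for col in df.columns:
        if col not in encoded.provenance:
            raise ValueError(f"encoded column {col!r} missing from provenance map")
    out = pd.DataFrame(index=df.index)
    for spec in config.columns:
        name = spec.name
        if spec.role == "identifier":
            if name not in transform.identifier_columns:
                raise ValueError(f"identifier {name!r} unknown to this transform")
            out[name] = [f"S{i:06d}" for i in range(len(df))]
        elif spec.role in ("continuous", "date"):
            st = transform.numeric.get(name)
            if st is None:
                raise ValueError(f"column {name!r} unknown to this transform")
            if transform.variant == "level3":
                vals = inverse_quantile_transform(
                    df[f"{name}_q"].to_numpy(float),
                    st.grid_values,
                    st.grid_levels,
                    transform.output_distribution,
                )
                vals = pd.Series(vals, index=df.index)
                if st.has_flag:
                    miss = df[f"{name}_q_m"].to_numpy(float) >= 0.5
                    vals = vals.mask(miss)
            else:
                vals = pd.Series(df[name].to_numpy(float), index=df.index)
                if not st.lossy:
                    vals = vals.mask(vals == -1.0)
            if spec.role == "date":
                out[name] = decode_dates(vals, transform.reference_date)
            else:
                out[name] = vals.astype(float)
        else:
            st_cat = transform.categorical.get(name)
            if st_cat is None:
                raise ValueError(f"column {name!r} unknown to this transform")
            cols = [f"{name}={lev}" for lev in st_cat.levels]
            missing_cols = [c for c in cols if c not in df.columns]
            if missing_cols:
                raise ValueError(f"encoded levels {missing_cols} absent from matrix")
            block = df[cols].to_numpy(float)
            winners = np.argmax(block, axis=1)
            labels = pd.Series(
                [st_cat.levels[w] for w in winners], index=df.index, dtype=object
            )
            out[name] = labels.mask(labels == PLACEHOLDER)
    return out
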