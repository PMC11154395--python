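"""Stable-isotope tracer correction and rate-unit conversions.

Enriched ⁶⁵Cu is used as a tracer so that newly accumulated copper can be
separated from the animal's natural copper background.  A raw ICP-MS reading
gives the total ⁶⁵Cu and the ⁶³Cu signal of a sample; because natural copper
carries both isotopes at fixed abundances (F65 = 0.3085, F63 = 0.6915), the
⁶³Cu signal measures the natural background and can be used to correct the
⁶⁵Cu total.

Two corrections are provided:

``as_printed``
    ``(cu65_total - cu63) * F65`` — the correction as commonly printed in
    tracer studies of this design.
``abundance_ratio``
    ``cu65_total - cu63 * (F65 / F63)`` — the standard natural-abundance
    subtraction: the background ⁶⁵Cu implied by the ⁶³Cu signal is removed.

Both are exposed because the two differ and field usage is not uniform;
``as_printed`` is the default.  All internal rates are kept in h⁻¹; Cu
elimination rates are conventionally reported in d⁻¹, hence the converters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "Matrix",
    "TracerMode",
    "IsotopeReading",
    "IsotopeConstants",
    "TracerResult",
    "tracer_correct",
    "ke_per_day_to_per_hour",
    "ke_per_hour_to_per_day",
    "read_isotope_csv",
]

F65_NATURAL = 0.3085
F63_NATURAL = 0.6915


class Matrix(str, enum.Enum):
    """Sample matrix: water (µg L⁻¹) or soft tissue (µg g⁻¹ dry weight)."""

    WATER = "water"
    TISSUE = "tissue"


class TracerMode(str, enum.Enum):
    AS_PRINTED = "as_printed"
    ABUNDANCE_RATIO = "abundance_ratio"


@dataclass(frozen=True)
class IsotopeConstants:
    """Natural isotopic abundances of copper (dimensionless fractions)."""

    f65: float = F65_NATURAL
    f63: float = F63_NATURAL

    def __post_init__(self) -> None:
        if not (0.0 < self.f65 < 1.0 and 0.0 < self.f63 < 1.0):
            raise ValueError("isotope abundances must lie strictly in (0, 1)")
        if abs(self.f65 + self.f63 - 1.0) > 1e-6:
            raise ValueError(
                f"abundances must sum to 1 (got {self.f65 + self.f63:.8f})"
            )


@dataclass(frozen=True)
class IsotopeReading:
    """One raw isotope measurement.

    ``cu65_total`` and ``cu63`` share units: µg L⁻¹ for water samples,
    µg g⁻¹ dry weight for tissue samples.
    """

    cu65_total: float
    cu63: float
    matrix: Matrix = Matrix.TISSUE

    def __post_init__(self) -> None:
        if self.cu65_total < 0 or self.cu63 < 0:
            raise ValueError("isotope concentrations must be nonnegative")


@dataclass(frozen=True)
class TracerResult:
    """Newly accumulated ⁶⁵Cu, same units as the input reading.

    ``clipped`` flags readings whose corrected value was negative (noise can
    drive the background subtraction below zero) and was clipped to 0; the
    flag lets downstream fits exclude such points rather than losing them.
    """

    value: float
    clipped: bool = False


def tracer_correct(
    reading: IsotopeReading,
    constants: IsotopeConstants = IsotopeConstants(),
    mode: Union[TracerMode, str] = TracerMode.AS_PRINTED,
) -> TracerResult:
    """Convert a raw isotope reading into newly accumulated ⁶⁵Cu.

    Parameters
    ----------
    reading
        Raw total-⁶⁵Cu and ⁶³Cu concentrations (same units).
    constants
        Natural abundances; defaults F65 = 0.3085, F63 = 0.6915.
    mode
        ``as_printed`` (default) or ``abundance_ratio``; see module docstring.

    Returns
    -------
    TracerResult
        Corrected concentration, clipped at 0 with ``clipped=True`` if the
        raw difference was negative.
    """
    mode = TracerMode(mode)
    if mode is TracerMode.AS_PRINTED:
        value = (reading.cu65_total - reading.cu63) * constants.f65
    else:
        if constants.f63 == 0:
            raise ValueError("abundance_ratio mode requires F63 > 0")
        value = reading.cu65_total - reading.cu63 * (constants.f65 / constants.f63)
    if value < 0:
        return TracerResult(0.0, clipped=True)
    return TracerResult(value, clipped=False)


def ke_per_day_to_per_hour(ke_d: float) -> float:
    """Convert a first-order elimination rate from d⁻¹ to h⁻¹."""
    if ke_d < 0:
        raise ValueError("rate constants must be nonnegative")
    return ke_d / 24.0


def ke_per_hour_to_per_day(ke_h: float) -> float:
    """Convert a first-order elimination rate from h⁻¹ to d⁻¹."""
    if ke_h < 0:
        raise ValueError("rate constants must be nonnegative")
    return ke_h * 24.0


_ISOTOPE_COLUMNS = {"sample_id", "time_h", "matrix", "replicate", "cu65_ug", "cu63_ug"}


def read_isotope_csv(
    path: Union[str, Path],
    constants: IsotopeConstants = IsotopeConstants(),
    mode: Union[TracerMode, str] = TracerMode.AS_PRINTED,
) -> pd.DataFrame:
    """Read a raw isotope table and append the tracer-corrected column.

    Expected columns: ``sample_id, time_h, matrix, replicate, cu65_ug,
    cu63_ug`` and, for tissue rows, ``dry_weight_g``.  Concentrations are
    per-litre for water rows and per-gram dry weight for tissue rows.

    Returns the table with ``cu65_new`` (corrected concentration) and
    ``clipped`` (bool) columns appended.
    """
    df = pd.read_csv(path)
    missing = _ISOTOPE_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"isotope CSV missing columns: {sorted(missing)}")
    bad = df[(df["cu65_ug"] < 0) | (df["cu63_ug"] < 0)]
    if not bad.empty:
        raise ValueError(
            f"negative isotope concentrations at rows {bad.index.tolist()}"
        )
    results = [
        tracer_correct(
            IsotopeReading(row.cu65_ug, row.cu63_ug, Matrix(row.matrix)),
            constants,
            mode,
        )
        for row in df.itertuples()
    ]
    df = df.copy()
    df["cu65_new"] = [r.value for r in results]
    df["clipped"] = [r.clipped for r in results]
    return df
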