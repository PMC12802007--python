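"""Binned population exposure distributions for annual-mean PM2.5.

A distribution is an ordered, contiguous set of half-open concentration
bins ``[lower, upper)`` each carrying the fraction of the population
exposed within that bin.  The representative concentration of a bin is
its midpoint, so a ``[4.5, 5.5)`` bin represents 5.0 µg/m³.  Bin widths
are nominally 1 µg/m³ but arbitrary widths are accepted; nothing
downstream assumes width 1.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ExposureBin",
    "ExposureDistribution",
    "VARIANTS",
    "load_exposure",
    "load_exposure_variants",
    "population_weighted_concentration",
    "shift_distribution",
    "collapse_to_pwc",
    "write_exposure_csv",
]

logger = logging.getLogger(__name__)

#: Recognised distribution variant labels.
VARIANTS = ("central", "lo95", "hi95")

#: Tolerated deviation of the fraction sum from 1 before a warning is logged.
_NORMALISE_WARN_TOL = 1e-6
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class ExposureBin:
    """One half-open concentration interval ``[lower, upper)`` in µg/m³."""

    lower: float
    upper: float
    fraction: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper) and np.isfinite(self.fraction)):
            raise ValidationError(f"non-finite bin values: {self}")
        if self.lower < 0:
            raise ValidationError(f"negative concentration: lower={self.lower}")
        if not self.lower < self.upper:
            raise ValidationError(f"bin must satisfy lower < upper, got [{self.lower}, {self.upper})")
        if self.fraction < 0:
            raise ValidationError(f"negative population fraction {self.fraction} in bin [{self.lower}, {self.upper})")

    @property
    def midpoint(self) -> float:
        """Representative concentration of the bin (µg/m³)."""
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class ExposureDistribution:
    """Contiguous ascending bins whose fractions sum to 1.

    Parameters
    ----------
    bins
        Ordered bins, contiguous and non-overlapping.
    variant
        One of ``{"central", "lo95", "hi95"}``; CI variants are whole
        separate distributions, not per-bin intervals.
    population_total
        Raw population count behind the fractions, kept when the input
        carried absolute counts so attributable numbers can be reported
        as counts.
    """

    bins: tuple[ExposureBin, ...]
    variant: str = "central"
    population_total: float | None = None

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError("exposure distribution needs at least one bin")
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}, expected one of {VARIANTS}")
        for prev, cur in zip(self.bins, self.bins[1:]):
            if abs(prev.upper - cur.lower) > _EDGE_TOL:
                kind = "gap" if cur.lower > prev.upper else "overlap"
                raise FormatError(
                    f"{kind} between bins [{prev.lower}, {prev.upper}) and [{cur.lower}, {cur.upper})"
                )
        total = float(sum(b.fraction for b in self.bins))
        if total <= 0:
            raise ValidationError("population fractions are all zero")
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"fractions sum to {total}, not 1; use load_exposure() or normalize() first"
            )

    # -- array views -------------------------------------------------

    @property
    def lowers(self) -> np.ndarray:
        return np.array([b.lower for b in self.bins])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([b.upper for b in self.bins])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([b.fraction for b in self.bins])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins])

    def pwc(self) -> float:
        """Population-weighted mean concentration, Σ C_i · EF_i."""
        return population_weighted_concentration(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower_ugm3": self.lowers,
                "upper_ugm3": self.uppers,
                "fraction": self.fractions,
                "variant": self.variant,
            }
        )


def _build(
    lowers: Sequence[float],
    uppers: Sequence[float],
    fractions: Sequence[float],
    variant: str,
    population_total: float | None,
) -> ExposureDistribution:
    order = np.argsort(np.asarray(lowers, dtype=float), kind="stable")
    lowers = np.asarray(lowers, dtype=float)[order]
    uppers = np.asarray(uppers, dtype=float)[order]
    fractions = np.asarray(fractions, dtype=float)[order]
    if np.any(fractions < 0):
        bad = int(np.argmax(fractions < 0))
        raise ValidationError(
            f"negative fraction {fractions[bad]} in bin [{lowers[bad]}, {uppers[bad]})"
        )
    total = float(fractions.sum())
    if total <= 0:
        raise ValidationError("population fractions are all zero")
    if abs(total - 1.0) > _NORMALISE_WARN_TOL:
        logger.warning(
            "exposure fractions sum to %.9g; renormalizing to 1 (variant=%s)", total, variant
        )
    bins = tuple(
        ExposureBin(float(lo), float(up), float(fr / total))
        for lo, up, fr in zip(lowers, uppers, fractions)
    )
    return ExposureDistribution(bins=bins, variant=variant, population_total=population_total)


def load_exposure(
    table: pd.DataFrame | str | os.PathLike,
    variant: str = "central",
) -> ExposureDistribution:
    """Load one exposure distribution from a CSV file or data frame.

    Expected columns: ``lower_ugm3, upper_ugm3, fraction`` (or
    ``population`` for absolute counts), optional ``variant``.  Rows are
    sorted by lower edge, validated for contiguity, and fractions are
    renormalized to sum to 1 (a warning is logged when the deviation
    exceeds 1e-6).
    """
    df = _read_table(table)
    if "variant" in df.columns:
        df = df[df["variant"].astype(str) == variant]
        if df.empty:
            raise FormatError(f"no rows for variant {variant!r}")
    lowers, uppers, values, pop_total = _extract_columns(df)
    return _build(lowers, uppers, values, variant, pop_total)


def load_exposure_variants(
    table: pd.DataFrame | str | os.PathLike,
) -> dict[str, ExposureDistribution]:
    """Load every variant present in the table, keyed by variant label."""
    df = _read_table(table)
    if "variant" not in df.columns:
        return {"central": load_exposure(df)}
    out: dict[str, ExposureDistribution] = {}
    for label in df["variant"].astype(str).unique():
        if label not in VARIANTS:
            raise FormatError(f"unknown variant label {label!r}, expected one of {VARIANTS}")
        out[label] = load_exposure(df, variant=label)
    return out


def _read_table(table: pd.DataFrame | str | os.PathLike) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table)
    if df.empty:
        raise FormatError("exposure table has no rows")
    return df


def _extract_columns(df: pd.DataFrame):
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        lowers = pd.to_numeric(df[cols["lower_ugm3"]], errors="raise").to_numpy(float)
        uppers = pd.to_numeric(df[cols["upper_ugm3"]], errors="raise").to_numpy(float)
    except KeyError as exc:
        raise FormatError(f"missing exposure column: {exc}") from None
    pop_total = None
    if "fraction" in cols:
        values = pd.to_numeric(df[cols["fraction"]], errors="raise").to_numpy(float)
    elif "population" in cols:
        values = pd.to_numeric(df[cols["population"]], errors="raise").to_numpy(float)
        pop_total = float(values.sum())
    else:
        raise FormatError("exposure table needs a 'fraction' or 'population' column")
    return lowers, uppers, values, pop_total


def population_weighted_concentration(dist: ExposureDistribution) -> float:
    """PWC = Σ (bin midpoint) × EF_i, in µg/m³."""
    return float(np.dot(dist.midpoints, dist.fractions))


def shift_distribution(dist: ExposureDistribution, delta: float) -> ExposureDistribution:
    """Translate every bin up by ``delta`` µg/m³, fractions unchanged.

    ``PWC(shifted) == PWC(dist) + delta`` exactly.  Negative deltas are
    rejected: shifting down could push bins below zero concentration.
    """
    if delta < 0:
        raise ValidationError(f"shift delta must be >= 0, got {delta}")
    bins = tuple(
        ExposureBin(b.lower + delta, b.upper + delta, b.fraction) for b in dist.bins
    )
    return ExposureDistribution(
        bins=bins, variant=dist.variant, population_total=dist.population_total
    )


def collapse_to_pwc(dist: ExposureDistribution) -> ExposureDistribution:
    """Degenerate single-bin distribution of width 1 centred on the PWC.

    Feeding the result to the attribution engine reproduces the PWC
    shortcut: the single representative concentration is the PWC itself.
    """
    pwc = population_weighted_concentration(dist)
    if pwc >= 0.5:
        bin_ = ExposureBin(pwc - 0.5, pwc + 0.5, 1.0)
    else:
        # keep the midpoint on the PWC without going below zero
        bin_ = ExposureBin(0.0, 2.0 * pwc, 1.0)
    return ExposureDistribution(
        bins=(bin_,), variant=dist.variant, population_total=dist.population_total
    )


def write_exposure_csv(
    distributions: Iterable[ExposureDistribution], path: str | os.PathLike
) -> None:
    """Write one or more variants to a single CSV with a variant column."""
    frames = [d.to_frame() for d in distributions]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
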