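"""Population attributable fraction and attributable burden.

PAF over a binned exposure distribution:

    PAF = (Σ RR_i · EF_i − 1) / (Σ RR_i · EF_i)

with RR evaluated at each bin's representative (midpoint) concentration.
When the exposure is summarised to its population-weighted mean
concentration (PWC) the sum collapses to the shortcut
``PAF = (RR_PWC − 1)/RR_PWC``.

Attributable burden is ``AB = PAF × BoD`` for any burden measure
(deaths, YLL, YLD, DALY).  A mortality-based PAF is applied to YLL, YLD
and DALY alike.  Counts are kept unrounded internally; rounding to whole
deaths happens only at the reporting layer.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError
from .exposure import ExposureDistribution

__all__ = [
    "MEASURES",
    "CAUSES",
    "HealthOutcomeRecord",
    "HealthOutcomeTable",
    "AttributionResult",
    "SUM_LABEL",
    "paf_distribution",
    "paf_pwc",
    "attributable_burden",
    "attributable_by_cause",
    "daly_decomposition",
    "load_health_table",
]

logger = logging.getLogger(__name__)

MEASURES = ("deaths", "YLL", "YLD", "DALY")

#: Canonical cause labels used by the synthetic generator and configs.
CAUSES = (
    "all-cause",
    "NCD+LRI",
    "IHD",
    "stroke",
    "COPD",
    "ALRI",
    "lung cancer",
    "diabetes-2",
)

SUM_LABEL = "sum"


@dataclass(frozen=True)
class HealthOutcomeRecord:
    """One cause × measure burden count with an optional 95% CI."""

    cause: str
    measure: str
    value: float
    lo: float | None = None
    hi: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}, expected one of {MEASURES}")
        if self.value < 0:
            raise ValidationError(f"negative burden value {self.value} for {self.cause}/{self.measure}")
        if (self.lo is None) != (self.hi is None):
            raise ValidationError(f"{self.cause}/{self.measure}: CI needs both lo and hi")
        if self.lo is not None and not (0 <= self.lo <= self.value <= self.hi):
            raise ValidationError(
                f"{self.cause}/{self.measure}: CI must satisfy 0 <= lo <= value <= hi, "
                f"got ({self.lo}, {self.value}, {self.hi})"
            )

    @property
    def has_interval(self) -> bool:
        return self.lo is not None

    def endpoint(self, which: str) -> float:
        if which == "central":
            return self.value
        if not self.has_interval:
            raise DataError(f"{self.cause}/{self.measure} ({self.source}): no interval available")
        return self.lo if which == "lo" else self.hi  # type: ignore[return-value]


class HealthOutcomeTable:
    """Cause × measure burden table (GBD/WHO/registry style)."""

    #: tolerance for DALY == YLL + YLD on rounded inputs
    DALY_TOL = 0.5

    def __init__(self, records: Iterable[HealthOutcomeRecord], source: str = ""):
        self.records: tuple[HealthOutcomeRecord, ...] = tuple(records)
        self.source = source or (self.records[0].source if self.records else "")
        self._index: dict[tuple[str, str], HealthOutcomeRecord] = {}
        for rec in self.records:
            key = (rec.cause, rec.measure)
            if key in self._index:
                raise ValidationError(f"duplicate record for {key}")
            self._index[key] = rec
        self._check_daly_consistency()

    def _check_daly_consistency(self) -> None:
        for cause in self.causes():
            try:
                yll = self._index[(cause, "YLL")].value
                yld = self._index[(cause, "YLD")].value
                daly = self._index[(cause, "DALY")].value
            except KeyError:
                continue
            if abs(daly - (yll + yld)) > self.DALY_TOL:
                raise ValidationError(
                    f"{cause}: DALY {daly} != YLL {yll} + YLD {yld} (tolerance {self.DALY_TOL})"
                )

    def causes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.cause, None)
        return tuple(seen)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._index

    def get(self, cause: str, measure: str) -> HealthOutcomeRecord:
        try:
            return self._index[(cause, measure)]
        except KeyError:
            raise DataError(
                f"no health record for cause {cause!r}, measure {measure!r} (source {self.source!r})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cause": [r.cause for r in self.records],
                "measure": [r.measure for r in self.records],
                "value": [r.value for r in self.records],
                "lo": [r.lo for r in self.records],
                "hi": [r.hi for r in self.records],
                "source": [r.source for r in self.records],
            }
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def load_health_table(
    table: pd.DataFrame | str | os.PathLike, source: str | None = None
) -> HealthOutcomeTable:
    """Read a health-table CSV (``cause, measure, value, lo, hi, source``).

    Missing CI endpoints are allowed (registry-style data ships without
    uncertainty intervals).
    """
    df = table.copy() if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    required = {"cause", "measure", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"health table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        lo = getattr(row, "lo", None)
        hi = getattr(row, "hi", None)
        lo = None if lo is None or pd.isna(lo) else float(lo)
        hi = None if hi is None or pd.isna(hi) else float(hi)
        records.append(
            HealthOutcomeRecord(
                cause=str(row.cause),
                measure=str(row.measure),
                value=float(row.value),
                lo=lo,
                hi=hi,
                source=source or str(getattr(row, "source", "") or ""),
            )
        )
    return HealthOutcomeTable(records, source=source or "")


@dataclass(frozen=True)
class AttributionResult:
    """PAF and attributable burden for one cause × measure."""

    cause: str
    measure: str
    paf: float
    attributable: float
    interval: tuple[float, float] | None = None
    uncertainty_source: str = "none"

    def __post_init__(self) -> None:
        if self.interval is not None:
            lo, hi = self.interval
            if lo > hi:
                raise ValidationError(f"interval lo {lo} > hi {hi} for {self.cause}/{self.measure}")


def paf_distribution(dist: ExposureDistribution, curve: Callable) -> float:
    """PAF from the full binned distribution.

    ``curve`` maps concentration (µg/m³) to RR and must be evaluable at
    every bin midpoint.
    """
    rr = np.asarray(curve(dist.midpoints), dtype=float)
    if np.any(rr <= 0):
        raise ValidationError("curve produced a non-positive relative risk")
    # Σ(RR_i - 1)·EF_i avoids cancellation so a null curve gives exactly 0
    excess = float(np.dot(rr - 1.0, dist.fractions))
    return excess / (1.0 + excess)


def paf_pwc(rr_pwc: float) -> float:
    """PAF shortcut from a single RR evaluated at the PWC."""
    if rr_pwc <= 0:
        raise ValidationError(f"RR must be > 0, got {rr_pwc}")
    return (rr_pwc - 1.0) / rr_pwc


def attributable_burden(paf: float, record: HealthOutcomeRecord) -> AttributionResult:
    """AB = PAF × BoD for one record; cause and measure carried through."""
    if not 0 <= paf < 1:
        raise ValidationError(f"PAF must lie in [0, 1), got {paf}")
    return AttributionResult(
        cause=record.cause,
        measure=record.measure,
        paf=paf,
        attributable=paf * record.value,
    )


def attributable_by_cause(
    dist: ExposureDistribution,
    curves: Mapping[str, Callable],
    table: HealthOutcomeTable,
    measure: str = "deaths",
    use_pwc: bool = False,
) -> list[AttributionResult]:
    """One result per cause (that cause's curve × that cause's burden),
    plus a final ``sum`` row totalling the attributable values.

    Causes present in the table but absent from the curve set are
    skipped with a logged notice; a cause in the curve set but missing
    from the table is a hard error.
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}")
    skipped = [c for c in table.causes() if c not in curves]
    if skipped:
        logger.info("causes without curves skipped: %s", ", ".join(skipped))
    results = []
    from .exposure import collapse_to_pwc  # local to avoid cycle at import time

    eval_dist = collapse_to_pwc(dist) if use_pwc else dist
    for cause, curve in curves.items():
        record = table.get(cause, measure)  # DataError if missing
        paf = paf_distribution(eval_dist, curve)
        results.append(attributable_burden(paf, record))
    total = sum(r.attributable for r in results)
    mean_paf = float(np.mean([r.paf for r in results])) if results else 0.0
    results.append(
        AttributionResult(cause=SUM_LABEL, measure=measure, paf=mean_paf, attributable=total)
    )
    return results


def daly_decomposition(
    yll: AttributionResult, yld: AttributionResult
) -> tuple[AttributionResult, float | None]:
    """Combine YLL and YLD results into a DALY result with the YLL share.

    Both inputs must refer to the same cause and be computed with the
    same PAF.  The share is ``None`` when YLL + YLD = 0.
    """
    if yll.cause != yld.cause:
        raise DataError(f"cause mismatch: {yll.cause!r} vs {yld.cause!r}")
    if yll.measure != "YLL" or yld.measure != "YLD":
        raise DataError("daly_decomposition expects a YLL result and a YLD result")
    if abs(yll.paf - yld.paf) > 1e-12:
        raise DataError(f"PAF mismatch for {yll.cause}: {yll.paf} vs {yld.paf}")
    total = yll.attributable + yld.attributable
    share = None if total == 0 else yll.attributable / total
    daly = AttributionResult(
        cause=yll.cause, measure="DALY", paf=yll.paf, attributable=total
    )
    return daly, share
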