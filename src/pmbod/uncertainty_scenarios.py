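"""Endpoint-substitution uncertainty and the scenario grid.

Uncertainty is propagated one input category at a time: the pipeline is
re-run with the 2.5% and then the 97.5% variant of exactly one input
(relative risk, exposure distribution, or health table) while everything
else stays at its central value.  No Monte-Carlo combination is
performed.

The scenario grid evaluates a list of methodological configurations and
reports each result as a signed percent change versus a designated
reference configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import (
    SUM_LABEL,
    AttributionResult,
    HealthOutcomeTable,
    attributable_by_cause,
)
from .curves import CurveSpec, make_curve
from .errors import ConfigurationError, DataError, ValidationError
from .exposure import ExposureDistribution, collapse_to_pwc, shift_distribution

__all__ = [
    "UNCERTAINTY_SOURCES",
    "ScenarioConfig",
    "ScenarioResult",
    "EndpointInterval",
    "run_scenario",
    "propagate_endpoint",
    "sum_cause_intervals",
    "percent_change",
    "run_scenario_grid",
    "ledger_frame",
]

UNCERTAINTY_SOURCES = ("rr", "exposure", "health", "none")


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully resolved methodological configuration.

    ``exposure`` maps variant labels (central, lo95, hi95) to whole
    distributions; only ``central`` is required.  ``curves`` maps cause
    labels to curve specs.  ``shift_delta`` moves every exposure variant
    up before evaluation; ``use_pwc`` collapses the distribution to its
    population-weighted mean first.
    """

    id: str
    exposure: Mapping[str, ExposureDistribution]
    curves: Mapping[str, CurveSpec]
    health: HealthOutcomeTable
    measure: str = "deaths"
    use_pwc: bool = False
    shift_delta: float = 0.0
    exposure_label: str = ""
    health_label: str = ""

    def __post_init__(self) -> None:
        if "central" not in self.exposure:
            raise ConfigurationError(f"scenario {self.id!r}: no central exposure distribution")
        if not self.curves:
            raise ConfigurationError(f"scenario {self.id!r}: no curves configured")

    def distribution(self, variant: str = "central") -> ExposureDistribution:
        try:
            dist = self.exposure[variant]
        except KeyError:
            raise DataError(
                f"scenario {self.id!r}: no {variant!r} exposure variant available"
            ) from None
        if self.shift_delta:
            dist = shift_distribution(dist, self.shift_delta)
        return dist

    def describe(self) -> dict:
        """Every resolved methodological choice, for the run log."""
        return {
            "scenario": self.id,
            "exposure_source": self.exposure_label,
            "health_source": self.health_label or self.health.source,
            "measure": self.measure,
            "use_pwc": self.use_pwc,
            "shift_delta": self.shift_delta,
            "curves": [spec.describe() for spec in self.curves.values()],
        }


@dataclass(frozen=True)
class EndpointInterval:
    """Result of one endpoint substitution: (lo, hi) attributable values,
    or an explicit no-interval marker with a reason."""

    source: str
    lo: float | None = None
    hi: float | None = None
    reason: str = ""

    @property
    def available(self) -> bool:
        return self.lo is not None

    def __post_init__(self) -> None:
        if self.source not in UNCERTAINTY_SOURCES:
            raise ValidationError(f"unknown uncertainty source {self.source!r}")
        if (self.lo is None) != (self.hi is None):
            raise ValidationError("interval needs both endpoints")


@dataclass(frozen=True)
class ScenarioResult:
    scenario_id: str
    measure: str
    attributable: float
    interval: EndpointInterval | None = None
    pct_change_vs_reference: float | None = None
    per_cause: tuple[AttributionResult, ...] = ()


def _evaluate(
    config: ScenarioConfig,
    rr_endpoint: str = "central",
    exposure_variant: str = "central",
    health_endpoint: str = "central",
) -> list[AttributionResult]:
    """Run the full pipeline once with the given per-category endpoints."""
    dist = config.distribution(exposure_variant)
    curves = {cause: make_curve(spec, rr_endpoint) for cause, spec in config.curves.items()}
    if health_endpoint == "central":
        table = config.health
    else:
        from .attribution import HealthOutcomeRecord

        table = HealthOutcomeTable(
            [
                HealthOutcomeRecord(
                    cause=r.cause,
                    measure=r.measure,
                    value=r.endpoint(health_endpoint),
                    source=r.source,
                )
                for r in config.health.records
            ],
            source=config.health.source,
        )
    return attributable_by_cause(dist, curves, table, config.measure, use_pwc=config.use_pwc)


def run_scenario(config: ScenarioConfig) -> list[AttributionResult]:
    """Central-estimate pipeline run; per-cause results plus a sum row."""
    return _evaluate(config)


def _total(results: Sequence[AttributionResult]) -> float:
    for r in results:
        if r.cause == SUM_LABEL:
            return r.attributable
    raise DataError("pipeline results carry no sum row")


def propagate_endpoint(config: ScenarioConfig, which: str) -> EndpointInterval:
    """Substitute the lo/hi variants of one input category and re-run.

    Returns the resulting pair of total attributable values ordered
    (min, max), or an explicit no-interval marker when the chosen
    category carries no CI (e.g. registry health data).
    """
    if which not in ("rr", "exposure", "health"):
        raise ConfigurationError(f"unknown uncertainty category {which!r}")
    kwargs_lo: dict[str, str] = {}
    kwargs_hi: dict[str, str] = {}
    if which == "rr":
        if not all(spec.has_interval for spec in config.curves.values()):
            return EndpointInterval(source="rr", reason="no interval available: curve lacks a 95% CI")
        kwargs_lo["rr_endpoint"], kwargs_hi["rr_endpoint"] = "lo", "hi"
    elif which == "exposure":
        if "lo95" not in config.exposure or "hi95" not in config.exposure:
            return EndpointInterval(
                source="exposure", reason="no interval available: exposure lacks lo95/hi95 variants"
            )
        kwargs_lo["exposure_variant"], kwargs_hi["exposure_variant"] = "lo95", "hi95"
    else:
        needed = [config.health.get(c, config.measure) for c in config.curves]
        if not all(r.has_interval for r in needed):
            return EndpointInterval(
                source="health",
                reason=f"no interval available: health source {config.health.source!r} provides no 95% CI",
            )
        kwargs_lo["health_endpoint"], kwargs_hi["health_endpoint"] = "lo", "hi"
    a = _total(_evaluate(config, **kwargs_lo))
    b = _total(_evaluate(config, **kwargs_hi))
    return EndpointInterval(source=which, lo=min(a, b), hi=max(a, b))


def sum_cause_intervals(
    intervals: Sequence[tuple[float, float] | AttributionResult],
) -> tuple[float, float]:
    """Componentwise sum of per-cause intervals (lo = Σ lo_i, hi = Σ hi_i).

    Accepts bare (lo, hi) pairs or AttributionResults carrying
    intervals; mixing measures across results is an error.
    """
    if not intervals:
        raise DataError("no intervals to sum")
    lo_total = hi_total = 0.0
    measures = set()
    for item in intervals:
        if isinstance(item, AttributionResult):
            if item.interval is None:
                raise DataError(f"{item.cause}/{item.measure}: no interval to sum")
            measures.add(item.measure)
            lo, hi = item.interval
        else:
            lo, hi = item
        if lo > hi:
            raise ValidationError(f"interval lo {lo} > hi {hi}")
        lo_total += lo
        hi_total += hi
    if len(measures) > 1:
        raise DataError(f"cannot sum intervals across measures: {sorted(measures)}")
    return (lo_total, hi_total)


def percent_change(estimate: float, reference: float) -> float | None:
    """Signed percent change versus the reference; None when undefined."""
    if reference == 0:
        return None
    return (estimate - reference) / reference * 100.0


def run_scenario_grid(
    configs: Sequence[ScenarioConfig],
    reference_id: str,
    uncertainty: str | None = "rr",
) -> list[ScenarioResult]:
    """Evaluate every scenario and attach percent changes vs the reference.

    Scenarios are evaluated deterministically in configuration order;
    ``uncertainty`` selects which input category's CI is substituted for
    the reported intervals (None skips interval computation).
    """
    ids = [c.id for c in configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate scenario ids: {dupes}")
    if reference_id not in ids:
        raise ConfigurationError(f"reference scenario {reference_id!r} not in grid")

    totals: dict[str, float] = {}
    evaluated: dict[str, list[AttributionResult]] = {}
    for config in configs:
        results = run_scenario(config)
        evaluated[config.id] = results
        totals[config.id] = _total(results)
    reference_total = totals[reference_id]

    out = []
    for config in configs:
        interval = propagate_endpoint(config, uncertainty) if uncertainty else None
        out.append(
            ScenarioResult(
                scenario_id=config.id,
                measure=config.measure,
                attributable=totals[config.id],
                interval=interval,
                pct_change_vs_reference=percent_change(totals[config.id], reference_total),
                per_cause=tuple(evaluated[config.id]),
            )
        )
    return out


def ledger_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tabulate grid results in stable order.

    Attributable values are written at full precision; percent changes
    are rounded to one decimal (presentation layers round further to
    whole percents).
    """
    rows = []
    for r in results:
        rows.append(
            {
                "scenario_id": r.scenario_id,
                "measure": r.measure,
                "attributable": r.attributable,
                "lo": r.interval.lo if r.interval and r.interval.available else None,
                "hi": r.interval.hi if r.interval and r.interval.available else None,
                "uncertainty_source": r.interval.source if r.interval else "none",
                "pct_change_vs_reference": (
                    None
                    if r.pct_change_vs_reference is None
                    else round(r.pct_change_vs_reference, 1)
                ),
            }
        )
    return pd.DataFrame(rows)
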