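"""Concentration-response curves: relative risk as a function of PM2.5.

Four families are supported, each with a counterfactual cut-off C0 below
which RR is clamped to 1:

* ``linear``     RR(C) = 1 + (RR10 - 1)/10 · (C - C0)
* ``loglinear``  RR(C) = exp(β (C - C0)),            β = ln(RR10)/10
* ``loglog``     RR(C) = ((C+1)/(C0+1))^β,           β = ln(RR10)/(ln(C0+11) - ln(C0+1))
* ``tabulated``  piecewise-linear interpolation of a fitted RR grid
                 (GEMM/MR-BRT style) with an intrinsic cut-off

All closed-form shapes are anchored so that RR(C0 + 10) = RR10 for any
cut-off.  Evaluators are vectorised over numpy arrays and return scalars
for scalar input.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "SHAPES",
    "ENDPOINTS",
    "RelativeRisk10",
    "TabulatedCurve",
    "CurveSpec",
    "rr_linear",
    "rr_loglinear",
    "rr_loglog",
    "rr_tabulated",
    "make_curve",
    "load_tabulated_curve",
    "write_tabulated_curve",
]

SHAPES = ("linear", "loglinear", "loglog", "tabulated")
ENDPOINTS = ("central", "lo", "hi")

Endpoint = Literal["central", "lo", "hi"]


@dataclass(frozen=True)
class RelativeRisk10:
    """Relative risk per 10 µg/m³ with optional 95% CI endpoints."""

    central: float
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.central <= 0:
            raise ValidationError(f"RR10 must be > 0, got {self.central}")
        if (self.lo is None) != (self.hi is None):
            raise ValidationError("RR10 CI needs both lo and hi endpoints")
        if self.lo is not None:
            if self.lo <= 0:
                raise ValidationError(f"RR10 lo endpoint must be > 0, got {self.lo}")
            if not self.lo <= self.central <= self.hi:
                raise ValidationError(
                    f"RR10 CI must satisfy lo <= central <= hi, got ({self.lo}, {self.central}, {self.hi})"
                )

    @property
    def has_interval(self) -> bool:
        return self.lo is not None

    def endpoint(self, which: Endpoint) -> float:
        if which == "central":
            return self.central
        if not self.has_interval:
            raise ValidationError(f"RR10 {self.central} has no CI; cannot take {which!r} endpoint")
        return self.lo if which == "lo" else self.hi  # type: ignore[return-value]


@dataclass(frozen=True)
class TabulatedCurve:
    """A fitted RR curve given on a concentration grid (GEMM/MR-BRT style).

    RR is 1 at and below the intrinsic ``cutoff``, interpolated linearly
    between grid points, and clamped to the last grid value beyond the
    grid.
    """

    grid: tuple[float, ...]
    rr_central: tuple[float, ...]
    rr_lo: tuple[float, ...] | None = None
    rr_hi: tuple[float, ...] | None = None
    cutoff: float = 2.4
    cause: str = ""
    source_label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        rr = np.asarray(self.rr_central, dtype=float)
        if grid.size < 2:
            raise ValidationError("tabulated curve needs at least 2 grid points")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("tabulated curve grid must be strictly ascending")
        if rr.shape != grid.shape:
            raise ValidationError("rr_central length must match grid length")
        if np.any(rr <= 0):
            raise ValidationError("tabulated RR values must be > 0")
        if self.cutoff < 0 or not np.isfinite(self.cutoff):
            raise ValidationError(f"cutoff must be finite and >= 0, got {self.cutoff}")
        at_or_below = grid <= self.cutoff + 1e-12
        if np.any(np.abs(rr[at_or_below] - 1.0) > 1e-9):
            raise ValidationError("tabulated RR must equal 1 at and below the intrinsic cutoff")
        if (self.rr_lo is None) != (self.rr_hi is None):
            raise ValidationError("tabulated curve CI needs both rr_lo and rr_hi")
        if self.rr_lo is not None:
            lo = np.asarray(self.rr_lo, dtype=float)
            hi = np.asarray(self.rr_hi, dtype=float)
            if lo.shape != grid.shape or hi.shape != grid.shape:
                raise ValidationError("rr_lo/rr_hi length must match grid length")
            if np.any(lo <= 0):
                raise ValidationError("tabulated rr_lo values must be > 0")
            if np.any(lo > rr + 1e-12) or np.any(rr > hi + 1e-12):
                raise ValidationError("tabulated curve must satisfy rr_lo <= rr <= rr_hi pointwise")

    @property
    def has_interval(self) -> bool:
        return self.rr_lo is not None

    def values(self, which: Endpoint) -> np.ndarray:
        if which == "central":
            return np.asarray(self.rr_central, dtype=float)
        if not self.has_interval:
            raise ValidationError("tabulated curve has no CI band")
        return np.asarray(self.rr_lo if which == "lo" else self.rr_hi, dtype=float)


def _eval_closed_form(rr10: float, c, c0: float, kernel) -> float | np.ndarray:
    if rr10 <= 0:
        raise ValidationError(f"RR10 must be > 0, got {rr10}")
    if c0 < 0 or not np.isfinite(c0):
        raise ValidationError(f"cutoff must be finite and >= 0, got {c0}")
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("concentration must be >= 0")
    out = np.where(arr <= c0, 1.0, kernel(np.maximum(arr, c0), c0))
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def rr_linear(rr10: float, c, c0: float = 0.0):
    """Linear curve: RR = 1 + (RR10 − 1)/10 · (C − C0), clamped to 1 below C0."""
    return _eval_closed_form(rr10, c, c0, lambda x, c0: 1.0 + (rr10 - 1.0) / 10.0 * (x - c0))


def rr_loglinear(rr10: float, c, c0: float = 0.0):
    """Log-linear curve: RR = exp(ln(RR10)/10 · (C − C0)), clamped to 1 below C0."""
    beta = np.log(rr10) / 10.0
    return _eval_closed_form(rr10, c, c0, lambda x, c0: np.exp(beta * (x - c0)))


def rr_loglog(rr10: float, c, c0: float = 0.0):
    """Log-log curve: RR = ((C+1)/(C0+1))^β with β = ln(RR10)/(ln(C0+11) − ln(C0+1)).

    Anchored so RR(C0) = 1 and RR(C0+10) = RR10 for every cut-off.
    """
    if rr10 <= 0:
        raise ValidationError(f"RR10 must be > 0, got {rr10}")
    beta = np.log(rr10) / (np.log(10.0 + c0 + 1.0) - np.log(c0 + 1.0))
    return _eval_closed_form(rr10, c, c0, lambda x, c0: ((x + 1.0) / (c0 + 1.0)) ** beta)


def rr_tabulated(curve: TabulatedCurve, c, endpoint: Endpoint = "central"):
    """Evaluate a tabulated curve: RR = 1 below the cutoff, interpolated on
    the grid, clamped to the last grid value beyond the grid."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("concentration must be >= 0")
    grid = np.asarray(curve.grid, dtype=float)
    rr = curve.values(endpoint)
    out = np.interp(arr, grid, rr)  # np.interp clamps at both ends
    out = np.where(arr <= curve.cutoff, 1.0, out)
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


@dataclass(frozen=True)
class CurveSpec:
    """A complete curve choice: shape × relative risk × cut-off.

    Exactly one of ``rr10`` (closed-form shapes) or ``table`` (tabulated
    shape) must be populated.  For tabulated curves a ``cutoff`` above
    the table's intrinsic one re-clamps RR to 1 below the override and
    leaves the curve unchanged above it.
    """

    shape: str
    rr10: RelativeRisk10 | None = None
    cutoff: float | None = None
    table: TabulatedCurve | None = None
    cause: str = "all-cause"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(f"unknown curve shape {self.shape!r}, expected one of {SHAPES}")
        if self.shape == "tabulated":
            if self.table is None or self.rr10 is not None:
                raise ValidationError("tabulated shape requires table= and no rr10=")
        else:
            if self.rr10 is None or self.table is not None:
                raise ValidationError(f"{self.shape} shape requires rr10= and no table=")
            if self.rr10.central < 1.0:
                raise ValidationError(
                    f"protective RR10 {self.rr10.central} < 1 rejected; no supported curve is protective"
                )
        c0 = self.effective_cutoff
        if c0 < 0 or not np.isfinite(c0):
            raise ValidationError(f"cutoff must be finite and >= 0, got {c0}")

    @property
    def effective_cutoff(self) -> float:
        if self.shape == "tabulated":
            intrinsic = self.table.cutoff  # type: ignore[union-attr]
            return intrinsic if self.cutoff is None else max(intrinsic, float(self.cutoff))
        return 0.0 if self.cutoff is None else float(self.cutoff)

    @property
    def has_interval(self) -> bool:
        src = self.rr10 if self.shape != "tabulated" else self.table
        return src.has_interval  # type: ignore[union-attr]

    def describe(self) -> dict:
        d = {"cause": self.cause, "shape": self.shape, "cutoff": self.effective_cutoff}
        if self.rr10 is not None:
            d["rr10"] = self.rr10.central
        if self.table is not None:
            d["table"] = self.table.source_label or "tabulated"
        return d


def make_curve(spec: CurveSpec, endpoint: Endpoint = "central") -> Callable:
    """Build a vector-evaluable concentration → RR mapping from a spec."""
    if endpoint not in ENDPOINTS:
        raise ConfigurationError(f"unknown endpoint {endpoint!r}, expected one of {ENDPOINTS}")
    c0 = spec.effective_cutoff
    if spec.shape == "tabulated":
        table = spec.table
        if endpoint != "central":
            table.values(endpoint)  # raises if the CI band is absent

        def curve(c):
            out = rr_tabulated(table, c, endpoint)
            arr = np.asarray(c, dtype=float)
            clamped = np.where(arr <= c0, 1.0, np.asarray(out))
            return float(clamped) if np.isscalar(c) or arr.ndim == 0 else clamped

        return curve

    rr10 = spec.rr10.endpoint(endpoint)
    fn = {"linear": rr_linear, "loglinear": rr_loglinear, "loglog": rr_loglog}[spec.shape]
    return lambda c: fn(rr10, c, c0)


# -- I/O -------------------------------------------------------------


def load_tabulated_curve(
    csv_path: str | os.PathLike, meta: dict | str | os.PathLike | None = None
) -> TabulatedCurve:
    """Read a tabulated curve CSV (``concentration_ugm3, rr, rr_lo, rr_hi``).

    ``meta`` is a dict or sidecar JSON path with ``cause``,
    ``cutoff_ugm3`` and ``source_label``; defaults to a sidecar file
    named ``<csv>.meta.json`` when present.
    """
    df = pd.read_csv(csv_path)
    required = {"concentration_ugm3", "rr"}
    if not required.issubset(df.columns):
        raise FormatError(f"tabulated curve CSV needs columns {sorted(required)}")
    if meta is None:
        sidecar = str(csv_path) + ".meta.json"
        meta = sidecar if os.path.exists(sidecar) else {}
    if not isinstance(meta, dict):
        with open(meta, encoding="utf-8") as fh:
            meta = json.load(fh)
    has_ci = "rr_lo" in df.columns and df["rr_lo"].notna().all()
    return TabulatedCurve(
        grid=tuple(df["concentration_ugm3"].astype(float)),
        rr_central=tuple(df["rr"].astype(float)),
        rr_lo=tuple(df["rr_lo"].astype(float)) if has_ci else None,
        rr_hi=tuple(df["rr_hi"].astype(float)) if has_ci else None,
        cutoff=float(meta.get("cutoff_ugm3", 2.4)),
        cause=str(meta.get("cause", "")),
        source_label=str(meta.get("source_label", "")),
    )


def write_tabulated_curve(curve: TabulatedCurve, csv_path: str | os.PathLike) -> None:
    """Write the grid CSV plus a ``.meta.json`` sidecar."""
    df = pd.DataFrame({"concentration_ugm3": curve.grid, "rr": curve.rr_central})
    if curve.has_interval:
        df["rr_lo"] = curve.rr_lo
        df["rr_hi"] = curve.rr_hi
    df.to_csv(csv_path, index=False)
    meta = {
        "cause": curve.cause,
        "cutoff_ugm3": curve.cutoff,
        "source_label": curve.source_label,
    }
    with open(str(csv_path) + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
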