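"""Run-configuration parsing and resolution.

Configurations are JSON or YAML documents (YAML is a superset, so one
``yaml.safe_load`` handles both).  A scenario block names its exposure
(file, synthetic spec, or bare PWC endpoints), its curve(s), its health
table (file or synthetic spec) and the methodological switches; this
module resolves each block into concrete domain objects.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Any, Mapping

import yaml

from .attribution import HealthOutcomeTable, load_health_table
from .curves import CurveSpec, RelativeRisk10, load_tabulated_curve
from .errors import ConfigurationError
from .exposure import ExposureBin, ExposureDistribution, load_exposure_variants
from .synthetic_data import (
    SyntheticExposureSpec,
    SyntheticHealthSpec,
    generate_exposure,
    generate_health_table,
)
from .uncertainty_scenarios import ScenarioConfig

__all__ = [
    "load_config",
    "resolve_scenario",
    "resolve_grid",
]


def load_config(path: str | os.PathLike) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    return doc


def _degenerate(pwc: float, variant: str) -> ExposureDistribution:
    if pwc >= 0.5:
        bin_ = ExposureBin(pwc - 0.5, pwc + 0.5, 1.0)
    else:
        bin_ = ExposureBin(0.0, 2.0 * pwc, 1.0)
    return ExposureDistribution(bins=(bin_,), variant=variant)


def _resolve_exposure(
    block: Mapping[str, Any], base: Path, scenario_id: str
) -> tuple[dict[str, ExposureDistribution], str]:
    if not isinstance(block, Mapping):
        raise ConfigurationError(f"scenario {scenario_id!r}: exposure block must be a mapping")
    if "path" in block:
        path = base / str(block["path"])
        if not path.exists():
            raise ConfigurationError(f"scenario {scenario_id!r}: exposure file not found: {path}")
        return dict(load_exposure_variants(path)), str(block.get("label", path.name))
    if "synthetic" in block:
        params = dict(block["synthetic"] or {})
        spec = SyntheticExposureSpec(**params)
        return dict(generate_exposure(spec)), str(
            block.get("label", f"synthetic(pwc={spec.target_pwc})")
        )
    if "pwc" in block:
        # bare PWC endpoints: substitute in the PWC pathway
        variants = {"central": _degenerate(float(block["pwc"]), "central")}
        if "pwc_lo" in block and "pwc_hi" in block:
            variants["lo95"] = _degenerate(float(block["pwc_lo"]), "lo95")
            variants["hi95"] = _degenerate(float(block["pwc_hi"]), "hi95")
        return variants, str(block.get("label", f"pwc={block['pwc']}"))
    raise ConfigurationError(
        f"scenario {scenario_id!r}: exposure block needs 'path', 'synthetic' or 'pwc'"
    )


def _resolve_curve(block: Mapping[str, Any], cause: str, base: Path, scenario_id: str) -> CurveSpec:
    if not isinstance(block, Mapping):
        raise ConfigurationError(f"scenario {scenario_id!r}: curve block must be a mapping")
    cutoff = block.get("cutoff")
    cutoff = None if cutoff is None else float(cutoff)
    if "table" in block:
        path = base / str(block["table"])
        if not path.exists():
            raise ConfigurationError(f"scenario {scenario_id!r}: curve table not found: {path}")
        table = load_tabulated_curve(path)
        return CurveSpec(shape="tabulated", table=table, cutoff=cutoff, cause=cause)
    try:
        shape = str(block["shape"])
        central = float(block["rr10"])
    except KeyError as exc:
        raise ConfigurationError(
            f"scenario {scenario_id!r}: curve block needs 'shape' and 'rr10' (or 'table'): missing {exc}"
        ) from None
    lo = block.get("rr10_lo")
    hi = block.get("rr10_hi")
    rr10 = RelativeRisk10(
        central=central,
        lo=None if lo is None else float(lo),
        hi=None if hi is None else float(hi),
    )
    return CurveSpec(shape=shape, rr10=rr10, cutoff=cutoff, cause=cause)


def _resolve_health(
    block: Mapping[str, Any], base: Path, scenario_id: str
) -> tuple[HealthOutcomeTable, str]:
    if not isinstance(block, Mapping):
        raise ConfigurationError(f"scenario {scenario_id!r}: health block must be a mapping")
    if "path" in block:
        path = base / str(block["path"])
        if not path.exists():
            raise ConfigurationError(f"scenario {scenario_id!r}: health file not found: {path}")
        source = str(block.get("source", ""))
        return load_health_table(path, source=source or None), source or path.name
    if "synthetic" in block:
        params = dict(block["synthetic"] or {})
        spec = SyntheticHealthSpec(**params)
        return generate_health_table(spec), spec.source
    raise ConfigurationError(f"scenario {scenario_id!r}: health block needs 'path' or 'synthetic'")


def resolve_scenario(block: Mapping[str, Any], base: str | os.PathLike = ".") -> ScenarioConfig:
    """Resolve one scenario mapping into a concrete :class:`ScenarioConfig`."""
    base = Path(base)
    scenario_id = str(block.get("id", "")) or "unnamed"
    if "exposure" not in block or "health" not in block:
        raise ConfigurationError(f"scenario {scenario_id!r}: needs 'exposure' and 'health' blocks")
    exposure, exposure_label = _resolve_exposure(block["exposure"], base, scenario_id)
    health, health_label = _resolve_health(block["health"], base, scenario_id)
    if "curves" in block:
        curves = {
            str(cause): _resolve_curve(spec, str(cause), base, scenario_id)
            for cause, spec in block["curves"].items()
        }
    elif "curve" in block:
        cause = str(block.get("cause", "all-cause"))
        curves = {cause: _resolve_curve(block["curve"], cause, base, scenario_id)}
    else:
        raise ConfigurationError(f"scenario {scenario_id!r}: needs a 'curve' or 'curves' block")
    use_pwc = bool(block.get("use_pwc", False))
    if "pwc" in block.get("exposure", {}):
        use_pwc = True  # bare-PWC exposure only supports the PWC pathway
    return ScenarioConfig(
        id=scenario_id,
        exposure=exposure,
        curves=curves,
        health=health,
        measure=str(block.get("measure", "deaths")),
        use_pwc=use_pwc,
        shift_delta=float(block.get("shift_delta", 0.0)),
        exposure_label=exposure_label,
        health_label=health_label,
    )


def resolve_grid(doc: Mapping[str, Any], base: str | os.PathLike = ".") -> tuple[list[ScenarioConfig], str]:
    """Resolve a grid document into scenario configs plus the reference id."""
    scenarios = doc.get("scenarios")
    if not scenarios:
        raise ConfigurationError("config has no scenarios")
    configs = [resolve_scenario(block, base) for block in scenarios]
    reference = doc.get("reference")
    if not reference:
        raise ConfigurationError("config names no reference scenario")
    return configs, str(reference)
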