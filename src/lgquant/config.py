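"""Run configuration: YAML schema, validation, defaults.

A run config describes a whole synthetic experiment: the scene and noise
models, detection and classification parameters, the conditions to compare
and the stages to execute.  Validation is eager and collects *all*
violations into one error, so a config is fixed in one pass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from ._errors import ValidationError
from .classify import ClassificationParams
from .detect import DetectionParams, ThresholdRule
from .synthetic import NoiseModel, SceneParams

__all__ = ["Condition", "RunConfig", "load_config", "config_from_dict",
           "params_from_dict"]

STAGES = ("simulate", "count", "classify", "index", "dda", "compare")

_TUPLE_FIELDS = {"shape", "spacing", "radius_range", "psc_center_frac",
                 "psc_semiaxes", "dye_channels"}


def _build(cls, data: Mapping[str, Any], errors: list[str], context: str,
           base=None):
    """Instantiate a params dataclass from a dict, collecting problems."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        errors.append(f"{context}: unknown keys {sorted(unknown)}; allowed: {sorted(known)}")
    clean = {k: (tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v)
             for k, v in data.items() if k in known}
    try:
        if base is not None:
            return replace(base, **clean)
        return cls(**clean)
    except (ValidationError, TypeError, ValueError) as exc:
        errors.append(f"{context}: {exc}")
        return base if base is not None else None


def params_from_dict(cls, data: Mapping[str, Any], context: str = "params"):
    """Build a single params dataclass (SceneParams, NoiseModel, ...) from a
    mapping, raising one ValidationError listing every problem."""
    errors: list[str] = []
    obj = _build(cls, data, errors, context)
    if errors:
        raise ValidationError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return obj


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a name and its scene parameters."""

    name: str
    n_specimens: int
    scene: SceneParams


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: Path = Path("lgquant-out")
    stages: tuple[str, ...] = ("simulate", "count", "classify", "index", "compare")
    scene: SceneParams = field(default_factory=SceneParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    detection: DetectionParams = field(default_factory=DetectionParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    conditions: tuple[Condition, ...] = ()
    write_stacks: bool = False
    dda_specimens: int = 0          # per condition (intact/broken) when 'dda' staged
    raw: Mapping[str, Any] = field(default_factory=dict, compare=False)

    def effective_conditions(self) -> tuple[Condition, ...]:
        if self.conditions:
            return self.conditions
        return (Condition("default", 1, self.scene),)


_TOP_KEYS = {"seed", "outdir", "stages", "scene", "noise", "detection",
             "classification", "experiment", "write_stacks", "dda_specimens"}


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Validate a config mapping and fill defaults.

    Raises
    ------
    ValidationError
        Listing every violation found (unknown keys, bad parameter values,
        contradictory channel roles, unknown stages or threshold rules).
    """
    errors: list[str] = []
    unknown = set(data) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}")

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0

    stages = tuple(data.get("stages", ("simulate", "count", "classify", "index", "compare")))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        errors.append(f"unknown stages {bad}; allowed: {list(STAGES)}")

    scene = _build(SceneParams, data.get("scene", {}), errors, "scene") or SceneParams()
    noise = _build(NoiseModel, data.get("noise", {}), errors, "noise") or NoiseModel()
    detection = _build(DetectionParams, data.get("detection", {}), errors,
                       "detection") or DetectionParams()
    cls_data = dict(data.get("classification", {}))
    classification = _build(ClassificationParams, cls_data, errors,
                            "classification") or ClassificationParams()

    # channel roles: the nuclear channel must be named exactly once
    roles = [scene.nuclear_channel, *scene.marker_names(), *scene.dye_channels]
    dupes = {r for r in roles if roles.count(r) > 1}
    if dupes:
        errors.append(f"channel role conflict: {sorted(dupes)} assigned more than one role")

    conditions: list[Condition] = []
    for i, cond in enumerate(data.get("experiment", {}).get("conditions", [])):
        name = cond.get("name", f"condition{i}")
        n_specimens = cond.get("n_specimens", 1)
        if not (isinstance(n_specimens, int) and n_specimens >= 1):
            errors.append(f"condition {name!r}: n_specimens must be a positive integer")
            n_specimens = 1
        extra = set(cond) - {"name", "n_specimens", "scene"}
        if extra:
            errors.append(f"condition {name!r}: unknown keys {sorted(extra)}")
        cscene = _build(SceneParams, cond.get("scene", {}), errors,
                        f"condition {name!r} scene", base=scene) or scene
        conditions.append(Condition(name, n_specimens, cscene))
    if "compare" in stages and len(conditions) == 1:
        errors.append("compare stage needs at least two conditions")

    dda_specimens = data.get("dda_specimens", 5 if "dda" in stages else 0)

    if errors:
        raise ValidationError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(seed=seed, outdir=Path(data.get("outdir", "lgquant-out")),
                     stages=stages, scene=scene, noise=noise, detection=detection,
                     classification=classification, conditions=tuple(conditions),
                     write_stacks=bool(data.get("write_stacks", False)),
                     dda_specimens=int(dda_specimens), raw=dict(data))


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValidationError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)
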