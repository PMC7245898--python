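"""Model configuration: loading, validation and base-case evaluation.

A model config (YAML) has four blocks: ``arms`` (per-arm conditional
probabilities as events/total pairs, base lengths of stay and the upfront
pre-admission profile), ``los_increments``, ``profiles`` (resource-use
quantities) and ``psa`` (distribution conventions). ``default_config()``
loads the packaged calibrated base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .cohort import Arm, MODEL_EVENTS
from .costing import CostCatalogue, ResourceProfile, default_catalogue, load_catalogue
from .exceptions import ConfigurationError, ValidationError
from .model import (
    EventProbabilities,
    IncrementalResult,
    LOSModel,
    PROBABILITY_PARAMS,
    ResourceModel,
    StrategyExpectation,
    build_tree,
    incremental,
    rollback,
)


@dataclass(frozen=True)
class PSASettings:
    """Distribution conventions for the probabilistic sensitivity analysis."""

    n_draws: int = 10_000
    evidence_weight: float = 10.0
    gamma_bound_fraction: float = 0.10
    uniform_halfwidth: float = 0.10
    shared_cost_draws: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if self.evidence_weight <= 0:
            raise ValidationError("evidence_weight must be > 0")
        if not 0 <= self.uniform_halfwidth < 1:
            raise ValidationError("uniform_halfwidth must be in [0, 1)")
        if not 0 < self.gamma_bound_fraction < 1:
            raise ValidationError("gamma_bound_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ArmSpec:
    probabilities: EventProbabilities
    los: LOSModel
    upfront: ResourceProfile


@dataclass(frozen=True)
class ModelConfig:
    arms: Mapping[Arm, ArmSpec]
    catalogue: CostCatalogue
    resources: ResourceModel
    psa: PSASettings = field(default_factory=PSASettings)

    def arm(self, arm: Arm | str) -> ArmSpec:
        return self.arms[Arm(arm)]


def _require(raw: Mapping, key: str, where: str):
    if key not in raw:
        raise ConfigurationError(f"config block {where!r} is missing {key!r}")
    return raw[key]


def _parse_probabilities(raw: Mapping, where: str) -> EventProbabilities:
    values: dict[str, float] = {}
    counts: dict[str, tuple[float, float]] = {}
    for name in PROBABILITY_PARAMS:
        entry = _require(raw, name, where)
        if isinstance(entry, Mapping):
            events = float(_require(entry, "events", f"{where}.{name}"))
            total = float(_require(entry, "total", f"{where}.{name}"))
            if total <= 0 or events < 0 or events > total:
                raise ValidationError(f"{where}.{name}: invalid counts ({events}, {total})")
            values[name] = events / total
            counts[name] = (events, total)
        else:
            values[name] = float(entry)
            counts[name] = (float(entry), 1.0)
    return EventProbabilities(counts=counts, **values)


def _parse_increments(raw: Mapping, kind: str) -> dict[str, float]:
    out = {}
    for ev in MODEL_EVENTS:
        entry = _require(raw, ev, "los_increments")
        out[ev] = float(_require(entry, kind, f"los_increments.{ev}"))
    return out


def _profile(raw: Mapping, applies_to: str) -> ResourceProfile:
    return ResourceProfile({str(k): float(v) for k, v in raw.items()}, applies_to)


def load_config(
    path: str | Path | None = None,
    catalogue_path: str | Path | None = None,
) -> ModelConfig:
    """Load a model config; both paths default to the packaged files."""
    if path is None:
        ref = resources.files("levocea.data").joinpath("base_case.yaml")
        with resources.as_file(ref) as p:
            return load_config(p, catalogue_path)
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"model config {path} must be a mapping")

    catalogue = (
        default_catalogue() if catalogue_path is None else load_catalogue(catalogue_path)
    )

    inc_raw = _require(raw, "los_increments", "top level")
    icu_inc = _parse_increments(inc_raw, "icu")
    ward_inc = _parse_increments(inc_raw, "ward")

    arms_raw = _require(raw, "arms", "top level")
    arms: dict[Arm, ArmSpec] = {}
    upfront: dict[Arm, ResourceProfile] = {}
    for arm in Arm:
        arm_raw = _require(arms_raw, arm.value, "arms")
        probs = _parse_probabilities(_require(arm_raw, "probabilities", arm.value), arm.value)
        los_raw = _require(arm_raw, "los", arm.value)
        los = LOSModel(
            base_icu_days=float(_require(los_raw, "base_icu_days", f"{arm.value}.los")),
            base_ward_days=float(_require(los_raw, "base_ward_days", f"{arm.value}.los")),
            icu_increments=icu_inc,
            ward_increments=ward_inc,
        )
        up = _profile(arm_raw.get("upfront", {}), f"{arm.value} pre-operative admission")
        arms[arm] = ArmSpec(probabilities=probs, los=los, upfront=up)
        upfront[arm] = up

    prof_raw = _require(raw, "profiles", "top level")
    complications = {
        ev: _profile(p, f"{ev} add-on")
        for ev, p in _require(prof_raw, "complications", "profiles").items()
    }
    unknown = set(complications) - set(MODEL_EVENTS)
    if unknown:
        raise ConfigurationError(f"unknown complications in profiles: {sorted(unknown)}")
    resources_model = ResourceModel(
        per_patient=_profile(_require(prof_raw, "per_patient", "profiles"), "every pathway"),
        per_icu_day=_profile(_require(prof_raw, "per_icu_day", "profiles"), "per ICU day"),
        per_ward_day=_profile(_require(prof_raw, "per_ward_day", "profiles"), "per ward day"),
        complications=complications,
        upfront=upfront,
    )

    # verify every profile code resolves in the catalogue up front
    all_profiles = [
        resources_model.per_patient,
        resources_model.per_icu_day,
        resources_model.per_ward_day,
        *complications.values(),
        *upfront.values(),
    ]
    for profile in all_profiles:
        for code in profile.quantities:
            catalogue[code]  # raises LookupError_ with the code name

    psa_raw = raw.get("psa", {})
    psa = PSASettings(
        n_draws=int(psa_raw.get("n_draws", 10_000)),
        evidence_weight=float(psa_raw.get("evidence_weight", 10.0)),
        gamma_bound_fraction=float(psa_raw.get("gamma_bound_fraction", 0.10)),
        uniform_halfwidth=float(psa_raw.get("uniform_halfwidth", 0.10)),
        shared_cost_draws=bool(psa_raw.get("shared_cost_draws", True)),
    )
    return ModelConfig(arms=arms, catalogue=catalogue, resources=resources_model, psa=psa)


def default_config() -> ModelConfig:
    """The packaged calibrated base-case configuration."""
    return load_config()


@dataclass(frozen=True)
class BaseCaseResult:
    expectations: Mapping[Arm, StrategyExpectation]
    difference: IncrementalResult


def evaluate_arm(config: ModelConfig, arm: Arm) -> StrategyExpectation:
    spec = config.arm(arm)
    return rollback(
        build_tree(spec.probabilities, spec.los, config.catalogue, config.resources, arm)
    )


def base_case(config: ModelConfig) -> BaseCaseResult:
    """Roll back both strategies and form the incremental result."""
    exps = {arm: evaluate_arm(config, arm) for arm in Arm}
    return BaseCaseResult(
        expectations=exps,
        difference=incremental(exps[Arm.INTERVENTION], exps[Arm.CONTROL]),
    )
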