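"""Deterministic and probabilistic sensitivity analysis.

Deterministic (DSA): one-parameter-at-a-time re-evaluation of the base case
with the marginal LCO incidence of one arm overridden to a published
scenario value (both LCO conditionals rescaled by a common factor, which
preserves the NOAF-LCO association).

Probabilistic (PSA): Monte Carlo over the full parameter space.
Probabilities draw from beta distributions parameterised by occurrence /
non-occurrence counts (times a configurable evidence weight; zero-event
cells get the Jeffreys half-count adjustment); unit costs draw from gamma
distributions whose central 95% interval spans mean*(1 +/- bound);
resource quantities and lengths of stay draw from uniform distributions
q*(1 +/- halfwidth). Each draw re-evaluates the full tree for both
strategies; unit-cost draws are shared between strategies by default.

Draw order is fixed and documented: every parameter is drawn as a full
vector of ``n_draws`` values from a single seeded generator, parameters in
config order (unit costs, resource quantities, probabilities, lengths of
stay), so results are bit-reproducible for a given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _res
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Arm, MODEL_EVENTS
from .config import ArmSpec, ModelConfig, PSASettings, evaluate_arm
from .costing import CostCatalogue, ResourceProfile, UnitCost
from .exceptions import ConfigurationError, ValidationError
from .model import (
    EventProbabilities,
    LOSModel,
    PROBABILITY_PARAMS,
    ResourceModel,
    build_tree,
    rollback,
)

# --------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class DistributionSpec:
    """One parameter's uncertainty distribution.

    kind = beta | gamma | uniform | fixed. Construct via the classmethods;
    ``params`` is kind-specific.
    """

    kind: str
    params: tuple[float, ...]

    @classmethod
    def beta(cls, events: float, non_events: float) -> "DistributionSpec":
        if events < 0 or non_events < 0 or events + non_events <= 0:
            raise ValidationError(f"invalid beta counts ({events}, {non_events})")
        return cls("beta", (float(events), float(non_events)))

    @classmethod
    def gamma(cls, mean: float, bound_fraction: float = 0.10) -> "DistributionSpec":
        if mean <= 0:
            raise ValidationError(f"gamma mean must be > 0, got {mean}")
        if not 0 < bound_fraction < 1:
            raise ValidationError("gamma bound_fraction must be in (0, 1)")
        return cls("gamma", (float(mean), float(bound_fraction)))

    @classmethod
    def uniform(cls, lower: float, upper: float) -> "DistributionSpec":
        if lower > upper:
            raise ValidationError(f"uniform lower {lower} > upper {upper}")
        return cls("uniform", (float(lower), float(upper)))

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", (float(value),))

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.kind == "beta":
            r, s = self.params
            if r == 0.0 or s == 0.0:
                # Jeffreys half-count adjustment for empty cells
                r, s = r + 0.5, s + 0.5
            return rng.beta(r, s, size=size)
        if self.kind == "gamma":
            mean, bound = self.params
            # shape set so that +/-1.96 sd spans mean*(1 +/- bound)
            shape = (1.96 / bound) ** 2
            return rng.gamma(shape, mean / shape, size=size)
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size=size)
        if self.kind == "fixed":
            v = self.params[0]
            return np.full(size, v) if size is not None else v
        raise ValidationError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "beta":
            r, s = self.params
            if r == 0.0 or s == 0.0:
                r, s = r + 0.5, s + 0.5
            return r / (r + s)
        if self.kind == "gamma":
            return self.params[0]
        if self.kind == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]


def sample(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from a parameter distribution."""
    return float(spec.draw(rng))


# --------------------------------------------------------------------------
# deterministic sensitivity analysis


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    arm: Arm
    p_lco: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_lco <= 1.0:
            raise ValidationError(f"scenario {self.label!r}: p_lco outside [0, 1]")


def load_scenarios(path: str | Path | None = None) -> list[ScenarioSpec]:
    """Load DSA scenarios (defaults to the packaged published-incidence set)."""
    if path is None:
        ref = _res.files("levocea.data").joinpath("scenarios.yaml")
        with _res.as_file(ref) as p:
            return load_scenarios(p)
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ConfigurationError(f"scenario file {path} must be a list")
    return [
        ScenarioSpec(
            label=str(item["label"]),
            arm=Arm(item["arm"]),
            p_lco=float(item["p_lco"]),
            source_note=str(item.get("source_note", "")),
        )
        for item in raw
    ]


def run_dsa(config: ModelConfig, scenarios: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Base case plus one re-evaluation per LCO-incidence scenario.

    Returns a tidy table with one row per (scenario, arm): expected cost,
    mean ICU and ward days and % complication-free.
    """
    rows = []

    def row(label: str, arm: Arm, exp) -> dict:
        return {
            "scenario": label,
            "arm": arm.value,
            "expected_cost": exp.expected_cost,
            "mean_icu_days": exp.mean_icu_days,
            "mean_ward_days": exp.mean_ward_days,
            "pct_no_complications": exp.pct_no_complications,
        }

    for arm in Arm:
        rows.append(row("base case", arm, evaluate_arm(config, arm)))
    for sc in scenarios:
        spec = config.arm(sc.arm)
        probs = spec.probabilities.with_lco_marginal(sc.p_lco)
        exp = rollback(
            build_tree(probs, spec.los, config.catalogue, config.resources, sc.arm)
        )
        rows.append(row(sc.label, sc.arm, exp))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class PSADrawSet:
    """Per-draw strategy outcomes: cost (EUR), effect (% complication-free),
    ICU and ward days, for each strategy."""

    cost: Mapping[Arm, np.ndarray]
    effect: Mapping[Arm, np.ndarray]
    icu_days: Mapping[Arm, np.ndarray]
    ward_days: Mapping[Arm, np.ndarray]
    seed: int
    n_draws: int


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float


@dataclass(frozen=True)
class PSASummary:
    strategies: Mapping[Arm, Mapping[str, IntervalEstimate]]
    dominance_fraction: float
    seed: int
    n_draws: int
    ci_level: float


def _quantity_specs(
    prefix: str, profile: ResourceProfile, halfwidth: float, degenerate: bool
) -> dict[str, DistributionSpec]:
    out = {}
    for code, q in profile.quantities.items():
        name = f"{prefix}.{code}"
        if degenerate or q == 0.0:
            out[name] = DistributionSpec.fixed(q)
        else:
            out[name] = DistributionSpec.uniform(q * (1 - halfwidth), q * (1 + halfwidth))
    return out


def build_distributions(
    config: ModelConfig, degenerate: bool = False
) -> dict[str, DistributionSpec]:
    """The full named parameter->distribution map, in draw order.

    ``degenerate=True`` pins every parameter at its base-case value (a
    consistency check: the PSA must then reproduce the base case exactly).
    """
    psa: PSASettings = config.psa
    dists: dict[str, DistributionSpec] = {}

    # 1. unit costs (catalogue order), shared between strategies by default
    cost_arms = [None] if psa.shared_cost_draws else list(Arm)
    for owner in cost_arms:
        tag = "cost" if owner is None else f"cost.{owner.value}"
        for code, uc in config.catalogue.entries.items():
            name = f"{tag}.{code}"
            if degenerate or uc.unit_cost == 0.0:
                dists[name] = DistributionSpec.fixed(uc.unit_cost)
            else:
                dists[name] = DistributionSpec.gamma(uc.unit_cost, psa.gamma_bound_fraction)

    # 2. resource quantities (shared profiles, then per-arm upfront)
    h = psa.uniform_halfwidth
    dists.update(_quantity_specs("quantity.per_patient", config.resources.per_patient, h, degenerate))
    dists.update(_quantity_specs("quantity.per_icu_day", config.resources.per_icu_day, h, degenerate))
    dists.update(_quantity_specs("quantity.per_ward_day", config.resources.per_ward_day, h, degenerate))
    for ev in MODEL_EVENTS:
        profile = config.resources.complications.get(ev)
        if profile is not None:
            dists.update(_quantity_specs(f"quantity.complication.{ev}", profile, h, degenerate))
    for arm in Arm:
        dists.update(
            _quantity_specs(f"quantity.upfront.{arm.value}", config.arm(arm).upfront, h, degenerate)
        )

    # 3. transition probabilities (beta from evidence counts x weight)
    for arm in Arm:
        probs = config.arm(arm).probabilities
        for pname in PROBABILITY_PARAMS:
            name = f"prob.{arm.value}.{pname}"
            if degenerate:
                dists[name] = DistributionSpec.fixed(getattr(probs, pname))
            else:
                if probs.counts is None or pname not in probs.counts:
                    raise ConfigurationError(
                        f"no evidence counts for {name}; cannot parameterise its beta"
                    )
                events, total = probs.counts[pname]
                w = psa.evidence_weight
                dists[name] = DistributionSpec.beta(events * w, (total - events) * w)

    # 4. lengths of stay: per-arm bases, shared increments
    for arm in Arm:
        los = config.arm(arm).los
        for pname, v in (
            ("base_icu_days", los.base_icu_days),
            ("base_ward_days", los.base_ward_days),
        ):
            name = f"los.{arm.value}.{pname}"
            if degenerate or v == 0.0:
                dists[name] = DistributionSpec.fixed(v)
            else:
                dists[name] = DistributionSpec.uniform(v * (1 - h), v * (1 + h))
    ref_los = config.arm(Arm.INTERVENTION).los
    for ev in MODEL_EVENTS:
        for kind, mapping in (("icu", ref_los.icu_increments), ("ward", ref_los.ward_increments)):
            v = mapping.get(ev, 0.0)
            name = f"los.increment.{ev}.{kind}"
            if degenerate or v == 0.0:
                dists[name] = DistributionSpec.fixed(v)
            else:
                dists[name] = DistributionSpec.uniform(v * (1 - h), v * (1 + h))

    return dists


def _draw_profile(
    prefix: str, base: ResourceProfile, draws: Mapping[str, np.ndarray], i: int
) -> ResourceProfile:
    return ResourceProfile(
        {code: float(draws[f"{prefix}.{code}"][i]) for code in base.quantities},
        base.applies_to,
    )


def run_psa(
    config: ModelConfig,
    psa: PSAConfig | None = None,
    distributions: Mapping[str, DistributionSpec] | None = None,
) -> PSADrawSet:
    """Monte Carlo PSA: n_draws parameter vectors through the full tree.

    Each draw evaluates ``build_tree`` + ``rollback`` for both strategies
    with a jointly drawn parameter set; shared parameters (unit costs,
    shared profiles, LOS increments) use one draw for both strategies.
    """
    psa = psa or PSAConfig()
    if distributions is None:
        distributions = build_distributions(config)
    rng = np.random.default_rng(psa.seed)
    n = psa.n_draws
    draws: dict[str, np.ndarray] = {
        name: np.asarray(spec.draw(rng, size=n), dtype=float)
        for name, spec in distributions.items()
    }

    shared_costs = config.psa.shared_cost_draws
    res = config.resources
    out = {
        metric: {arm: np.empty(n) for arm in Arm}
        for metric in ("cost", "effect", "icu", "ward")
    }

    for i in range(n):
        # per-draw catalogue(s)
        def catalogue_for(arm: Arm) -> CostCatalogue:
            tag = "cost" if shared_costs else f"cost.{arm.value}"
            return CostCatalogue(
                {
                    code: UnitCost(code, uc.label, float(draws[f"{tag}.{code}"][i]), uc.category)
                    for code, uc in config.catalogue.entries.items()
                }
            )

        per_patient = _draw_profile("quantity.per_patient", res.per_patient, draws, i)
        per_icu = _draw_profile("quantity.per_icu_day", res.per_icu_day, draws, i)
        per_ward = _draw_profile("quantity.per_ward_day", res.per_ward_day, draws, i)
        complications = {
            ev: _draw_profile(f"quantity.complication.{ev}", profile, draws, i)
            for ev, profile in res.complications.items()
        }
        icu_inc = {ev: float(draws[f"los.increment.{ev}.icu"][i]) for ev in MODEL_EVENTS}
        ward_inc = {ev: float(draws[f"los.increment.{ev}.ward"][i]) for ev in MODEL_EVENTS}

        shared_cat = catalogue_for(Arm.INTERVENTION) if shared_costs else None
        for arm in Arm:
            spec_a: ArmSpec = config.arm(arm)
            upfront = _draw_profile(f"quantity.upfront.{arm.value}", spec_a.upfront, draws, i)
            resources_i = ResourceModel(
                per_patient=per_patient,
                per_icu_day=per_icu,
                per_ward_day=per_ward,
                complications=complications,
                upfront={arm: upfront},
            )
            probs = EventProbabilities(
                **{p: float(draws[f"prob.{arm.value}.{p}"][i]) for p in PROBABILITY_PARAMS}
            )
            los = LOSModel(
                base_icu_days=float(draws[f"los.{arm.value}.base_icu_days"][i]),
                base_ward_days=float(draws[f"los.{arm.value}.base_ward_days"][i]),
                icu_increments=icu_inc,
                ward_increments=ward_inc,
            )
            cat = shared_cat if shared_cat is not None else catalogue_for(arm)
            exp = rollback(build_tree(probs, los, cat, resources_i, arm))
            out["cost"][arm][i] = exp.expected_cost
            out["effect"][arm][i] = exp.pct_no_complications
            out["icu"][arm][i] = exp.mean_icu_days
            out["ward"][arm][i] = exp.mean_ward_days

    return PSADrawSet(
        cost=out["cost"],
        effect=out["effect"],
        icu_days=out["icu"],
        ward_days=out["ward"],
        seed=psa.seed,
        n_draws=n,
    )


def summarize_psa(draws: PSADrawSet, ci_level: float = 0.95) -> PSASummary:
    """Means, percentile intervals and the dominance fraction."""
    if draws.n_draws < 2:
        raise ValidationError("need at least 2 draws for percentile intervals")
    alpha = (1.0 - ci_level) / 2.0
    strategies: dict[Arm, dict[str, IntervalEstimate]] = {}
    metrics = {
        "cost": draws.cost,
        "pct_no_complications": draws.effect,
        "icu_days": draws.icu_days,
        "ward_days": draws.ward_days,
    }
    for arm in Arm:
        strategies[arm] = {}
        for metric, values in metrics.items():
            v = values[arm]
            lo, hi = np.quantile(v, [alpha, 1.0 - alpha])
            strategies[arm][metric] = IntervalEstimate(
                point=float(np.mean(v)), lower=float(lo), upper=float(hi)
            )
    dominant = (draws.cost[Arm.CONTROL] > draws.cost[Arm.INTERVENTION]) & (
        draws.effect[Arm.INTERVENTION] > draws.effect[Arm.CONTROL]
    )
    return PSASummary(
        strategies=strategies,
        dominance_fraction=float(np.mean(dominant)),
        seed=draws.seed,
        n_draws=draws.n_draws,
        ci_level=ci_level,
    )


def ce_plane(draws: PSADrawSet) -> pd.DataFrame:
    """Cost-effectiveness-plane points, one per draw.

    ``d_effect`` = intervention - control, percentage points of
    complication-free patients (x axis); ``d_cost`` = control -
    intervention, euros saved (y axis). The dominant quadrant is
    ``d_effect > 0 and d_cost > 0``.
    """
    d_effect = draws.effect[Arm.INTERVENTION] - draws.effect[Arm.CONTROL]
    d_cost = draws.cost[Arm.CONTROL] - draws.cost[Arm.INTERVENTION]
    return pd.DataFrame(
        {
            "draw": np.arange(draws.n_draws),
            "d_effect": d_effect,
            "d_cost": d_cost,
            "dominant": (d_effect > 0) & (d_cost > 0),
        }
    )
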