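"""Two-strategy decision tree: pathways, roll-back and incremental results.

The tree compares preconditioning with levosimendan against standard care.
From each strategy branch the chance nodes unfold as

    NOAF  ->  LCO | NOAF  ->  { renal failure, prolonged MV } | LCO,

i.e. new-onset atrial fibrillation is upstream of low cardiac output, and
renal failure and prolonged mechanical ventilation are conditionally
independent given LCO. Each of the 2^4 = 16 terminal pathways per arm
carries a probability (chain product), a length of stay (arm base days plus
additive per-complication increments) and a cost (surgery and fixed
resources, pre-operative add-on for the intervention arm, per-day ICU and
ward bundles, and complication-specific add-ons).

Rolling back a strategy is the probability-weighted expectation over its 16
pathways; the effectiveness endpoint is the percentage of patients free of
all four complications.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .cohort import Arm, MODEL_EVENTS, PatientRecord
from .costing import CostCatalogue, ResourceProfile, pathway_cost
from .exceptions import ConservationError, EstimationError, ValidationError

#: Conditional-probability parameter names, in canonical (draw) order.
PROBABILITY_PARAMS = (
    "p_noaf",
    "p_lco_given_noaf",
    "p_lco_given_no_noaf",
    "p_rf_given_lco",
    "p_rf_given_no_lco",
    "p_mv_given_lco",
    "p_mv_given_no_lco",
)


@dataclass(frozen=True)
class EventProbabilities:
    """Arm-specific conditional probabilities of the four complications.

    ``counts`` optionally carries the (events, total) pairs behind each
    fraction; the probabilistic sensitivity analysis uses them to
    parameterise beta distributions.
    """

    p_noaf: float
    p_lco_given_noaf: float
    p_lco_given_no_noaf: float
    p_rf_given_lco: float
    p_rf_given_no_lco: float
    p_mv_given_lco: float
    p_mv_given_no_lco: float
    counts: Mapping[str, tuple[float, float]] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in PROBABILITY_PARAMS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")

    @property
    def marginal_lco(self) -> float:
        return self.p_noaf * self.p_lco_given_noaf + (1 - self.p_noaf) * self.p_lco_given_no_noaf

    @property
    def marginal_rf(self) -> float:
        m = self.marginal_lco
        return m * self.p_rf_given_lco + (1 - m) * self.p_rf_given_no_lco

    @property
    def marginal_mv(self) -> float:
        m = self.marginal_lco
        return m * self.p_mv_given_lco + (1 - m) * self.p_mv_given_no_lco

    @property
    def p_complication_free(self) -> float:
        """Closed-form probability of the all-clear pathway."""
        return (
            (1 - self.p_noaf)
            * (1 - self.p_lco_given_no_noaf)
            * (1 - self.p_rf_given_no_lco)
            * (1 - self.p_mv_given_no_lco)
        )

    def check_lco_marginal(self, supplied: float, tol: float = 1e-6) -> None:
        """Verify a supplied marginal LCO probability against the chain."""
        if abs(self.marginal_lco - supplied) > tol:
            raise ValidationError(
                f"marginal LCO inconsistency: chain gives {self.marginal_lco:.6f}, "
                f"supplied {supplied:.6f}"
            )

    def with_lco_marginal(self, target: float) -> "EventProbabilities":
        """Rescale both LCO conditionals by a common factor to hit a new marginal.

        Preserves the NOAF->LCO association structure; used by the
        deterministic sensitivity analysis.
        """
        if not 0.0 <= target <= 1.0:
            raise ValidationError(f"target LCO marginal {target} outside [0, 1]")
        current = self.marginal_lco
        if current == 0.0:
            if target == 0.0:
                return self
            raise ValidationError("cannot rescale a zero LCO marginal to a positive target")
        factor = target / current
        new_given_noaf = self.p_lco_given_noaf * factor
        new_given_no = self.p_lco_given_no_noaf * factor
        if new_given_noaf > 1.0 or new_given_no > 1.0:
            raise ValidationError(
                f"LCO override {target} pushes a conditional above 1 "
                f"(factor {factor:.3f})"
            )
        return replace(
            self,
            p_lco_given_noaf=new_given_noaf,
            p_lco_given_no_noaf=new_given_no,
            counts=None,
        )


@dataclass(frozen=True)
class LOSModel:
    """Arm base ICU/ward days plus additive per-complication increments."""

    base_icu_days: float
    base_ward_days: float
    icu_increments: Mapping[str, float]
    ward_increments: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.base_icu_days < 0 or self.base_ward_days < 0:
            raise ValidationError("base lengths of stay must be >= 0")
        for m in (self.icu_increments, self.ward_increments):
            for ev, v in m.items():
                if ev not in MODEL_EVENTS:
                    raise ValidationError(f"unknown complication {ev!r} in LOS increments")
                if v < 0:
                    raise ValidationError(f"LOS increment for {ev!r} must be >= 0")

    def days(self, indicators: Mapping[str, bool]) -> tuple[float, float]:
        icu = self.base_icu_days + sum(
            self.icu_increments.get(ev, 0.0) for ev in MODEL_EVENTS if indicators.get(ev)
        )
        ward = self.base_ward_days + sum(
            self.ward_increments.get(ev, 0.0) for ev in MODEL_EVENTS if indicators.get(ev)
        )
        return icu, ward


@dataclass(frozen=True)
class ResourceModel:
    """Per-pathway resource-use profiles, keyed by catalogue codes.

    ``per_patient`` is consumed once on every pathway (surgery, the ICU
    echocardiogram, the pre-discharge ECG); ``per_icu_day`` and
    ``per_ward_day`` scale with the stay (the day bundles include the stay
    item itself); ``complications`` maps each complication to its add-on;
    ``upfront`` maps each arm to its pre-operative admission profile.
    """

    per_patient: ResourceProfile
    per_icu_day: ResourceProfile
    per_ward_day: ResourceProfile
    complications: Mapping[str, ResourceProfile]
    upfront: Mapping[Arm, ResourceProfile]


@dataclass(frozen=True)
class Pathway:
    """One terminal branch of a strategy's tree."""

    arm: Arm
    noaf: bool
    lco: bool
    renal_failure: bool
    prolonged_mv: bool
    probability: float
    cost: float
    icu_days: float
    ward_days: float

    @property
    def complication_free(self) -> bool:
        return not (self.noaf or self.lco or self.renal_failure or self.prolonged_mv)

    @property
    def indicators(self) -> dict[str, bool]:
        return {
            "noaf": self.noaf,
            "lco": self.lco,
            "renal_failure": self.renal_failure,
            "prolonged_mv": self.prolonged_mv,
        }


@dataclass(frozen=True)
class StrategyExpectation:
    expected_cost: float
    mean_icu_days: float
    mean_ward_days: float
    pct_no_complications: float


@dataclass(frozen=True)
class IncrementalResult:
    """Differences between strategies, in the reporting sign convention:

    ``delta_cost`` = control - intervention (positive = the intervention
    saves money); the stay and effect deltas are intervention - control.
    ``dominance`` is true when the intervention is both cheaper and more
    effective; otherwise ``icer`` reports the incremental cost (euros) per
    additional complication-free patient.
    """

    delta_cost: float
    delta_icu: float
    delta_ward: float
    delta_effect: float
    dominance: bool
    icer: float | None = None


def estimate_probabilities(records: Sequence[PatientRecord]) -> dict[Arm, EventProbabilities]:
    """Empirical conditional probabilities per arm from per-patient flags.

    Conditionals with an empty conditioning set fall back to the arm
    marginal of the event, with a warning.
    """
    out: dict[Arm, EventProbabilities] = {}
    for arm in Arm:
        sub = [r for r in records if r.arm is arm]
        if not sub:
            raise EstimationError(f"no records in arm {arm.value!r}")
        n = len(sub)

        def frac(event: str, condition) -> tuple[float, float, float]:
            pool = [r for r in sub if condition(r)]
            if not pool:
                marg = sum(getattr(r, event) for r in sub) / n
                warnings.warn(
                    f"{arm.value}: empty conditioning set for {event}; "
                    f"falling back to the arm marginal {marg:.3f}",
                    stacklevel=2,
                )
                return marg, marg * n, n
            k = sum(bool(getattr(r, event)) for r in pool)
            return k / len(pool), float(k), float(len(pool))

        values: dict[str, float] = {}
        counts: dict[str, tuple[float, float]] = {}
        spec = {
            "p_noaf": ("noaf", lambda r: True),
            "p_lco_given_noaf": ("lco", lambda r: r.noaf),
            "p_lco_given_no_noaf": ("lco", lambda r: not r.noaf),
            "p_rf_given_lco": ("renal_failure", lambda r: r.lco),
            "p_rf_given_no_lco": ("renal_failure", lambda r: not r.lco),
            "p_mv_given_lco": ("prolonged_mv", lambda r: r.lco),
            "p_mv_given_no_lco": ("prolonged_mv", lambda r: not r.lco),
        }
        for name, (event, cond) in spec.items():
            p, k, m = frac(event, cond)
            values[name] = p
            counts[name] = (k, m)
        out[arm] = EventProbabilities(counts=counts, **values)
    return out


def build_tree(
    probs: EventProbabilities,
    los: LOSModel,
    catalogue: CostCatalogue,
    resources: ResourceModel,
    arm: Arm,
) -> list[Pathway]:
    """Enumerate the 16 terminal pathways of one strategy."""
    fixed = pathway_cost(resources.per_patient, catalogue).total
    upfront = resources.upfront.get(arm)
    if upfront is not None:
        fixed += pathway_cost(upfront, catalogue).total
    icu_rate = pathway_cost(resources.per_icu_day, catalogue).total
    ward_rate = pathway_cost(resources.per_ward_day, catalogue).total
    addon = {
        ev: pathway_cost(profile, catalogue).total
        for ev, profile in resources.complications.items()
    }

    pathways: list[Pathway] = []
    for noaf, lco, rf, mv in itertools.product((False, True), repeat=4):
        p = probs.p_noaf if noaf else 1 - probs.p_noaf
        p_lco = probs.p_lco_given_noaf if noaf else probs.p_lco_given_no_noaf
        p *= p_lco if lco else 1 - p_lco
        p_rf = probs.p_rf_given_lco if lco else probs.p_rf_given_no_lco
        p *= p_rf if rf else 1 - p_rf
        p_mv = probs.p_mv_given_lco if lco else probs.p_mv_given_no_lco
        p *= p_mv if mv else 1 - p_mv
        indicators = {"noaf": noaf, "lco": lco, "renal_failure": rf, "prolonged_mv": mv}
        icu_days, ward_days = los.days(indicators)
        cost = fixed + icu_days * icu_rate + ward_days * ward_rate
        for ev, present in indicators.items():
            if present:
                cost += addon.get(ev, 0.0)
        pathways.append(
            Pathway(
                arm=arm,
                noaf=noaf,
                lco=lco,
                renal_failure=rf,
                prolonged_mv=mv,
                probability=p,
                cost=cost,
                icu_days=icu_days,
                ward_days=ward_days,
            )
        )
    return pathways


def rollback(pathways: Sequence[Pathway]) -> StrategyExpectation:
    """Probability-weighted expectations over one strategy's pathways."""
    total_p = sum(pw.probability for pw in pathways)
    if abs(total_p - 1.0) > 1e-9:
        raise ConservationError(f"pathway probabilities sum to {total_p!r}, not 1")
    cost = sum(pw.probability * pw.cost for pw in pathways)
    icu = sum(pw.probability * pw.icu_days for pw in pathways)
    ward = sum(pw.probability * pw.ward_days for pw in pathways)
    eff = 100.0 * sum(pw.probability for pw in pathways if pw.complication_free)
    return StrategyExpectation(
        expected_cost=cost,
        mean_icu_days=icu,
        mean_ward_days=ward,
        pct_no_complications=eff,
    )


def incremental(
    intervention: StrategyExpectation, control: StrategyExpectation
) -> IncrementalResult:
    """Componentwise strategy differences, dominance flag and (if needed) ICER."""
    delta_cost = control.expected_cost - intervention.expected_cost
    delta_effect = intervention.pct_no_complications - control.pct_no_complications
    dominance = delta_cost > 0 and delta_effect > 0
    icer = None
    if not dominance and delta_effect != 0.0:
        # euros per additional complication-free patient
        icer = (intervention.expected_cost - control.expected_cost) / (delta_effect / 100.0)
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_icu=intervention.mean_icu_days - control.mean_icu_days,
        delta_ward=intervention.mean_ward_days - control.mean_ward_days,
        delta_effect=delta_effect,
        dominance=dominance,
        icer=icer,
    )
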