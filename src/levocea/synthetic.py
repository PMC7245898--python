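"""Synthetic cohorts and the reconstructed 54-patient study cohort.

``generate_cohort`` draws independent patients under the same conditional
chain the decision tree assumes (NOAF -> LCO -> {renal failure, prolonged
MV, shock} | LCO) with log-normal lengths of stay per (arm,
complication-free) cell, so every pipeline stage can be exercised at any
sample size without external data.

``study_cohort`` returns a deterministic 54-record cohort (13 intervention,
41 control) whose margins reproduce every published count of the source
evaluation: per-arm complication counts, LVEF-stratified LCO counts,
complication-free totals, and length-of-stay medians/IQRs (SPSS-style
(n+1)-position percentiles). The joint structure -- which patients share
which complications -- is NOT published; the packaged assignment is one
documented solution of that constraint system (synthetic reconstruction),
chosen so that shock nests inside LCO, deaths nest inside shock, and
sicker patients stay longer. Conditionals estimated from it are
calibration artifacts, not published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import Arm, LvefStratum, PatientRecord
from .exceptions import ValidationError
from .model import EventProbabilities

# --------------------------------------------------------------------------
# generator


@dataclass(frozen=True)
class LOSCell:
    """Log-normal length-of-stay distribution for one (arm, outcome) cell."""

    icu_median: float
    icu_sigma: float
    ward_median: float
    ward_sigma: float

    def __post_init__(self) -> None:
        if min(self.icu_median, self.ward_median) <= 0:
            raise ValidationError("LOS medians must be > 0")
        if min(self.icu_sigma, self.ward_sigma) <= 0:
            raise ValidationError("LOS sigmas must be > 0")


@dataclass(frozen=True)
class ArmGenParams:
    n: int
    probabilities: EventProbabilities
    p_shock_given_lco: float
    p_death_given_shock: float
    p_lvef_lt_35: float
    los_complication_free: LOSCell
    los_complicated: LOSCell

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("arm size must be >= 1")
        for name in ("p_shock_given_lco", "p_death_given_shock", "p_lvef_lt_35"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class CohortGenParams:
    arms: Mapping[Arm, ArmGenParams]
    seed: int = 0

    @classmethod
    def study_defaults(cls, seed: int = 0, n_scale: float = 1.0) -> "CohortGenParams":
        """Generating parameters matching the study conditions.

        Event conditionals are the empirical conditionals of the
        reconstructed study cohort; arm sizes are the study's 13 vs 41
        (scalable via ``n_scale`` for convergence experiments); LOS cells
        approximate the published medians.
        """
        intervention = ArmGenParams(
            n=max(1, round(13 * n_scale)),
            probabilities=EventProbabilities(
                p_noaf=2 / 13,
                p_lco_given_noaf=0.0,
                p_lco_given_no_noaf=2 / 11,
                p_rf_given_lco=0.0,
                p_rf_given_no_lco=1 / 11,
                p_mv_given_lco=0.0,
                p_mv_given_no_lco=1 / 11,
            ),
            p_shock_given_lco=0.0,
            p_death_given_shock=0.0,
            p_lvef_lt_35=8 / 13,
            los_complication_free=LOSCell(1.5, 0.45, 5.0, 0.30),
            los_complicated=LOSCell(4.0, 0.40, 8.0, 0.35),
        )
        control = ArmGenParams(
            n=max(1, round(41 * n_scale)),
            probabilities=EventProbabilities(
                p_noaf=9 / 41,
                p_lco_given_noaf=7 / 9,
                p_lco_given_no_noaf=18 / 32,
                p_rf_given_lco=9 / 25,
                p_rf_given_no_lco=1 / 16,
                p_mv_given_lco=8 / 25,
                p_mv_given_no_lco=1 / 16,
            ),
            p_shock_given_lco=10 / 25,
            p_death_given_shock=5 / 10,
            p_lvef_lt_35=8 / 41,
            los_complication_free=LOSCell(3.0, 0.30, 4.5, 0.30),
            los_complicated=LOSCell(6.0, 0.50, 8.0, 0.50),
        )
        return cls(arms={Arm.INTERVENTION: intervention, Arm.CONTROL: control}, seed=seed)


def generate_cohort(
    params: CohortGenParams, rng: np.random.Generator | None = None
) -> list[PatientRecord]:
    """Draw a synthetic per-patient cohort; reproducible via ``params.seed``."""
    rng = rng or np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    for arm in Arm:
        ap = params.arms[arm]
        p = ap.probabilities
        for i in range(ap.n):
            noaf = rng.random() < p.p_noaf
            p_lco = p.p_lco_given_noaf if noaf else p.p_lco_given_no_noaf
            lco = rng.random() < p_lco
            p_rf = p.p_rf_given_lco if lco else p.p_rf_given_no_lco
            rf = rng.random() < p_rf
            p_mv = p.p_mv_given_lco if lco else p.p_mv_given_no_lco
            mv = rng.random() < p_mv
            shock = lco and rng.random() < ap.p_shock_given_lco
            death = shock and rng.random() < ap.p_death_given_shock
            cell = ap.los_complication_free if not (noaf or lco or rf or mv) else ap.los_complicated
            icu = float(rng.lognormal(np.log(cell.icu_median), cell.icu_sigma))
            ward = 0.0 if death else float(rng.lognormal(np.log(cell.ward_median), cell.ward_sigma))
            stratum = (
                LvefStratum.LVEF_LT_35
                if rng.random() < ap.p_lvef_lt_35
                else LvefStratum.LVEF_35_40
            )
            records.append(
                PatientRecord(
                    id=f"{arm.value[:3]}-{i + 1:05d}",
                    arm=arm,
                    lvef_stratum=stratum,
                    noaf=noaf,
                    lco=lco,
                    cardiogenic_shock=shock,
                    renal_failure=rf,
                    prolonged_mv=mv,
                    death=death,
                    icu_los=round(icu, 1),
                    ward_los=round(ward, 1),
                )
            )
    return records


# --------------------------------------------------------------------------
# reconstructed study cohort

# (id, stratum, events, icu_days, ward_days); events is a compact token set.
# I = intervention, C = control; "40" = LVEF 35-40%, "35" = LVEF < 35%.
_N, _L, _S, _R, _M, _D = "noaf", "lco", "shock", "rf", "mv", "death"
_STUDY_TABLE: tuple[tuple[str, str, str, tuple[str, ...], float, float], ...] = (
    # --- intervention arm (n = 13): 6 complication slots on 6 patients ---
    ("int-01", "I", "40", (_N,), 3, 7),
    ("int-02", "I", "40", (_R,), 4, 8),
    ("int-03", "I", "40", (_M,), 4, 8),
    ("int-04", "I", "40", (), 1, 4),
    ("int-05", "I", "40", (), 1, 4),
    ("int-06", "I", "35", (_N,), 2, 6),
    ("int-07", "I", "35", (_L,), 5, 13),
    ("int-08", "I", "35", (_L,), 5, 10),
    ("int-09", "I", "35", (), 1, 3),
    ("int-10", "I", "35", (), 1, 4),
    ("int-11", "I", "35", (), 2, 5),
    ("int-12", "I", "35", (), 2, 6),
    ("int-13", "I", "35", (), 2, 6),
    # --- control arm (n = 41): 25 LCO, 3 complicated without LCO, 13 clean ---
    ("ctl-01", "C", "40", (_L, _N, _R, _M, _S, _D), 18, 0),
    ("ctl-02", "C", "40", (_L, _N, _R, _M, _S, _D), 16, 0),
    ("ctl-03", "C", "40", (_L, _N, _M, _S, _D), 15, 0),
    ("ctl-04", "C", "40", (_L, _N), 6, 9),
    ("ctl-05", "C", "40", (_L, _N), 6, 9),
    ("ctl-06", "C", "40", (_L, _N), 6, 9),
    ("ctl-07", "C", "40", (_L, _R, _M, _S, _D), 14, 0),
    ("ctl-08", "C", "40", (_L, _R, _M, _S, _D), 12, 0),
    ("ctl-09", "C", "40", (_L, _R, _S), 10, 17),
    ("ctl-10", "C", "40", (_L, _R), 5, 9),
    ("ctl-11", "C", "40", (_L, _R), 5, 9),
    ("ctl-12", "C", "40", (_L, _M, _S), 9, 15),
    ("ctl-13", "C", "40", (_L, _S), 8, 14),
    ("ctl-14", "C", "40", (_L,), 4, 8),
    ("ctl-15", "C", "40", (_L,), 4, 7),
    ("ctl-16", "C", "40", (_L,), 4, 7),
    ("ctl-17", "C", "40", (_L,), 4, 6),
    ("ctl-18", "C", "40", (_L,), 4, 6),
    ("ctl-19", "C", "40", (_L,), 4, 5),
    ("ctl-20", "C", "40", (_L,), 4, 5),
    ("ctl-21", "C", "35", (_L, _N, _M, _S), 7, 13),
    ("ctl-22", "C", "35", (_L, _R), 5, 11),
    ("ctl-23", "C", "35", (_L, _R), 5, 10),
    ("ctl-24", "C", "35", (_L, _M), 4, 9),
    ("ctl-25", "C", "35", (_L, _S), 6, 12),
    ("ctl-26", "C", "40", (_N,), 4, 5),
    ("ctl-27", "C", "40", (_N,), 4, 5),
    ("ctl-28", "C", "40", (_R, _M), 4, 8),
    ("ctl-29", "C", "40", (), 4, 5),
    ("ctl-30", "C", "40", (), 3, 5),
    ("ctl-31", "C", "40", (), 3, 5),
    ("ctl-32", "C", "40", (), 3, 5),
    ("ctl-33", "C", "40", (), 3, 5),
    ("ctl-34", "C", "40", (), 3, 4),
    ("ctl-35", "C", "40", (), 3, 4),
    ("ctl-36", "C", "40", (), 3, 4),
    ("ctl-37", "C", "40", (), 3, 4),
    ("ctl-38", "C", "40", (), 3, 4),
    ("ctl-39", "C", "35", (), 2, 3),
    ("ctl-40", "C", "35", (), 2, 3),
    ("ctl-41", "C", "35", (), 2, 3),
)


@dataclass(frozen=True)
class FixtureCohort:
    records: tuple[PatientRecord, ...]
    provenance: str = field(
        default=(
            "Synthetic reconstruction: one solution of the published marginal "
            "constraint system (arm sizes, complication counts, LVEF-stratified "
            "LCO, complication-free totals, LOS medians/IQRs). The joint event "
            "assignment is not published data."
        ),
        compare=False,
    )


def study_cohort() -> FixtureCohort:
    """The deterministic 54-patient reconstructed study cohort."""
    records = []
    for pid, arm_code, stratum_code, events, icu, ward in _STUDY_TABLE:
        records.append(
            PatientRecord(
                id=pid,
                arm=Arm.INTERVENTION if arm_code == "I" else Arm.CONTROL,
                lvef_stratum=(
                    LvefStratum.LVEF_35_40 if stratum_code == "40" else LvefStratum.LVEF_LT_35
                ),
                noaf=_N in events,
                lco=_L in events,
                cardiogenic_shock=_S in events,
                renal_failure=_R in events,
                prolonged_mv=_M in events,
                death=_D in events,
                icu_los=float(icu),
                ward_los=float(ward),
            )
        )
    return FixtureCohort(records=tuple(records))


# --------------------------------------------------------------------------
# fixture validation


@dataclass(frozen=True)
class ConstraintCheck:
    name: str
    passed: bool
    detail: str


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and IQR with (n+1)-position percentiles (SPSS convention)."""
    q1, med, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75], method="weibull")
    return float(med), float(q1), float(q3)


def validate_study_cohort(cohort: FixtureCohort) -> list[ConstraintCheck]:
    """Check every published-margin constraint; returns one line per check."""
    recs = cohort.records
    inter = [r for r in recs if r.arm is Arm.INTERVENTION]
    ctl = [r for r in recs if r.arm is Arm.CONTROL]
    checks: list[ConstraintCheck] = []

    def check(name: str, observed, expected) -> None:
        checks.append(
            ConstraintCheck(
                name=name,
                passed=observed == expected,
                detail=f"observed {observed}, expected {expected}",
            )
        )

    check("arm sizes", (len(inter), len(ctl)), (13, 41))

    def counts(event: str) -> tuple[int, int]:
        return (
            sum(bool(getattr(r, event)) for r in inter),
            sum(bool(getattr(r, event)) for r in ctl),
        )

    check("new-onset atrial fibrillation", counts("noaf"), (2, 9))
    check("low cardiac output", counts("lco"), (2, 25))
    check("cardiogenic shock", counts("cardiogenic_shock"), (0, 10))
    check("renal failure", counts("renal_failure"), (1, 10))
    check("prolonged mechanical ventilation", counts("prolonged_mv"), (1, 9))
    check("deaths", counts("death"), (0, 5))
    check(
        "shock nested in LCO",
        sum(1 for r in recs if r.cardiogenic_shock and not r.lco),
        0,
    )
    check(
        "deaths nested in shock",
        sum(1 for r in recs if r.death and not r.cardiogenic_shock),
        0,
    )

    def stratum_lco(rows, stratum: LvefStratum) -> tuple[int, int]:
        sub = [r for r in rows if r.lvef_stratum is stratum]
        return (sum(r.lco for r in sub), len(sub))

    check("LVEF 35-40% LCO intervention", stratum_lco(inter, LvefStratum.LVEF_35_40), (0, 5))
    check("LVEF 35-40% LCO control", stratum_lco(ctl, LvefStratum.LVEF_35_40), (20, 33))
    check("LVEF <35% LCO intervention", stratum_lco(inter, LvefStratum.LVEF_LT_35), (2, 8))
    check("LVEF <35% LCO control", stratum_lco(ctl, LvefStratum.LVEF_LT_35), (5, 8))

    check(
        "complication-free intervention",
        (sum(r.complication_free for r in inter), len(inter)),
        (7, 13),
    )
    check(
        "complication-free control",
        (sum(r.complication_free for r in ctl), len(ctl)),
        (13, 41),
    )

    check("ICU LOS intervention median (IQR)", _quartiles([r.icu_los for r in inter]), (2.0, 1.0, 4.0))
    check("ICU LOS control median (IQR)", _quartiles([r.icu_los for r in ctl]), (4.0, 3.0, 6.0))
    check("ward LOS intervention median (IQR)", _quartiles([r.ward_los for r in inter]), (6.0, 4.0, 8.0))
    check("ward LOS control median (IQR)", _quartiles([r.ward_los for r in ctl]), (5.0, 4.0, 9.0))
    return checks
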