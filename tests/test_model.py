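"""Decision tree: pathway enumeration, roll-back and incremental results."""

import dataclasses
import itertools

import numpy as np
import pytest

import levocea as lv
from levocea.cohort import Arm
from levocea.exceptions import ConservationError, EstimationError, ValidationError
from levocea.model import MODEL_EVENTS, PROBABILITY_PARAMS


def random_probs(rng):
    return lv.EventProbabilities(
        **{name: float(rng.uniform(0, 1)) for name in PROBABILITY_PARAMS}
    )


def oracle_expectation(probs, los, catalogue, resources, arm):
    """Independent enumeration of the strategy expectation.

    Recomputes pathway probabilities, stays and costs with its own
    arithmetic (explicit branch conditioning, costs as raw quantity sums)
    rather than through build_tree/rollback.
    """

    def profile_total(profile):
        return sum(q * catalogue.cost(code) for code, q in profile.quantities.items())

    e_cost = e_icu = e_ward = p_free = 0.0
    for noaf in (0, 1):
        p_n = probs.p_noaf if noaf else 1 - probs.p_noaf
        for lco in (0, 1):
            pl = probs.p_lco_given_noaf if noaf else probs.p_lco_given_no_noaf
            p_nl = p_n * (pl if lco else 1 - pl)
            for rf in (0, 1):
                pr = probs.p_rf_given_lco if lco else probs.p_rf_given_no_lco
                p_nlr = p_nl * (pr if rf else 1 - pr)
                for mv in (0, 1):
                    pm = probs.p_mv_given_lco if lco else probs.p_mv_given_no_lco
                    p = p_nlr * (pm if mv else 1 - pm)
                    present = dict(
                        zip(MODEL_EVENTS, (noaf, lco, rf, mv))
                    )
                    icu = los.base_icu_days + sum(
                        los.icu_increments[e] for e in MODEL_EVENTS if present[e]
                    )
                    ward = los.base_ward_days + sum(
                        los.ward_increments[e] for e in MODEL_EVENTS if present[e]
                    )
                    cost = (
                        profile_total(resources.per_patient)
                        + profile_total(resources.upfront[arm])
                        + icu * profile_total(resources.per_icu_day)
                        + ward * profile_total(resources.per_ward_day)
                        + sum(
                            profile_total(resources.complications[e])
                            for e in MODEL_EVENTS
                            if present[e]
                        )
                    )
                    e_cost += p * cost
                    e_icu += p * icu
                    e_ward += p * ward
                    if not any(present.values()):
                        p_free += p
    return e_cost, e_icu, e_ward, 100.0 * p_free


class TestEstimateProbabilities:
    def test_study_cohort_marginals(self, study_records):
        probs = lv.estimate_probabilities(study_records)
        assert probs[Arm.INTERVENTION].p_noaf == pytest.approx(2 / 13)
        assert probs[Arm.INTERVENTION].marginal_lco == pytest.approx(2 / 13)
        assert probs[Arm.CONTROL].marginal_lco == pytest.approx(25 / 41)
        assert probs[Arm.CONTROL].marginal_rf == pytest.approx(10 / 41)
        assert probs[Arm.CONTROL].marginal_mv == pytest.approx(9 / 41)

    def test_all_flags_false_gives_zero_probabilities(self, study_records):
        quiet = [
            dataclasses.replace(
                r, noaf=False, lco=False, cardiogenic_shock=False,
                renal_failure=False, prolonged_mv=False, death=False,
            )
            for r in study_records
        ]
        with pytest.warns(UserWarning):  # empty LCO conditioning sets
            probs = lv.estimate_probabilities(quiet)
        for arm in Arm:
            for name in PROBABILITY_PARAMS:
                assert getattr(probs[arm], name) == 0.0

    def test_empty_arm_rejected(self, study_records):
        only_control = [r for r in study_records if r.arm is Arm.CONTROL]
        with pytest.raises(EstimationError):
            lv.estimate_probabilities(only_control)


class TestBuildTree:
    def test_sixteen_pathways_summing_to_one(self, config):
        for arm in Arm:
            spec = config.arm(arm)
            paths = lv.build_tree(
                spec.probabilities, spec.los, config.catalogue, config.resources, arm
            )
            assert len(paths) == 16
            assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-12)

    def test_zero_probabilities_single_live_pathway(self, config):
        probs = lv.EventProbabilities(**{n: 0.0 for n in PROBABILITY_PARAMS})
        spec = config.arm(Arm.CONTROL)
        paths = lv.build_tree(probs, spec.los, config.catalogue, config.resources, Arm.CONTROL)
        live = [p for p in paths if p.probability > 0]
        assert len(live) == 1
        assert live[0].complication_free
        assert live[0].probability == 1.0

    def test_complication_free_closed_form(self, config):
        spec = config.arm(Arm.INTERVENTION)
        paths = lv.build_tree(
            spec.probabilities, spec.los, config.catalogue, config.resources, Arm.INTERVENTION
        )
        free = sum(p.probability for p in paths if p.complication_free)
        assert free == pytest.approx(spec.probabilities.p_complication_free, abs=1e-12)

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            lv.EventProbabilities(1.2, 0, 0, 0, 0, 0, 0)


class TestRollback:
    def test_degenerate_single_pathway(self, config):
        path = lv.Pathway(
            arm=Arm.CONTROL, noaf=False, lco=False, renal_failure=False,
            prolonged_mv=False, probability=1.0, cost=1234.5, icu_days=2.0, ward_days=5.0,
        )
        exp = lv.rollback([path])
        assert exp.expected_cost == 1234.5
        assert exp.pct_no_complications == 100.0

    def test_linearity_of_expectation(self):
        mk = lambda p, cost: lv.Pathway(
            arm=Arm.CONTROL, noaf=False, lco=False, renal_failure=False,
            prolonged_mv=False, probability=p, cost=cost, icu_days=0.0, ward_days=0.0,
        )
        exp = lv.rollback([mk(0.5, 0.0), mk(0.5, 100.0)])
        assert exp.expected_cost == pytest.approx(50.0)

    def test_probability_leak_rejected(self, config):
        spec = config.arm(Arm.CONTROL)
        paths = lv.build_tree(
            spec.probabilities, spec.los, config.catalogue, config.resources, Arm.CONTROL
        )
        with pytest.raises(ConservationError):
            lv.rollback(paths[:-1])

    def test_oracle_equivalence_over_random_draws(self, config):
        """Roll-back equals exhaustive enumeration for 1,000 random parameter sets."""
        rng = np.random.default_rng(42)
        spec = config.arm(Arm.INTERVENTION)
        for _ in range(1000):
            probs = random_probs(rng)
            los = lv.LOSModel(
                base_icu_days=float(rng.uniform(0, 5)),
                base_ward_days=float(rng.uniform(0, 8)),
                icu_increments={e: float(rng.uniform(0, 4)) for e in MODEL_EVENTS},
                ward_increments={e: float(rng.uniform(0, 4)) for e in MODEL_EVENTS},
            )
            cat = config.catalogue.replace(icu_day=float(rng.uniform(500, 2000)))
            exp = lv.rollback(
                lv.build_tree(probs, los, cat, config.resources, Arm.INTERVENTION)
            )
            o_cost, o_icu, o_ward, o_free = oracle_expectation(
                probs, los, cat, config.resources, Arm.INTERVENTION
            )
            assert exp.expected_cost == pytest.approx(o_cost, abs=1e-9, rel=1e-12)
            assert exp.mean_icu_days == pytest.approx(o_icu, abs=1e-9)
            assert exp.mean_ward_days == pytest.approx(o_ward, abs=1e-9)
            assert exp.pct_no_complications == pytest.approx(o_free, abs=1e-9)

    def test_expected_cost_monotone_in_lco(self, config):
        """Raising the LCO marginal never lowers expected cost."""
        spec = config.arm(Arm.CONTROL)
        costs = []
        for target in (0.2, 0.4, 0.6, 0.7):
            probs = spec.probabilities.with_lco_marginal(target)
            exp = lv.rollback(
                lv.build_tree(probs, spec.los, config.catalogue, config.resources, Arm.CONTROL)
            )
            costs.append(exp.expected_cost)
        assert costs == sorted(costs)

    def test_expected_cost_linear_in_unit_cost(self, config):
        """Finite differences in one unit cost are constant (linearity)."""
        spec = config.arm(Arm.CONTROL)

        def cost_at(icu_price):
            cat = config.catalogue.replace(icu_day=icu_price)
            return lv.rollback(
                lv.build_tree(spec.probabilities, spec.los, cat, config.resources, Arm.CONTROL)
            ).expected_cost

        d1 = cost_at(1300.0) - cost_at(1200.0)
        d2 = cost_at(1500.0) - cost_at(1400.0)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestIncremental:
    def test_identical_strategies(self):
        e = lv.StrategyExpectation(1000.0, 2.0, 5.0, 50.0)
        res = lv.incremental(e, e)
        assert res.delta_cost == 0.0 and res.delta_effect == 0.0
        assert not res.dominance

    def test_arithmetic_difference(self):
        intervention = lv.StrategyExpectation(14792.33, 2.50, 6.46, 53.85)
        control = lv.StrategyExpectation(17006.94, 5.70, 6.40, 31.71)
        res = lv.incremental(intervention, control)
        assert res.delta_cost == pytest.approx(2214.61)
        assert res.delta_icu == pytest.approx(-3.20)
        assert res.delta_ward == pytest.approx(0.06)
        assert res.delta_effect == pytest.approx(22.14)
        assert res.dominance

    def test_cheaper_but_less_effective_reports_icer(self):
        intervention = lv.StrategyExpectation(9000.0, 2.0, 5.0, 30.0)
        control = lv.StrategyExpectation(10000.0, 3.0, 5.0, 40.0)
        res = lv.incremental(intervention, control)
        assert not res.dominance
        # saves 1000 EUR but loses 10 points: ICER = -1000 / -0.10
        assert res.icer == pytest.approx(10000.0)
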