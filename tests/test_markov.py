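import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    EconConfig,
    MarkovArm,
    ProgramCosts,
    annual_death_prob,
    closed_form_dly,
    compare_arms,
    icer,
    nmb,
    run_arm,
)
from markovcea.markov import MarkovTrace

from conftest import constant_table


# --------------------------------------------------------------------------
# Independent brute-force oracle: a plain per-person-state bookkeeping loop
# written from the model definition, sharing no code with run_arm.
# --------------------------------------------------------------------------
def brute_force_arm(arm, econ, life_table):
    """Per-cycle dict-based loop; returns (total QALYs, total costs)."""
    total_q = 0.0
    total_c = arm.program.one_off_per_patient
    for sex, w in (("F", econ.sex_mix), ("M", 1.0 - econ.sex_mix)):
        if w == 0.0:
            continue
        state = {"b": econ.start_state, "d": 1.0 - econ.start_state, "z": 0.0}
        for t in range(1, econ.horizon + 1):
            age = econ.start_age + t - 1
            qx = life_table.qx(age, sex)
            die_b = 1.0 - (1.0 - qx) ** arm.rr_baseline
            die_d = 1.0 - (1.0 - qx) ** arm.rr_deteriorated
            new_b = state["b"] * (1 - die_b) * (1 - arm.incidence) \
                + state["d"] * (1 - die_d) * arm.recovery
            new_d = state["b"] * (1 - die_b) * arm.incidence \
                + state["d"] * (1 - die_d) * (1 - arm.recovery)
            new_z = state["z"] + state["b"] * die_b + state["d"] * die_d
            state = {"b": new_b, "d": new_d, "z": new_z}
            ve = (1 + econ.discount_effects) ** (-t)
            vc = (1 + econ.discount_costs) ** (-t)
            total_q += w * ve * (state["b"] * arm.utility_baseline
                                 + state["d"] * arm.utility_deteriorated)
            total_c += w * vc * (state["b"] * arm.cost_baseline
                                 + state["d"] * arm.cost_deteriorated
                                 + (state["b"] + state["d"])
                                 * arm.program.recurring_per_patient_year)
    return total_q, total_c


def _random_arm(rng, name="arm"):
    return MarkovArm(
        name=name,
        incidence=rng.uniform(0, 1),
        recovery=rng.uniform(0, 1),
        utility_baseline=rng.uniform(0, 1),
        utility_deteriorated=rng.uniform(0, 1),
        cost_baseline=rng.uniform(0, 10_000),
        cost_deteriorated=rng.uniform(0, 10_000),
        rr_baseline=rng.uniform(0.5, 3.0),
        rr_deteriorated=rng.uniform(0.5, 3.0),
        program=ProgramCosts(rng.uniform(0, 2000), rng.uniform(0, 500)),
    )


def _random_econ(rng):
    return EconConfig(
        discount_effects=rng.uniform(0, 0.08),
        discount_costs=rng.uniform(0, 0.08),
        horizon=int(rng.integers(1, 60)),
        start_age=int(rng.integers(60, 100)),
        sex_mix=rng.uniform(0, 1),
        start_state=rng.uniform(0, 1),
    )


class TestDeathProb:
    def test_rr_one_is_identity(self, packaged_table):
        for age in (60, 84, 100):
            assert annual_death_prob(age, "F", packaged_table, 1.0) == \
                packaged_table.qx(age, "F")

    def test_hazard_scaling_hand_value(self):
        lt = constant_table(0.1)
        assert annual_death_prob(70, "M", lt, 2.0) == pytest.approx(0.19)

    def test_certain_death_absorbing_cap(self):
        lt = constant_table(1.0)
        for rr in (0.1, 1.0, 7.0):
            assert annual_death_prob(70, "F", lt, rr) == 1.0

    def test_nonpositive_rr_rejected(self, packaged_table):
        with pytest.raises(ValueError):
            annual_death_prob(70, "F", packaged_table, 0.0)


class TestRunArm:
    def test_immortal_cohort_conserves_everything(self):
        """No mortality, no incidence, utility 1, no discounting: QALYs equal
        the horizon and occupancy never moves."""
        lt = constant_table(0.0)
        arm = MarkovArm("a", incidence=0.0, recovery=0.5, utility_baseline=1.0,
                        utility_deteriorated=1.0, cost_baseline=0.0, cost_deteriorated=0.0,
                        rr_baseline=1.0, rr_deteriorated=1.0)
        econ = EconConfig(discount_effects=0.0, discount_costs=0.0, horizon=10,
                          start_age=70)
        trace = run_arm(arm, econ, lt)
        assert trace.total_qalys == pytest.approx(10.0, abs=1e-12)
        occ = trace.trace[["baseline", "deteriorated", "dead"]].to_numpy()
        assert np.allclose(occ, np.tile([1.0, 0.0, 0.0], (11, 1)))

    def test_constant_survival_matches_closed_form(self):
        """With constant qx and no stage dynamics, discounted life-years
        follow the geometric closed form."""
        lt = constant_table(0.1)
        arm = MarkovArm("a", incidence=0.0, recovery=0.0, utility_baseline=1.0,
                        utility_deteriorated=1.0, cost_baseline=0.0,
                        cost_deteriorated=0.0, rr_baseline=1.0, rr_deteriorated=1.0)
        econ = EconConfig(discount_effects=0.03, discount_costs=0.03, horizon=40,
                          start_age=60)
        trace = run_arm(arm, econ, lt)
        expected = closed_form_dly(0.9, 0.03, 40)
        assert trace.life_years == pytest.approx(expected, abs=1e-10)
        assert trace.total_qalys == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_on_randomized_parameters(self, packaged_table):
        """run_arm agrees with the independent bookkeeping loop to 1e-10 on
        100 random parameter sets."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            arm = _random_arm(rng)
            econ = _random_econ(rng)
            trace = run_arm(arm, econ, packaged_table)
            q, c = brute_force_arm(arm, econ, packaged_table)
            assert trace.total_qalys == pytest.approx(q, abs=1e-10 * max(1, abs(q)))
            assert trace.total_costs == pytest.approx(c, abs=1e-10 * max(1, abs(c)))

    @settings(max_examples=40, deadline=None)
    @given(
        incidence=st.floats(0, 1),
        recovery=st.floats(0, 1),
        rr=st.floats(0.2, 4.0),
        start_state=st.floats(0, 1),
        horizon=st.integers(1, 50),
    )
    def test_occupancy_conservation_and_absorbing_death(
        self, packaged_table, incidence, recovery, rr, start_state, horizon
    ):
        arm = MarkovArm("a", incidence=incidence, recovery=recovery,
                        utility_baseline=0.5, utility_deteriorated=0.3,
                        cost_baseline=100.0, cost_deteriorated=100.0,
                        rr_baseline=rr, rr_deteriorated=rr)
        econ = EconConfig(horizon=horizon, start_age=80, start_state=start_state)
        occ = run_arm(arm, econ, packaged_table).trace
        sums = occ[["baseline", "deteriorated", "dead"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (occ[["baseline", "deteriorated", "dead"]] >= -1e-15).all().all()
        assert (np.diff(occ["dead"]) >= -1e-15).all()

    def test_start_age_beyond_table_rejected(self, packaged_table):
        arm = MarkovArm("a", 0.3, 0.7, 0.5, 0.3, 0.0, 0.0)
        with pytest.raises(ValueError, match="start_age"):
            run_arm(arm, EconConfig(start_age=120), packaged_table)

    def test_monotonicity(self, packaged_table):
        base_arm = MarkovArm("a", 0.34, 0.66, 0.56, 0.30, 5000.0, 4500.0,
                             program=ProgramCosts(1000.0, 200.0))
        base = run_arm(base_arm, EconConfig(), packaged_table)
        # higher discount never increases totals
        hi_disc = run_arm(base_arm, EconConfig(discount_effects=0.06,
                                               discount_costs=0.06), packaged_table)
        assert hi_disc.total_qalys <= base.total_qalys
        assert hi_disc.total_costs <= base.total_costs
        # higher utility never decreases QALYs
        hi_u = run_arm(base_arm.replace(utility_deteriorated=0.5),
                       EconConfig(), packaged_table)
        assert hi_u.total_qalys >= base.total_qalys
        # higher mortality risk never increases life-years
        hi_rr = run_arm(base_arm.replace(rr_baseline=2.0, rr_deteriorated=2.0),
                        EconConfig(), packaged_table)
        assert hi_rr.life_years <= base.life_years

    def test_half_cycle_correction_brackets_end_of_cycle(self, packaged_table):
        arm = MarkovArm("a", 0.34, 0.66, 0.56, 0.30, 0.0, 0.0)
        end = run_arm(arm, EconConfig(), packaged_table)
        half = run_arm(arm, EconConfig(half_cycle_correction=True), packaged_table)
        # with declining survival, crediting mid-cycle occupancy adds QALYs
        assert half.total_qalys > end.total_qalys


class TestIncremental:
    def _trace(self, q, c):
        return MarkovTrace(arm="x", trace=None, total_qalys=q, total_costs=c,
                           life_years=q)

    def test_identical_arms_undefined_icer(self):
        r = compare_arms(self._trace(2.0, 100.0), self._trace(2.0, 100.0))
        assert r.delta_cost == 0 and r.delta_effect == 0
        assert r.icer is None and r.dominance == "undefined"
        assert r.nmb == 0.0

    def test_published_deltas_give_published_ratio(self):
        r = compare_arms(self._trace(10.731, 14755.0), self._trace(10.0, 10000.0))
        assert r.icer == pytest.approx(4755.0 / 0.731)
        assert r.icer == pytest.approx(6504.79, abs=0.01)

    def test_quadrant_classification(self):
        dominated = compare_arms(self._trace(1.0, 500.0), self._trace(2.0, 100.0))
        assert dominated.dominance == "dominated"
        dominant = compare_arms(self._trace(2.0, 100.0), self._trace(1.0, 500.0))
        assert dominant.dominance == "dominant"

    def test_currency_scale_invariance_of_icer(self, packaged_table):
        arm_i = MarkovArm("i", 0.34, 0.66, 0.56, 0.30, 5664.89, 4502.89,
                          program=ProgramCosts(1268.89, 230.40))
        arm_c = MarkovArm("c", 0.36, 0.64, 0.45, 0.33, 5198.62, 5221.69)
        econ = EconConfig()
        base = compare_arms(run_arm(arm_i, econ, packaged_table),
                            run_arm(arm_c, econ, packaged_table))
        k = 3.7
        scaled_i = arm_i.replace(cost_baseline=arm_i.cost_baseline * k,
                                 cost_deteriorated=arm_i.cost_deteriorated * k,
                                 program=ProgramCosts(1268.89 * k, 230.40 * k))
        scaled_c = arm_c.replace(cost_baseline=arm_c.cost_baseline * k,
                                 cost_deteriorated=arm_c.cost_deteriorated * k)
        scaled = compare_arms(run_arm(scaled_i, econ, packaged_table),
                              run_arm(scaled_c, econ, packaged_table))
        assert scaled.delta_cost == pytest.approx(k * base.delta_cost)
        assert scaled.delta_effect == pytest.approx(base.delta_effect, abs=1e-12)
        assert scaled.icer == pytest.approx(k * base.icer)


class TestNMB:
    def test_zero_wtp(self):
        assert nmb(4755.0, 0.731, 0.0) == -4755.0

    def test_published_deltas_at_threshold(self):
        assert nmb(4755.0, 0.731, 15000.0) == pytest.approx(6210.0)

    def test_zero_exactly_at_icer(self):
        value = nmb(4755.0, 0.731, icer(4755.0, 0.731))
        assert value == pytest.approx(0.0, abs=1e-9)


class TestClosedForm:
    def test_undiscounted_immortal_limit(self):
        assert closed_form_dly(1.0, 0.0, 40) == 40.0

    def test_hand_evaluated_value(self):
        # s*v = 0.9/1.03; sum of the geometric series to T=40
        sv = 0.9 / 1.03
        expected = sum(sv**t for t in range(1, 41))
        got = closed_form_dly(0.9, 0.03, 40)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(6.8917, abs=1e-4)
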