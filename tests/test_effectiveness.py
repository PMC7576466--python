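import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    UtilityMap,
    classify_transition,
    compare_groups_categorical,
    compare_groups_continuous,
    estimate_transition_probs,
    generate_cohort,
    map_barthel_to_utility,
    mean_change_ci,
)
from markovcea.cohort import Patient
from markovcea.defaults import REFERENCE_GENDER_TABLE, default_cohort_config


def _patient(pid, barthel_0, barthel_1, arm="intervention"):
    return Patient(
        id=pid, arm=arm, age=84.0, sex="F", comorbidities=set(),
        barthel_0=barthel_0, barthel_1=barthel_1,
        iadl_0=3, iadl_1=3, gds_0=7, gds_1=7,
    )


class TestMeanChangeCI:
    def test_zero_variance_identity(self):
        s = mean_change_ci([50, 60, 70], [50, 60, 70])
        assert s.mean_change == 0 and s.ci_low == 0 and s.ci_high == 0
        assert s.p_value == 1.0

    def test_hand_computed_t_interval(self):
        # differences {1,2,3}: mean 2, sd 1, t(df=2, .975) = 4.3027
        s = mean_change_ci([0, 0, 0], [1, 2, 3])
        assert s.mean_change == pytest.approx(2.0)
        assert s.ci_low == pytest.approx(-0.4841, abs=1e-3)
        assert s.ci_high == pytest.approx(4.4841, abs=1e-3)

    def test_generator_recovers_configured_decline(self):
        """An arm generated with mean Barthel change -3.23 recovers it
        within its own 95% CI at n=10,000 (baseline mid-scale, so the
        instrument ceiling does not truncate the change distribution)."""
        import dataclasses

        cfg = default_cohort_config(n_intervention=1, n_comparator=10_000, seed=31)
        comp = dataclasses.replace(
            cfg.arms["comparator"],
            score_baseline={"barthel": (50.0, 10.0), "iadl": (3.0, 1.5), "gds": (7.0, 3.0)},
        )
        cfg = dataclasses.replace(cfg, arms={**cfg.arms, "comparator": comp})
        arm = [p for p in generate_cohort(cfg) if p.arm == "comparator"]
        pre = [p.barthel_0 for p in arm]
        post = [p.barthel_1 for p in arm]
        s = mean_change_ci(pre, post)
        assert s.ci_low <= -3.23 <= s.ci_high

    def test_ci_brackets_estimate_and_widens_with_level(self):
        rng = np.random.default_rng(2)
        pre, post = rng.normal(50, 5, 40), rng.normal(48, 5, 40)
        widths = []
        for level in (0.80, 0.90, 0.95, 0.99):
            s = mean_change_ci(pre, post, level=level)
            assert s.ci_low <= s.mean_change <= s.ci_high
            widths.append(s.ci_high - s.ci_low)
        assert widths == sorted(widths)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mean_change_ci([1], [2])


def _brute_force_chi2(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestCategorical:
    def test_gender_table_p_rounds_to_02(self):
        _, p, _ = compare_groups_categorical(REFERENCE_GENDER_TABLE)
        assert round(p, 2) == 0.02

    def test_identical_columns_give_zero_statistic(self):
        stat, p, _ = compare_groups_categorical([[10, 10], [25, 25]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_perfect_separation_hand_value(self):
        stat, p, _ = compare_groups_categorical([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p < 0.001

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            compare_groups_categorical([[0, 0], [5, 3]])

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_matches_first_principles_chi_square(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        t = np.array(table)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return
        stat, _, _ = compare_groups_categorical(table)
        assert stat == pytest.approx(_brute_force_chi2(table), abs=1e-10)


class TestContinuous:
    def test_identical_samples_p_one(self):
        for method in ("t", "mann_whitney", "auto"):
            _, p = compare_groups_continuous([5, 5, 5], [5, 5, 5], method)
            assert p == 1.0

    def test_exact_mann_whitney_enumeration(self):
        # complete separation of 3 vs 3: U=0; 2/C(6,3)=0.1 two-sided
        u, p = compare_groups_continuous([1, 2, 3], [4, 5, 6], "mann_whitney")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_power_on_shifted_gaussians(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        for method in ("t", "mann_whitney", "auto"):
            _, p = compare_groups_continuous(a, b, method)
            assert p < 0.001

    def test_auto_gates_to_mann_whitney_for_skewed_data(self):
        rng = np.random.default_rng(9)
        a = rng.lognormal(0, 1.5, 400)
        b = rng.lognormal(0.1, 1.5, 400)
        stat_auto, p_auto = compare_groups_continuous(a, b, "auto")
        stat_mw, p_mw = compare_groups_continuous(a, b, "mann_whitney")
        assert (stat_auto, p_auto) == (stat_mw, p_mw)


class TestTransitions:
    def test_stable_at_zero_threshold(self):
        assert classify_transition(_patient("p", 50, 50)) == "stable_or_improved"

    def test_decline_beyond_threshold_worsens(self):
        assert classify_transition(_patient("p", 50, 40), worsening_threshold=5) == "worsened"

    def test_boundary_is_strict(self):
        # a decline exactly equal to the threshold does not count as worsening
        assert (
            classify_transition(_patient("p", 50, 45), worsening_threshold=5)
            == "stable_or_improved"
        )

    def test_counted_fractions(self):
        arm = [_patient(f"p{i}", 50, 40 if i < 3 else 55) for i in range(10)]
        est = estimate_transition_probs(arm)
        assert est.incidence == pytest.approx(0.30)
        assert est.recovery == pytest.approx(0.70)
        assert est.incidence + est.recovery == 1.0
        assert est.n == 10

    def test_none_worsened(self):
        arm = [_patient(f"p{i}", 50, 50) for i in range(5)]
        est = estimate_transition_probs(arm)
        assert est.incidence == 0.0 and est.recovery == 1.0

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            estimate_transition_probs([])

    @pytest.mark.parametrize("p_worsen", [0.1, 0.34, 0.36, 0.9])
    def test_binomial_parameter_recovery(self, p_worsen):
        """Cohorts generated with a known worsening probability recover it
        within 3 binomial standard errors at n=5000."""
        rng = np.random.default_rng(int(p_worsen * 1000))
        n = 5000
        arm = [
            _patient(f"p{i}", 50, 45 if rng.random() < p_worsen else 50)
            for i in range(n)
        ]
        est = estimate_transition_probs(arm)
        se = np.sqrt(p_worsen * (1 - p_worsen) / n)
        assert abs(est.incidence - p_worsen) <= 3 * se


class TestUtilityMap:
    def test_default_affine_endpoints(self):
        m = UtilityMap()
        assert map_barthel_to_utility(100, m) == 1.0
        assert map_barthel_to_utility(0, m) == 0.0

    def test_direct_mode_returns_configured_state_utility(self):
        m = UtilityMap(mode="direct", direct={"baseline": 0.56, "deteriorated": 0.30})
        assert map_barthel_to_utility(77, m, state="baseline") == 0.56
        assert map_barthel_to_utility(12, m, state="deteriorated") == 0.30

    def test_affine_output_clipped_to_unit_interval(self):
        m = UtilityMap(a=0.5, b=0.01)
        assert map_barthel_to_utility(100, m) == 1.0

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            map_barthel_to_utility(105, UtilityMap())
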