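"""Survival curves, log-rank, correlations, signature permutation, power."""

import numpy as np
import pytest
from scipy import stats

from mnscreen.exceptions import InputError, UndefinedStatisticError
from mnscreen.statsreport import (
    CorrResult,
    PowerSpec,
    SignatureComparison,
    SurvivalRecord,
    correlate_clinical,
    km_curve,
    logrank_test,
    required_sample_size,
    signature_correlation,
    t_test_power,
)


def records(times, events=None, prefix="u"):
    events = events if events is not None else [True] * len(times)
    return [
        SurvivalRecord(f"{prefix}{i}", t, e)
        for i, (t, e) in enumerate(zip(times, events))
    ]


def brute_force_logrank(group_a, group_b):
    """Independent observed/expected tabulation, one event time at a time."""
    ta = np.array([r.ld50_day for r in group_a])
    ea = np.array([r.event for r in group_a])
    tb = np.array([r.ld50_day for r in group_b])
    eb = np.array([r.event for r in group_b])
    times = sorted(set(ta[ea]).union(set(tb[eb])))
    o_minus_e, v = 0.0, 0.0
    for t in times:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        n = na + nb
        da = np.sum(ea & (ta == t))
        db = np.sum(eb & (tb == t))
        d = da + db
        o_minus_e += da - d * na / n
        if n > 1:
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0
    return o_minus_e**2 / v


class TestKaplanMeier:
    def test_all_events_at_one_day_drop_to_zero(self):
        curve = km_curve(records([50, 50, 50, 50]))
        assert curve.at(49) == 1.0
        assert curve.at(50) == 0.0

    def test_no_events_stays_at_one(self):
        curve = km_curve(records([60, 60, 60], events=[False] * 3))
        assert curve.days.size == 0
        assert curve.at(60) == 1.0

    def test_hand_computed_product_limit_with_censoring(self):
        curve = km_curve(records([40, 45, 50], events=[True, True, False]))
        assert curve.at(39) == 1.0
        assert curve.at(40) == pytest.approx(2 / 3)
        assert curve.at(45) == pytest.approx(1 / 3)
        assert curve.at(50) == pytest.approx(1 / 3)

    def test_matches_empirical_survival_without_censoring(self, rng):
        times = rng.integers(35, 60, 25)
        curve = km_curve(records(times))
        for day in range(34, 61):
            assert curve.at(day) == pytest.approx(np.mean(times > day))

    def test_non_increasing_from_one(self, rng):
        times = rng.normal(48, 4, 30)
        curve = km_curve(records(times))
        surv = np.concatenate([[1.0], curve.survival])
        assert np.all(np.diff(surv) <= 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            km_curve([])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.integers(35, 60, 30)
        events = rng.random(30) > 0.3
        curve = km_curve(records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for day in curve.days:
            assert curve.at(day) == pytest.approx(
                float(kmf.survival_function_at_times(day).iloc[0])
            )


class TestLogRank:
    def test_identical_groups_give_zero_chi2(self):
        a = records([40, 45, 50])
        b = records([40, 45, 50], prefix="b")
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_brute_force(self):
        a = records([1, 2, 3])
        b = records([4, 5, 6], prefix="b")
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(brute_force_logrank(a, b), abs=1e-9)

    def test_oracle_agreement_on_random_small_instances(self, rng):
        for _ in range(100):
            na, nb = rng.integers(2, 12, 2)
            a = records(rng.integers(30, 60, na), rng.random(na) > 0.25)
            b = records(rng.integers(30, 60, nb), rng.random(nb) > 0.25, prefix="b")
            if not any(r.event for r in a + b):
                continue
            chi2, _ = logrank_test(a, b)
            assert chi2 == pytest.approx(brute_force_logrank(a, b), abs=1e-9)

    def test_symmetric_in_group_order(self, rng):
        a = records(rng.integers(35, 55, 10))
        b = records(rng.integers(40, 60, 12), prefix="b")
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_no_events_anywhere_rejected(self):
        a = records([60], events=[False])
        b = records([60], events=[False], prefix="b")
        with pytest.raises(UndefinedStatisticError):
            logrank_test(a, b)

    def test_null_type1_error_calibrated(self):
        from mnscreen.benchmarks import logrank_null_type1

        rate = logrank_null_type1(n_reps=400, seed=21)
        assert rate == pytest.approx(0.05, abs=0.02)


class TestClinicalCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 11.0)
        res = correlate_clinical(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        x = np.arange(1.0, 11.0)
        assert correlate_clinical(x, -x).r == pytest.approx(-1.0)

    def test_spearman_small_sample_brute_force_value(self):
        # ranks d = (-1, 1, -1, 1, 0), Σd² = 4 → rho = 1 − 24/120 = 0.8
        res = correlate_clinical(
            [1, 2, 3, 4, 5], [2, 1, 4, 3, 5], method="spearman"
        )
        assert res.r == pytest.approx(0.8)
        # exact permutation p: fraction of the 120 orderings with |rho| ≥ 0.8
        assert 0 < res.p <= 1

    def test_log_transform_applied_to_clinical_variable(self):
        x = np.arange(1.0, 9.0)
        y = np.exp(0.5 * x)
        res = correlate_clinical(x, y, log_transform=True)
        assert res.r == pytest.approx(1.0)
        assert res.transform == "log"

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlate_clinical([1, 2, 3, 4], [5, 5, 5, 5])

    def test_pairwise_complete_drops_nan(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = correlate_clinical(x, y)
        assert res.n == 4
        assert res.r == pytest.approx(1.0)


class TestSignatureCorrelation:
    def _comparison(self, y=None, seed=0, n_perm=1000):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 50)
        y = x if y is None else y
        return SignatureComparison(
            [f"g{i}" for i in range(50)], x, y, n_perm=n_perm, seed=seed
        )

    def test_identical_vectors_give_rho_one(self):
        rho, p, _ = signature_correlation(self._comparison())
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_negated_vector_gives_rho_minus_one(self):
        comp = self._comparison()
        comp.logfc_reference = -comp.logfc_invitro
        rho, _, _ = signature_correlation(comp)
        assert rho == pytest.approx(-1.0)

    def test_permutation_null_centered(self):
        comp = self._comparison(seed=7)
        _, _, summary = signature_correlation(comp)
        assert abs(summary["null_mean"]) < 3 / np.sqrt(comp.n_perm)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            SignatureComparison(["g"] * 12, np.ones(12), np.ones(11))


class TestPower:
    def test_required_n_for_large_effect_verified_by_simulation(self):
        # simulation oracle (20k t-tests) gives power ≈0.79 at n=5 and
        # ≈0.875 at n=6 for d=2, so the smallest adequate n is 6
        assert required_sample_size(PowerSpec(effect_size_d=2.0)) == 6

    def test_floor_at_two_for_huge_effects(self):
        assert required_sample_size(PowerSpec(effect_size_d=10.0)) == 2

    def test_required_n_decreases_with_effect_size(self):
        n1 = required_sample_size(PowerSpec(effect_size_d=1.0))
        n2 = required_sample_size(PowerSpec(effect_size_d=2.0))
        assert n1 > n2

    def test_required_n_non_increasing_in_alpha(self):
        strict = required_sample_size(PowerSpec(alpha=0.01, effect_size_d=1.0))
        lax = required_sample_size(PowerSpec(alpha=0.10, effect_size_d=1.0))
        assert strict >= lax

    def test_power_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for n, d in ((6, 1.0), (9, 1.4), (12, 0.8)):
            ours = t_test_power(n, PowerSpec(effect_size_d=d))
            ref = TTestIndPower().power(effect_size=d, nobs1=n, alpha=0.05)
            assert ours == pytest.approx(ref, abs=1e-6)
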