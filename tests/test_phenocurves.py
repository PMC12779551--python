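"""Per-well phenotype statistics: normalization, rates, LD50, QC, donor means."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnscreen.exceptions import (
    InsufficientDataError,
    QuantificationError,
    ReferenceDayError,
)
from mnscreen.phenocurves import (
    QCConfig,
    aggregate_donor,
    apply_qc,
    compute_decline_rate,
    compute_growth_rate,
    compute_ld50,
    compute_phenotype,
    normalize_to_peak,
    normalize_to_reference_day,
)
from mnscreen.synthgen import CurveParams, analytic_ld50, simulate_neurite_curve

from conftest import make_series


class TestNormalization:
    def test_normalize_to_peak_values(self):
        s = make_series({40: 100_000, 41: 200_000, 42: 100_000})
        assert normalize_to_peak(s) == {40: 50.0, 41: 100.0, 42: 50.0}

    def test_constant_series_all_100(self):
        s = make_series({d: 5e4 for d in range(30, 35)})
        assert all(v == 100.0 for v in normalize_to_peak(s).values())

    def test_failed_day_omitted_and_peak_over_remaining(self):
        s = make_series({40: 100.0, 41: None, 42: 50.0})
        norm = normalize_to_peak(s)
        assert 41 not in norm
        assert norm == {40: 100.0, 42: 50.0}

    def test_all_failed_raises(self):
        with pytest.raises(QuantificationError):
            normalize_to_peak(make_series({40: None, 41: None}))

    def test_reference_day_normalization(self):
        s = make_series({36: 200_000, 40: 100_000})
        norm = normalize_to_reference_day(s, 36)
        assert norm[36] == 100.0
        assert norm[40] == 50.0

    def test_failed_reference_day_raises(self):
        s = make_series({36: None, 40: 100.0})
        with pytest.raises(ReferenceDayError):
            normalize_to_reference_day(s, 36)


class TestRates:
    def test_growth_rate_example(self):
        s = make_series({22: 100.0, 27: 300.0, 32: 300.0})
        assert compute_growth_rate(s) == pytest.approx(200.0)

    def test_monotone_decrease_gives_negative_growth(self):
        s = make_series({22: 100.0, 27: 50.0})
        assert compute_growth_rate(s) == pytest.approx(-50.0)

    def test_decline_rate_example(self):
        s = make_series({45: 200.0, 47: 100.0})
        assert compute_decline_rate(s) == pytest.approx(50.0)

    def test_monotone_increase_gives_negative_decline(self):
        s = make_series({45: 100.0, 47: 150.0, 49: 300.0})
        assert compute_decline_rate(s) == pytest.approx(-50.0)

    def test_no_valid_pair_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_growth_rate(make_series({22: 1.0, 24: 2.0}))

    def test_rates_match_brute_force_on_generated_curve(self, day_grid):
        series, _ = simulate_neurite_curve(CurveParams(), day_grid, rng_seed=5)
        obs = series.observed()
        for window, fn, sign in (
            (5, compute_growth_rate, +1),
            (2, compute_decline_rate, -1),
        ):
            brute = max(
                sign * (obs[d + window] - obs[d]) / obs[d] * 100.0
                for d in obs
                if d + window in obs
            )
            assert fn(series) == pytest.approx(brute)

    def test_pairs_with_failed_partner_are_skipped(self):
        s = make_series({22: 100.0, 27: None, 29: 100.0, 34: 400.0})
        # only (29, 34) is a valid 5-day pair
        assert compute_growth_rate(s) == pytest.approx(300.0)


class TestLD50:
    def test_first_crossing_day(self):
        s = make_series({40: 200.0, 42: 120.0, 44: 90.0, 46: 40.0}, endpoint_day=60)
        # peak 200 → threshold 100; day 44 (value 90) is the first at or below
        assert compute_ld50(s) == 44.0

    def test_endpoint_when_never_below_half(self):
        s = make_series({d: 100.0 - d / 10 for d in range(40, 61, 2)}, endpoint_day=60)
        assert compute_ld50(s) == 60.0

    def test_search_restricted_to_post_peak(self):
        s = make_series({30: 40.0, 35: 100.0, 40: 60.0}, endpoint_day=60)
        # the early sub-50% dip at day 30 must not count
        assert compute_ld50(s) == 60.0

    def test_interpolated_mode_between_days(self):
        s = make_series({40: 200.0, 42: 50.0}, endpoint_day=60)
        # crossing of 100 lies 2/3 of the way from 40 to 42
        assert compute_ld50(s, interpolate=True) == pytest.approx(40 + 2 / 3 * 2)

    def test_ld50_within_one_day_of_analytic_truth(self, day_grid):
        rng = np.random.default_rng(7)
        for _ in range(100):
            params = CurveParams(
                growth_midpoint=float(rng.uniform(24, 32)),
                growth_scale=float(rng.uniform(1, 3)),
                decline_midpoint=float(rng.uniform(40, 58)),
                decline_scale=float(rng.uniform(1, 3)),
            )
            series, truth = simulate_neurite_curve(
                params, day_grid, rng_seed=int(rng.integers(2**31))
            )
            assert abs(compute_ld50(series) - truth) <= 1.0

    def test_ld50_monotone_in_decline_midpoint(self, day_grid):
        previous = -np.inf
        for midpoint in (40, 44, 48, 52, 56):
            params = CurveParams(decline_midpoint=float(midpoint))
            series, _ = simulate_neurite_curve(params, day_grid, rng_seed=0)
            ld50 = compute_ld50(series)
            assert ld50 >= previous
            previous = ld50


class TestQC:
    def test_low_signal_exclusion(self):
        s = make_series({d: 10_000.0 for d in range(40, 50)})
        pheno = compute_phenotype(s)
        assert pheno.qc_status == "excluded"
        assert "low_signal" in pheno.qc_reasons

    def test_failed_fraction_exclusion_counts_only_outside_exempt_window(self):
        # 28 scheduled days 22–49; 9 failed (>25%); days 50–60 all fine
        obs = {d: 50_000.0 for d in range(22, 61)}
        for d in range(22, 31):
            obs[d] = None
        pheno = compute_phenotype(make_series(obs))
        assert "failed_fraction" in pheno.qc_reasons

    def test_failures_inside_exempt_window_do_not_count(self):
        obs = {d: 50_000.0 for d in range(22, 61)}
        for d in range(50, 61):
            obs[d] = None  # all exempt-window days failed
        pheno = compute_phenotype(make_series(obs))
        assert "failed_fraction" not in pheno.qc_reasons

    def test_premature_ld50_exclusion(self):
        obs = {d: 100_000.0 for d in range(22, 37)}
        obs.update({37: 100_000.0, 38: 40_000.0, 39: 30_000.0})
        pheno = compute_phenotype(make_series(obs))
        assert pheno.ld50_day == 38.0
        assert "premature_ld50" in pheno.qc_reasons

    def test_reasons_cumulative(self):
        s = make_series({36: 10_000.0, 38: 4_000.0, 40: 3_000.0})
        pheno = compute_phenotype(s)
        assert set(pheno.qc_reasons) >= {"low_signal", "premature_ld50"}

    def test_passing_well(self):
        obs = {d: 100_000.0 for d in range(22, 46)}
        obs.update({d: 30_000.0 for d in range(46, 61)})
        pheno = compute_phenotype(make_series(obs))
        assert pheno.qc_status == "pass"
        assert pheno.qc_reasons == []


class TestDonorAggregation:
    def test_mean_and_sem(self):
        obs = {d: 100_000.0 for d in range(22, 44)}
        phenos = []
        for i, ld in enumerate((44, 46, 48)):
            o = dict(obs)
            o.update({d: 20_000.0 for d in range(ld, 61)})
            phenos.append(compute_phenotype(make_series(o, well_id=f"w{i}")))
        donor = aggregate_donor(phenos)
        assert donor.mean_ld50 == pytest.approx(46.0)
        assert donor.sem_ld50 == pytest.approx(2.0 / math.sqrt(3))
        assert donor.n_wells_pass == 3

    def test_too_few_passing_wells_excludes_donor(self):
        obs = {d: 100_000.0 for d in range(22, 44)}
        obs.update({d: 20_000.0 for d in range(44, 61)})
        phenos = [
            compute_phenotype(make_series(obs, well_id=f"w{i}")) for i in range(2)
        ]
        with pytest.raises(InsufficientDataError):
            aggregate_donor(phenos, wells_required=3)


class TestScaleInvariance:
    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_phenotype_invariant_under_length_rescaling(self, scale):
        obs = {d: 100_000.0 * np.exp(-((d - 40) ** 2) / 50) for d in range(22, 61)}
        base = compute_phenotype(make_series(obs))
        scaled = compute_phenotype(
            make_series({d: v * scale for d, v in obs.items()})
        )
        assert scaled.normalized == pytest.approx(base.normalized)
        assert scaled.growth_rate_pct == pytest.approx(base.growth_rate_pct)
        assert scaled.decline_rate_pct == pytest.approx(base.decline_rate_pct)
        assert scaled.ld50_day == base.ld50_day

    def test_normalized_max_is_exactly_100(self, day_grid):
        for seed in range(10):
            series, _ = simulate_neurite_curve(
                CurveParams(noise_cv=0.1), day_grid, rng_seed=seed
            )
            assert max(normalize_to_peak(series).values()) == 100.0
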