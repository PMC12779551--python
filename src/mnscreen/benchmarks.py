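"""Validation experiments on synthetic data with known ground truth.

Each function runs one recovery or calibration experiment end to end —
generate synthetic inputs, run the corresponding estimator, score the
result against the generator's truth — and returns plain numbers. They
are used by the test suite and the reproduction script, and are sized so
a full run stays in the minutes range on one core.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .calcium import DetectConfig, analyze_trace
from .imagequant import ImageField, QuantConfig, measure_field
from .phenocurves import aggregate_donor, compute_ld50, compute_phenotype
from .screen import dunn_vs_reference, kruskal_wallis, screen_relative_rescue
from .statsreport import SurvivalRecord, logrank_test
from .synthgen import (
    CalciumSimSpec,
    CurveParams,
    analytic_ld50,
    random_image_truth,
    render_image,
    simulate_calcium_trace,
    simulate_neurite_curve,
)

DAY_GRID = list(range(22, 61))


def qc_fixture_plate() -> List[Tuple["object", str, List[str]]]:
    """A 12-well fixture exercising each exclusion rule exactly once.

    Returns (series, expected_status, expected_reasons) triples: nine
    healthy wells, one low-signal well (never reaches 12,500 µm), one
    well with >25% failed quantifications outside days 50–60, and one
    well whose LD50 falls before day 39.
    """
    from .phenocurves import WellSeries

    wells = []

    def series(well_id, obs):
        return WellSeries(well_id=well_id, donor_id="DFIX", observations=obs)

    healthy = {d: 100_000.0 for d in DAY_GRID if d < 46}
    healthy.update({d: 30_000.0 for d in DAY_GRID if d >= 46})
    for i in range(9):
        wells.append((series(f"ok{i}", dict(healthy)), "pass", []))

    low = {d: v * 0.1 for d, v in healthy.items()}  # peaks at 10,000 µm
    wells.append((series("low_signal", low), "excluded", ["low_signal"]))

    failed = dict(healthy)
    for d in range(22, 31):  # 9 of 28 non-exempt days > 25%
        failed[d] = None
    wells.append((series("failed_frac", failed), "excluded", ["failed_fraction"]))

    premature = {d: 100_000.0 for d in DAY_GRID if d <= 36}
    premature.update({37: 100_000.0, 38: 40_000.0})
    premature.update({d: 30_000.0 for d in DAY_GRID if d >= 39})
    wells.append((series("early_ld50", premature), "excluded", ["premature_ld50"]))
    return wells


def _random_curve(rng: np.random.Generator, noise_cv: float = 0.0) -> CurveParams:
    return CurveParams(
        peak_amplitude=float(rng.uniform(50_000, 400_000)),
        growth_midpoint=float(rng.uniform(24, 32)),
        growth_scale=float(rng.uniform(1.0, 3.0)),
        decline_midpoint=float(rng.uniform(40, 58)),
        decline_scale=float(rng.uniform(1.0, 3.0)),
        noise_cv=noise_cv,
    )


def ld50_grid_fidelity(n_draws: int = 100, seed: int = 0) -> float:
    """Max |sampled-day LD50 − analytic crossing| over noiseless random
    curves sampled daily; the sampling grid bounds this at 1 day."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        params = _random_curve(rng)
        series, truth = simulate_neurite_curve(
            params, DAY_GRID, rng_seed=int(rng.integers(2**31))
        )
        worst = max(worst, abs(compute_ld50(series) - truth))
    return worst


def donor_ld50_recovery(
    n_runs: int = 100,
    seed: int = 0,
    noise_cv: float = 0.10,
    wells_per_donor: int = 6,
    tolerance_days: float = 2.0,
) -> float:
    """Fraction of simulated donors whose QC-passed well-mean LD50 lands
    within ``tolerance_days`` of the analytic truth."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        params = CurveParams(
            decline_midpoint=float(rng.uniform(42, 52)), noise_cv=noise_cv
        )
        truth = analytic_ld50(params, DAY_GRID[0], DAY_GRID[-1])
        phenos = []
        for w in range(wells_per_donor):
            series, _ = simulate_neurite_curve(
                params,
                DAY_GRID,
                rng_seed=int(rng.integers(2**31)),
                well_id=f"w{w}",
            )
            phenos.append(compute_phenotype(series))
        donor = aggregate_donor(phenos)
        hits += abs(donor.mean_ld50 - truth) <= tolerance_days
    return hits / n_runs


def image_length_errors(n_fields: int = 50, seed: int = 0) -> np.ndarray:
    """Signed relative skeleton-length error on random rendered fields."""
    errors = []
    for i in range(n_fields):
        truth = random_image_truth(rng_seed=seed + i)
        image = render_image(
            truth,
            psf_sigma=1.5,
            background=10.0,
            noise_model=("poisson", 1.0),
            rng_seed=seed + i,
        )
        seg = measure_field(ImageField(image, truth.pixel_size_um))
        errors.append(
            (seg.total_length_um - truth.total_length_um) / truth.total_length_um
        )
    return np.array(errors)


def screen_ranking_recovery(
    n_runs: int = 50,
    seed: int = 0,
    n_drugs: int = 107,
    n_donors: int = 16,
    true_drugs: Tuple[str, ...] = ("drug005", "drug050", "drug099"),
    effect_days: float = 4.0,
    noise_sd_days: float = 1.0,
    top_k: int = 5,
) -> float:
    """Fraction of screens in which every truly effective drug ranks in
    the top ``top_k`` by mean screen-relative rescue across donors."""
    drugs = [f"drug{i:03d}" for i in range(n_drugs)]
    hits = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        rows = []
        for _ in range(n_donors):
            base = 46.0 + rng.normal(0.0, 2.0)
            ld50s = {
                d: base
                + (effect_days if d in true_drugs else 0.0)
                + rng.normal(0.0, noise_sd_days)
                for d in drugs
            }
            rows.append(screen_relative_rescue(ld50s))
        mean_rescue = pd.DataFrame(rows).mean()
        top = set(mean_rescue.sort_values(ascending=False).index[:top_k])
        hits += set(true_drugs) <= top
    return hits / n_runs


def screen_null_false_positive_rate(
    n_runs: int = 200,
    seed: int = 0,
    n_drugs: int = 107,
    n_donors: int = 16,
    alpha: float = 0.05,
) -> float:
    """Per-drug false-positive rate of the Kruskal–Wallis + Dunn calls on
    screens with no true effects (gatekept by the omnibus test)."""
    false_calls = 0
    comparisons = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        groups = {
            f"drug{i:03d}": rng.normal(0.0, 1.0, n_donors) for i in range(n_drugs)
        }
        groups["DMSO"] = rng.normal(0.0, 1.0, n_donors)
        _, omnibus_p = kruskal_wallis(list(groups.values()))
        p_adj = dunn_vs_reference(groups, "DMSO")
        for p in p_adj.values():
            comparisons += 1
            if omnibus_p < alpha and p < alpha:
                false_calls += 1
    return false_calls / comparisons


def logrank_null_type1(
    n_reps: int = 1000, seed: int = 0, n_per_group: int = 20, alpha: float = 0.05
) -> float:
    """Rejection rate of the log-rank test when both groups share one
    LD50 distribution."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        ta = rng.normal(48.0, 3.0, n_per_group)
        tb = rng.normal(48.0, 3.0, n_per_group)
        a = [SurvivalRecord(f"a{i}", t) for i, t in enumerate(ta)]
        b = [SurvivalRecord(f"b{i}", t) for i, t in enumerate(tb)]
        _, p = logrank_test(a, b)
        rejections += p < alpha
    return rejections / n_reps


def calcium_detection_performance(
    n_seeds: int = 50,
    seed: int = 0,
    event_rate: float = 0.1,
    duration: float = 100.0,
    amplitude_over_noise: float = 8.0,
    noise_sd: float = 0.1,
    match_window: int = 5,
) -> Dict[str, float]:
    """Recall and false-positive rate of the transient detector on
    synthetic traces; a truth event counts as detected when an onset falls
    within ``match_window`` samples of it."""
    cfg = DetectConfig()
    recalls: List[float] = []
    fp_rates: List[float] = []
    freqs: List[float] = []
    for i in range(n_seeds):
        spec = CalciumSimSpec(
            event_rate=event_rate,
            duration=duration,
            amplitude_scale=amplitude_over_noise * noise_sd,
            noise_sd=noise_sd,
            seed=seed + i,
        )
        trace, onsets, _ = simulate_calcium_trace(spec)
        events = analyze_trace(trace, cfg)
        if len(onsets):
            matched = sum(
                1
                for o in onsets
                if np.any(np.abs(events.event_onsets - o) <= match_window)
            )
            recalls.append(matched / len(onsets))
        extra = sum(
            1
            for o in events.event_onsets
            if not len(onsets) or not np.any(np.abs(onsets - o) <= match_window)
        )
        fp_rates.append(extra / duration)
        freqs.append(events.frequency)
    return {
        "recall": float(np.mean(recalls)) if recalls else float("nan"),
        "false_positives_per_s": float(np.mean(fp_rates)),
        "mean_detected_frequency_hz": float(np.mean(freqs)),
    }
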