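"""Synthetic plates, image fields and calcium traces with known ground truth.

The generators emulate the statistical structure of a longitudinal
motor-neuron phenotyping screen:

* per-well neurite-length time courses with a growth phase, plateau and
  degeneration phase, donor-level LD50 heterogeneity and treatment shifts;
* fluorescence image fields of filamentous neurites and bright somata with
  a known total skeleton length;
* ROI calcium traces with injected exponential-decay transients.

Every generator is deterministic under its seed, and for zero noise the
downstream estimators recover the analytic truth to grid resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .calcium import FluorTrace
from .exceptions import InputError, ParameterError
from .io import PlateLayout, well_address
from .phenocurves import WellSeries

# ---------------------------------------------------------------------------
# neurite curves


@dataclass
class CurveParams:
    """Latent three-phase neurite curve: growth × decline logistic product.

    L(t) = A · σ((t − t_g)/τ_g) · σ((t_d − t)/τ_d), with σ the logistic
    function. ``peak_amplitude`` A is in µm of total neurite length;
    midpoints and scales in days. Observed values multiply L(t) by
    (1 + ε) with ε zero-mean Gaussian of s.d. ``noise_cv``; each day is
    independently marked as failed quantification with ``dropout_prob``.
    """

    peak_amplitude: float = 200_000.0
    growth_midpoint: float = 28.0
    growth_scale: float = 2.0
    decline_midpoint: float = 48.0
    decline_scale: float = 2.0
    noise_cv: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0:
            raise ParameterError("peak_amplitude must be > 0")
        if self.growth_scale <= 0 or self.decline_scale <= 0:
            raise ParameterError("sigmoid scales must be > 0")
        if self.decline_midpoint <= self.growth_midpoint:
            raise ParameterError("decline_midpoint must exceed growth_midpoint")
        if not 0 <= self.noise_cv < 1:
            raise ParameterError("noise_cv must be in [0, 1)")
        if not 0 <= self.dropout_prob <= 1:
            raise ParameterError("dropout_prob must be in [0, 1]")

    def latent(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.peak_amplitude
            * expit((t - self.growth_midpoint) / self.growth_scale)
            * expit((self.decline_midpoint - t) / self.decline_scale)
        )


def analytic_ld50(
    params: CurveParams,
    day_start: float,
    day_end: float,
    grid_step: float = 0.01,
) -> float:
    """LD50 of the noiseless latent curve on a fine grid.

    Smallest grid time at or after the latent peak where L(t) ≤ 0.5·max L,
    or ``day_end`` when the curve never drops that far within range.
    """
    t = np.arange(day_start, day_end + grid_step / 2, grid_step)
    L = params.latent(t)
    i_peak = int(np.argmax(L))
    below = np.flatnonzero(L[i_peak:] <= 0.5 * L[i_peak])
    if below.size == 0:
        return float(day_end)
    return float(t[i_peak + below[0]])


def simulate_neurite_curve(
    params: CurveParams,
    days: Sequence[int],
    rng_seed: int,
    well_id: str = "W1",
    donor_id: str = "D1",
    group: str = "control",
    treatment: Optional[str] = None,
    dose_uM: float = 0.0,
) -> Tuple[WellSeries, float]:
    """One well's observed series plus the analytic true LD50.

    Days must be sorted and strictly increasing. Noise is multiplicative
    (CV-scaled); dropout marks a day as failed quantification rather than
    zero, because QC treats failed time points distinctly from low signal.
    """
    days = list(days)
    if not days:
        raise InputError("empty day grid")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise InputError("days must be sorted and strictly increasing")

    rng = np.random.default_rng(rng_seed)
    latent = params.latent(days)
    eps = rng.normal(0.0, params.noise_cv, size=len(days)) if params.noise_cv else 0.0
    observed = latent * (1.0 + eps)
    observed = np.clip(observed, 0.0, None)
    dropped = (
        rng.random(len(days)) < params.dropout_prob
        if params.dropout_prob
        else np.zeros(len(days), dtype=bool)
    )

    obs: Dict[int, Optional[float]] = {
        int(d): (None if drop else float(v))
        for d, v, drop in zip(days, observed, dropped)
    }
    series = WellSeries(
        well_id=well_id,
        donor_id=donor_id,
        group=group,
        treatment=treatment,
        dose_uM=dose_uM,
        observations=obs,
        endpoint_day=int(days[-1]),
    )
    return series, analytic_ld50(params, days[0], days[-1])


# ---------------------------------------------------------------------------
# plates


@dataclass
class SimPlateConfig:
    """Virtual screening plate: donors, replicate wells, treatments.

    Defaults mirror the screening scale: six replicate wells per donor,
    daily imaging from day 22 to day 60, and donor LD50s drawn from
    group-level normal distributions. Each treatment shifts the decline
    midpoint of treated wells by its effect in days; treatments are run
    in duplicate wells per donor as in the drug screen.
    """

    n_control_donors: int = 4
    n_case_donors: int = 4
    wells_per_donor: int = 6
    fields_per_well: int = 4
    day_range: Tuple[int, int] = (22, 60)
    donor_ld50_mean_control: float = 50.0
    donor_ld50_mean_case: float = 44.0
    donor_ld50_sd: float = 2.0
    treatment_effects: Dict[str, float] = field(default_factory=dict)
    treatment_wells_per_donor: int = 2
    noise_cv: float = 0.10
    dropout_prob: float = 0.0
    base_curve: CurveParams = field(default_factory=CurveParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_range[0] >= self.day_range[1]:
            raise ParameterError("day_range start must be < end")
        for name in (
            "n_control_donors",
            "n_case_donors",
            "wells_per_donor",
            "fields_per_well",
            "treatment_wells_per_donor",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be ≥ 1")


def calibrate_decline_midpoint(
    target_ld50: float,
    base: CurveParams,
    day_start: float = 22.0,
    day_end: float = 60.0,
) -> float:
    """Decline midpoint whose latent curve has the requested analytic LD50.

    The crossing day is not a pure translation of the decline midpoint
    (the growth sigmoid and the peak height both move a little), so the
    midpoint is solved by bisection; targets past the observable window
    simply return the target (the curve then never crosses in range).
    """
    def ld50_of(td: float) -> float:
        params = CurveParams(
            peak_amplitude=base.peak_amplitude,
            growth_midpoint=base.growth_midpoint,
            growth_scale=base.growth_scale,
            decline_midpoint=td,
            decline_scale=base.decline_scale,
        )
        return analytic_ld50(params, day_start, day_end)

    lo = max(base.growth_midpoint + 0.5, target_ld50 - 6.0)
    hi = min(target_ld50 + 6.0, day_end + 6.0)
    if ld50_of(lo) > target_ld50 or ld50_of(hi) < target_ld50:
        return float(target_ld50)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if ld50_of(mid) < target_ld50:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_plate(
    config: SimPlateConfig,
) -> Tuple[PlateLayout, List[WellSeries], pd.DataFrame]:
    """Simulate a full plate of well series with per-well ground truth.

    Returns (layout, well series, truth table). The truth table has one
    row per well with the donor's latent LD50-defining parameters, the
    analytic per-well true LD50 and the treatment's true effect in days.
    """
    rng = np.random.default_rng(config.seed)
    days = list(range(config.day_range[0], config.day_range[1] + 1))

    donors = []
    for i in range(config.n_control_donors):
        donors.append((f"CTRL{i + 1:03d}", "control", config.donor_ld50_mean_control))
    for i in range(config.n_case_donors):
        donors.append((f"SALS{i + 1:03d}", "SALS", config.donor_ld50_mean_case))

    layout_rows = []
    series_list: List[WellSeries] = []
    truth_rows = []
    widx = 0
    for donor_id, group, ld50_mean in donors:
        donor_ld50 = ld50_mean + rng.normal(0.0, config.donor_ld50_sd)
        conditions: List[Tuple[Optional[str], float, int]] = [
            (None, 0.0, config.wells_per_donor)
        ]
        for drug, effect in config.treatment_effects.items():
            conditions.append((drug, effect, config.treatment_wells_per_donor))
        for treatment, effect, n_wells in conditions:
            midpoint = calibrate_decline_midpoint(
                donor_ld50 + effect,
                config.base_curve,
                config.day_range[0],
                config.day_range[1],
            )
            for rep in range(n_wells):
                params = CurveParams(
                    peak_amplitude=config.base_curve.peak_amplitude,
                    growth_midpoint=config.base_curve.growth_midpoint,
                    growth_scale=config.base_curve.growth_scale,
                    decline_midpoint=midpoint,
                    decline_scale=config.base_curve.decline_scale,
                    noise_cv=config.noise_cv,
                    dropout_prob=config.dropout_prob,
                )
                well = well_address(widx)
                widx += 1
                series, true_ld50 = simulate_neurite_curve(
                    params,
                    days,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                    well_id=f"P1:{well}",
                    donor_id=donor_id,
                    group=group,
                    treatment=treatment,
                    dose_uM=2.5 if treatment else 0.0,
                )
                series_list.append(series)
                layout_rows.append(
                    {
                        "well": well,
                        "donor": donor_id,
                        "group": group,
                        "treatment": treatment if treatment else "",
                        "dose_uM": series.dose_uM,
                        "replicate": rep + 1,
                    }
                )
                truth_rows.append(
                    {
                        "well": well,
                        "donor": donor_id,
                        "group": group,
                        "treatment": treatment if treatment else "",
                        "donor_ld50": donor_ld50,
                        "treatment_effect_days": effect,
                        "true_ld50": true_ld50,
                    }
                )

    layout = PlateLayout(plate_id="P1", wells=pd.DataFrame(layout_rows))
    return layout, series_list, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# image fields


def polyline_length(path: np.ndarray) -> float:
    """Brute-force point-to-point arc length of a polyline, in pixels."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


@dataclass
class ImageTruth:
    """Ground truth for one synthetic image field.

    ``filament_paths`` are (row, col) polylines in pixel coordinates,
    already sampled at sub-pixel resolution; ``total_length_um`` is their
    summed arc length × pixel size and is recomputed at construction.
    """

    filament_paths: List[np.ndarray]
    soma_centers: List[Tuple[float, float]]
    pixel_size_um: float = 1.0
    total_length_um: float = 0.0

    def __post_init__(self) -> None:
        self.filament_paths = [np.asarray(p, dtype=float) for p in self.filament_paths]
        self.total_length_um = self.pixel_size_um * sum(
            polyline_length(p) for p in self.filament_paths
        )


def _spline_path(control_points: np.ndarray, n_samples: int = 600) -> np.ndarray:
    """Cubic-spline polyline through the control points, sampled densely."""
    cp = np.asarray(control_points, dtype=float)
    u = np.linspace(0.0, 1.0, len(cp))
    cs_r = CubicSpline(u, cp[:, 0])
    cs_c = CubicSpline(u, cp[:, 1])
    uu = np.linspace(0.0, 1.0, n_samples)
    return np.column_stack([cs_r(uu), cs_c(uu)])


def random_image_truth(
    shape: Tuple[int, int] = (256, 256),
    n_filaments: int = 5,
    n_somata: int = 3,
    pixel_size_um: float = 1.0,
    rng_seed: int = 0,
    margin: int = 12,
    filament_half_span: float = 80.0,
) -> ImageTruth:
    """Random curved filaments (cubic splines) plus soma centers.

    Spline overshoot is clipped to the frame; the recorded truth length is
    the arc length of the final clipped polylines, so the truth is always
    consistent with what is rendered.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = shape
    paths = []
    for _ in range(n_filaments):
        start = rng.uniform([margin, margin], [h - margin, w - margin])
        direction = rng.uniform(-1, 1, size=2)
        direction /= np.linalg.norm(direction) + 1e-12
        n_cp = rng.integers(4, 7)
        offsets = np.linspace(-filament_half_span, filament_half_span, n_cp)
        wiggle = rng.normal(0.0, 6.0, size=(n_cp, 2))
        cp = start + offsets[:, None] * direction + wiggle
        cp = np.clip(cp, margin / 2, [h - 1 - margin / 2, w - 1 - margin / 2])
        path = _spline_path(cp)
        path = np.clip(path, 1.0, [h - 2.0, w - 2.0])
        paths.append(path)
    centers = [
        tuple(rng.uniform([margin, margin], [h - margin, w - margin]))
        for _ in range(n_somata)
    ]
    return ImageTruth(paths, centers, pixel_size_um=pixel_size_um)


def render_image(
    truth: ImageTruth,
    shape: Tuple[int, int] = (256, 256),
    psf_sigma: float = 1.5,
    background: float = 0.0,
    noise_model: Optional[Tuple[str, float]] = None,
    rng_seed: int = 0,
    filament_intensity: float = 100.0,
    soma_intensity: float = 400.0,
    soma_radius_px: float = 5.0,
) -> np.ndarray:
    """Render a field: filaments at fixed intensity, somata as bright
    discs, Gaussian PSF blur, then background and noise.

    ``noise_model`` is ``("poisson", photons_per_unit)`` or
    ``("gaussian", sd)``; ``None`` renders noiselessly. The passed truth
    is never modified.
    """
    h, w = shape
    for path in truth.filament_paths:
        if (
            path.size
            and (path.min() < 0 or path[:, 0].max() > h - 1 or path[:, 1].max() > w - 1)
        ):
            raise InputError("filament path exits the image frame")
    for r, c in truth.soma_centers:
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise InputError("soma center outside the image frame")

    canvas = np.zeros(shape, dtype=float)
    for path in truth.filament_paths:
        # resample at 0.2-px steps so rasterization has no gaps
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        total = seg.sum()
        if total == 0:
            continue
        n = max(int(total / 0.2), 2)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        ss = np.linspace(0.0, total, n)
        rr = np.interp(ss, s, path[:, 0])
        cc = np.interp(ss, s, path[:, 1])
        canvas[np.round(rr).astype(int), np.round(cc).astype(int)] = filament_intensity

    if truth.soma_centers:
        yy, xx = np.mgrid[0:h, 0:w]
        for r, c in truth.soma_centers:
            disc = (yy - r) ** 2 + (xx - c) ** 2 <= soma_radius_px**2
            canvas[disc] = soma_intensity

    if psf_sigma > 0:
        canvas = gaussian_filter(canvas, psf_sigma)
    image = canvas + background

    if noise_model is not None:
        kind, scale = noise_model
        rng = np.random.default_rng(rng_seed)
        if kind == "poisson":
            if scale <= 0:
                raise ParameterError("poisson noise scale must be > 0")
            image = rng.poisson(np.clip(image, 0, None) * scale) / scale
        elif kind == "gaussian":
            image = image + rng.normal(0.0, scale, size=image.shape)
        else:
            raise ParameterError(f"unknown noise model {kind!r}")
    return np.clip(image, 0.0, None)


def save_rendered_field(image: np.ndarray, truth: ImageTruth, path) -> None:
    """Write a rendered field as single-plane TIFF with a JSON sidecar
    (same stem, ``.json``) holding the pixel size and ground truth."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    sidecar = {
        "pixel_size_um": truth.pixel_size_um,
        "total_length_um": truth.total_length_um,
        "n_filaments": len(truth.filament_paths),
        "soma_centers": [list(c) for c in truth.soma_centers],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# calcium traces


@dataclass
class CalciumSimSpec:
    """Synthetic ROI calcium trace: Poisson events with exponential decay.

    Events arrive at ``event_rate`` Hz over ``duration`` s; each adds
    ``amplitude_scale``·exp(−Δt/``decay_tau``) in ΔF/F units. Gaussian
    noise of ``noise_sd`` (ΔF/F units) rides on the baseline fluorescence.
    """

    sampling_rate: float = 10.0
    duration: float = 100.0
    event_rate: float = 0.2
    amplitude_scale: float = 0.8
    decay_tau: float = 0.5
    noise_sd: float = 0.1
    baseline_f: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0 or self.decay_tau <= 0:
            raise ParameterError("sampling_rate, duration and decay_tau must be > 0")
        if self.event_rate < 0 or self.noise_sd < 0:
            raise ParameterError("event_rate and noise_sd must be ≥ 0")
        if self.baseline_f <= 0:
            raise ParameterError("baseline_f must be > 0")


def simulate_calcium_trace(
    spec: CalciumSimSpec, roi_id: str = "roi1"
) -> Tuple[FluorTrace, np.ndarray, np.ndarray]:
    """Trace plus ground-truth event onset samples and amplitudes.

    F_t = baseline_f · (1 + Σ events + noise), so ΔF/F against the median
    baseline recovers the injected signal independent of baseline scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate

    n_events = rng.poisson(spec.event_rate * spec.duration)
    event_times = np.sort(rng.uniform(0.0, spec.duration, size=n_events))
    dff_signal = np.zeros(n)
    for t0 in event_times:
        dt = t - t0
        mask = dt >= 0
        dff_signal[mask] += spec.amplitude_scale * np.exp(-dt[mask] / spec.decay_tau)

    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd else 0.0
    samples = spec.baseline_f * (1.0 + dff_signal + noise)
    trace = FluorTrace(roi_id, samples, spec.sampling_rate)
    onsets = np.round(event_times * spec.sampling_rate).astype(int)
    amplitudes = np.full(n_events, spec.amplitude_scale)
    return trace, onsets, amplitudes
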