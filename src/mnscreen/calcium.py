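"""Calcium-transient detection from ROI fluorescence traces.

Traces are sampled at 10 Hz by default. ΔF/F is computed against the
median fluorescence of the whole session, smoothed with a Savitzky–Golay
filter, and events are called at upward crossings of k × s.d. of the
baseline noise (k = 3 by default). Frequency is averaged over ROIs;
amplitude is pooled over events, so the two summaries carry different n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal, stats

from .exceptions import ConfigError, DetectionError, TraceError


@dataclass
class FluorTrace:
    """Raw fluorescence samples for one ROI (arbitrary units)."""

    roi_id: str
    samples: np.ndarray
    sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise TraceError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class DffTrace:
    roi_id: str
    dff: np.ndarray
    baseline_f: float
    sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)


@dataclass
class DetectConfig:
    """Smoothing and thresholding parameters for event detection.

    ``k_sd`` multiplies the baseline noise s.d. to form the event
    threshold. The default noise estimator is robust (1.4826 × MAD of the
    smoothed ΔF/F), which ignores the events themselves; ``global_sd``
    uses the plain standard deviation instead. The refractory period
    suppresses re-triggering on threshold chatter.
    """

    savgol_window: int = 9
    savgol_order: int = 3
    k_sd: float = 3.0
    baseline_sd_estimator: str = "robust_mad"
    refractory: int = 5
    pileup_prominence_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0:
            raise ConfigError("savgol_window must be odd")
        if self.savgol_order >= self.savgol_window:
            raise ConfigError("savgol_order must be < savgol_window")
        if self.k_sd <= 0:
            raise ConfigError("k_sd must be positive")
        if self.baseline_sd_estimator not in ("robust_mad", "global_sd"):
            raise ConfigError(
                f"unknown baseline_sd_estimator {self.baseline_sd_estimator!r}"
            )


@dataclass
class CalciumEventSet:
    roi_id: str
    event_onsets: np.ndarray
    event_amplitudes: np.ndarray
    frequency: float
    mean_amplitude: float
    threshold_used: float
    duration: float
    group: str = ""


def compute_dff(trace: FluorTrace, mode: str = "delta") -> DffTrace:
    """ΔF/F against the session-median baseline.

    ``mode='delta'`` gives the conventional (F − F0)/F0; ``mode='ratio'``
    gives the raw ratio F/F0. F0 is the median of the full trace.
    """
    f0 = float(np.median(trace.samples))
    if f0 <= 0:
        raise TraceError(f"ROI {trace.roi_id}: non-positive baseline {f0}")
    if mode == "delta":
        dff = (trace.samples - f0) / f0
    elif mode == "ratio":
        dff = trace.samples / f0
    else:
        raise ConfigError(f"unknown dff mode {mode!r}")
    return DffTrace(trace.roi_id, dff, f0, trace.sampling_rate)


def smooth(dff: DffTrace, cfg: DetectConfig | None = None) -> DffTrace:
    """Savitzky–Golay smoothing; edge samples are fitted by the terminal
    window's polynomial rather than padded."""
    cfg = cfg or DetectConfig()
    if cfg.savgol_window >= len(dff.dff):
        raise ConfigError(
            f"savgol_window {cfg.savgol_window} >= trace length {len(dff.dff)}"
        )
    out = signal.savgol_filter(
        dff.dff, cfg.savgol_window, cfg.savgol_order, mode="interp"
    )
    return DffTrace(dff.roi_id, out, dff.baseline_f, dff.sampling_rate)


def _baseline_sd(dff: np.ndarray, estimator: str) -> float:
    if estimator == "robust_mad":
        return 1.4826 * float(np.median(np.abs(dff - np.median(dff))))
    return float(np.std(dff))


def detect_events(
    dff_smoothed: DffTrace,
    cfg: DetectConfig | None = None,
    dff_raw: DffTrace | None = None,
) -> CalciumEventSet:
    """Call transients at upward crossings of k_sd × baseline s.d.

    An event starts where the smoothed ΔF/F crosses the threshold from
    below, at least ``refractory`` samples after the previous onset; its
    amplitude is the ΔF/F maximum between onset and the next onset or the
    return below threshold, taken from ``dff_raw`` when provided (the
    smoothing filter flattens transient peaks whose decay is on the order
    of the filter window, so the unsmoothed trace estimates peak ΔF/F
    with less bias). While the trace is still elevated, a renewed
    rise of at least one threshold above the running local minimum is
    called as a further (piled-up) event, so transients arriving before
    the previous one has decayed are not silently merged.
    """
    cfg = cfg or DetectConfig()
    x = dff_smoothed.dff
    sd = _baseline_sd(x, cfg.baseline_sd_estimator)
    if sd <= 0:
        raise DetectionError(
            f"ROI {dff_smoothed.roi_id}: baseline s.d. is zero "
            f"({cfg.baseline_sd_estimator}); cannot set an event threshold"
        )
    threshold = cfg.k_sd * sd

    n_samp = len(x)
    above = x > threshold
    # peaks above threshold whose prominence is itself ≥ one threshold:
    # a piled-up transient shows as a renewed prominent peak while the
    # trace is still elevated
    peaks, _ = signal.find_peaks(
        x,
        height=threshold,
        prominence=cfg.pileup_prominence_fraction * threshold,
        distance=cfg.refractory,
    )
    if peaks.size == 0 and above.any():
        # e.g. a plateau or a maximum at the trace edge
        peaks = np.array([int(np.argmax(x))])

    amp_source = dff_raw.dff if dff_raw is not None else x
    onsets: List[int] = []
    amplitudes: List[float] = []
    prev_peak = None
    for pk in peaks:
        if prev_peak is None or not above[prev_peak:pk].all():
            # first peak of an elevated stretch: onset at the upward
            # threshold crossing preceding it
            i = pk
            while i > 0 and above[i - 1]:
                i -= 1
        else:
            # pileup: onset at the local minimum between the two peaks
            i = int(prev_peak + np.argmin(x[prev_peak:pk]))
        if onsets and i - onsets[-1] < cfg.refractory:
            continue
        # amplitude over the event's span: onset to return below threshold
        j = pk
        while j < n_samp and above[j]:
            j += 1
        onsets.append(int(i))
        amplitudes.append(float(np.max(amp_source[i : max(j, i + 1)])))
        prev_peak = pk

    duration = len(x) / dff_smoothed.sampling_rate
    n = len(onsets)
    return CalciumEventSet(
        roi_id=dff_smoothed.roi_id,
        event_onsets=np.array(onsets, dtype=int),
        event_amplitudes=np.array(amplitudes, dtype=float),
        frequency=n / duration,
        mean_amplitude=float(np.mean(amplitudes)) if n else float("nan"),
        threshold_used=threshold,
        duration=duration,
    )


def analyze_trace(
    trace: FluorTrace, cfg: DetectConfig | None = None, dff_mode: str = "delta"
) -> CalciumEventSet:
    """Convenience pipeline: ΔF/F → smooth → detect (amplitudes from the
    unsmoothed ΔF/F)."""
    dff = compute_dff(trace, dff_mode)
    return detect_events(smooth(dff, cfg), cfg, dff_raw=dff)


def summarize_rois(event_sets: Sequence[CalciumEventSet]) -> Dict[str, float]:
    """Group summary: frequency averaged over ROIs, amplitude pooled over
    events — the two report different n by construction."""
    if not event_sets:
        raise TraceError("no ROIs to summarize")
    freqs = np.array([e.frequency for e in event_sets])
    amps = np.concatenate(
        [e.event_amplitudes for e in event_sets]
        or [np.empty(0)]
    ) if event_sets else np.empty(0)
    n_roi = len(freqs)
    n_ev = len(amps)
    return {
        "n_rois": n_roi,
        "n_events": n_ev,
        "mean_frequency_hz": float(np.mean(freqs)),
        "sem_frequency_hz": float(np.std(freqs, ddof=1) / np.sqrt(n_roi))
        if n_roi > 1
        else 0.0,
        "mean_amplitude_dff": float(np.mean(amps)) if n_ev else float("nan"),
        "sem_amplitude_dff": float(np.std(amps, ddof=1) / np.sqrt(n_ev))
        if n_ev > 1
        else 0.0,
    }


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of two groups of per-ROI (or
    per-event) values: exact enumeration when min(n) ≤ 8, tie-corrected
    normal approximation otherwise. Returns (U, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise TraceError("both groups must be non-empty")
    method = "exact" if min(a.size, b.size) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
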