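"""Per-well longitudinal neurite phenotypes.

Each well contributes a day-indexed series of total neurite length (µm).
From it we derive the survival-time statistic used throughout the screen:
the LD50 day, defined as the first imaging day at or after the peak on
which total neurite length has dropped to 50% of the well's peak value,
or the experimental endpoint if the 50% threshold is never reached.
Growth and decline are summarized as the maximum percentage change over a
5-day (growth) or 2-day (decline) window, and wells failing quality
control (low signal, excessive failed quantifications, or an LD50 before
neuronal maturation) are excluded before donor-level aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    InsufficientDataError,
    QuantificationError,
    ReferenceDayError,
)

#: Sentinel stored for a day whose neurite quantification failed.
FAILED = None

GROUPS = ("control", "SALS", "FALS", "PLS")


@dataclass
class WellSeries:
    """One well's longitudinal total-neurite-length record.

    ``observations`` maps integer day (day of differentiation) to total
    neurite length in µm, or ``None`` for a day on which quantification
    failed. Failed days are part of the acquisition calendar and count
    toward the QC failed fraction; absent days were never scheduled.
    """

    well_id: str
    donor_id: str
    group: str = "control"
    treatment: Optional[str] = None
    dose_uM: float = 0.0
    observations: Dict[int, Optional[float]] = field(default_factory=dict)
    endpoint_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.endpoint_day is None and self.observations:
            self.endpoint_day = max(self.observations)
        for day, value in self.observations.items():
            if value is not None and value < 0:
                raise QuantificationError(
                    f"negative neurite length {value} on day {day} in {self.well_id}"
                )

    # -- helpers -----------------------------------------------------------
    def observed(self) -> Dict[int, float]:
        """Day → length for non-failed days, in day order."""
        return {
            d: v for d, v in sorted(self.observations.items()) if v is not None
        }

    def scheduled_days(self) -> List[int]:
        return sorted(self.observations)

    def failed_days(self) -> List[int]:
        return sorted(d for d, v in self.observations.items() if v is None)

    def peak(self) -> Tuple[int, float]:
        """(peak_day, peak_um); peak_day is the earliest day attaining the max."""
        obs = self.observed()
        if not obs:
            raise QuantificationError(f"well {self.well_id}: all days failed")
        peak_um = max(obs.values())
        if peak_um <= 0:
            raise QuantificationError(f"well {self.well_id}: all-zero series")
        peak_day = min(d for d, v in obs.items() if v == peak_um)
        return peak_day, peak_um


@dataclass
class QCConfig:
    """Well-exclusion thresholds.

    Defaults follow the screening protocol: wells are excluded when total
    neurite length never reaches 12,500 µm, when more than 25% of scheduled
    time points failed quantification (not counting days 50–60, where
    failure can be caused by genuine degeneration), or when the LD50 falls
    before day 39, i.e. before the neurons have matured.
    """

    min_length_um: float = 12_500.0
    max_failed_fraction: float = 0.25
    failure_exempt_window: Tuple[int, int] = (50, 60)
    min_ld50_day: int = 39

    def __post_init__(self) -> None:
        if self.min_length_um <= 0 or self.min_ld50_day <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.max_failed_fraction < 1:
            raise ValueError("max_failed_fraction must be in (0, 1)")


@dataclass
class WellPhenotype:
    well_id: str
    donor_id: str
    group: str
    treatment: Optional[str]
    dose_uM: float
    peak_um: float
    peak_day: int
    normalized: Dict[int, float]
    growth_rate_pct: Optional[float]
    decline_rate_pct: Optional[float]
    ld50_day: float
    qc_status: str = "pass"
    qc_reasons: List[str] = field(default_factory=list)


@dataclass
class DonorPhenotype:
    donor_id: str
    group: str
    treatment: Optional[str]
    mean_ld50: float
    sem_ld50: float
    n_wells_pass: int
    mean_growth_rate_pct: Optional[float] = None
    mean_decline_rate_pct: Optional[float] = None


# ---------------------------------------------------------------------------
# normalization


def normalize_to_peak(series: WellSeries) -> Dict[int, float]:
    """Express each observed day as a percentage of the well's peak.

    The maximum of the returned curve is exactly 100; failed days are
    omitted rather than interpolated.
    """
    _, peak_um = series.peak()
    return {d: v / peak_um * 100.0 for d, v in series.observed().items()}


def normalize_to_reference_day(series: WellSeries, ref_day: int) -> Dict[int, float]:
    """Express each observed day as a percentage of the value on ``ref_day``.

    Used for pre-treatment normalization (e.g. percentage of the day-36
    value when drugs are added on day 36).
    """
    obs = series.observed()
    if ref_day not in obs:
        raise ReferenceDayError(
            f"well {series.well_id}: reference day {ref_day} absent or failed"
        )
    ref = obs[ref_day]
    if ref <= 0:
        raise ReferenceDayError(
            f"well {series.well_id}: reference day {ref_day} value is not positive"
        )
    return {d: v / ref * 100.0 for d, v in obs.items()}


# ---------------------------------------------------------------------------
# rates

def _max_window_change(series: WellSeries, window: int, sign: int) -> float:
    """Maximum percentage change over pairs of observed days exactly
    ``window`` days apart. ``sign=+1`` measures increase, ``-1`` decrease.
    Pairs with a failed or unscheduled partner day are skipped.
    """
    obs = series.observed()
    best = None
    for day, value in obs.items():
        later = obs.get(day + window)
        if later is None or value <= 0:
            continue
        change = sign * (later - value) / value * 100.0
        if best is None or change > best:
            best = change
    if best is None:
        raise InsufficientDataError(
            f"well {series.well_id}: no observed day pair {window} days apart"
        )
    return best


def compute_growth_rate(series: WellSeries, window: int = 5) -> float:
    """Maximum percentage increase in neurite length over ``window`` days
    (default 5). Negative for monotonically declining wells."""
    return _max_window_change(series, window, sign=+1)


def compute_decline_rate(series: WellSeries, window: int = 2) -> float:
    """Maximum percentage decrease in neurite length over ``window`` days
    (default 2). Negative for monotonically growing wells."""
    return _max_window_change(series, window, sign=-1)


# ---------------------------------------------------------------------------
# LD50


def compute_ld50(
    series: WellSeries,
    endpoint_day: Optional[int] = None,
    interpolate: bool = False,
) -> float:
    """Day at which neurite length first drops to ≤50% of the well's peak.

    The search starts at the peak day (an early sub-50% dip during growth
    does not count) and returns the experimental endpoint when the curve
    never reaches the threshold. By default the statistic is the sampled
    day of first crossing; with ``interpolate=True`` the crossing day is
    linearly interpolated between the last day above and first day at or
    below threshold.
    """
    if endpoint_day is None:
        endpoint_day = series.endpoint_day
    peak_day, peak_um = series.peak()
    threshold = 0.5 * peak_um
    obs = series.observed()
    prev_day, prev_val = peak_day, peak_um
    for day, value in obs.items():
        if day < peak_day:
            continue
        if value <= threshold:
            if interpolate and prev_val > threshold and day > prev_day:
                frac = (prev_val - threshold) / (prev_val - value)
                return prev_day + frac * (day - prev_day)
            return float(day)
        prev_day, prev_val = day, value
    return float(endpoint_day)


# ---------------------------------------------------------------------------
# QC and aggregation


def apply_qc(
    series: WellSeries,
    pheno: WellPhenotype,
    cfg: Optional[QCConfig] = None,
) -> Tuple[str, List[str]]:
    """Apply the three well-exclusion rules; reasons are cumulative.

    The failed-fraction denominator is the number of scheduled acquisition
    days outside the exempt window, and only failures outside that window
    are counted.
    """
    cfg = cfg or QCConfig()
    reasons: List[str] = []

    max_observed = max(series.observed().values(), default=0.0)
    if max_observed < cfg.min_length_um:
        reasons.append("low_signal")

    lo, hi = cfg.failure_exempt_window
    counted = [d for d in series.scheduled_days() if not lo <= d <= hi]
    failed = [d for d in series.failed_days() if not lo <= d <= hi]
    if counted and len(failed) / len(counted) > cfg.max_failed_fraction:
        reasons.append("failed_fraction")

    if pheno.ld50_day < cfg.min_ld50_day:
        reasons.append("premature_ld50")

    status = "excluded" if reasons else "pass"
    return status, reasons


def compute_phenotype(
    series: WellSeries,
    qc: Optional[QCConfig] = None,
    interpolate_ld50: bool = False,
) -> WellPhenotype:
    """Full per-well phenotype: peak, normalized curve, rates, LD50, QC."""
    peak_day, peak_um = series.peak()
    try:
        growth = compute_growth_rate(series)
    except InsufficientDataError:
        growth = None
    try:
        decline = compute_decline_rate(series)
    except InsufficientDataError:
        decline = None
    pheno = WellPhenotype(
        well_id=series.well_id,
        donor_id=series.donor_id,
        group=series.group,
        treatment=series.treatment,
        dose_uM=series.dose_uM,
        peak_um=peak_um,
        peak_day=peak_day,
        normalized=normalize_to_peak(series),
        growth_rate_pct=growth,
        decline_rate_pct=decline,
        ld50_day=compute_ld50(series, interpolate=interpolate_ld50),
    )
    pheno.qc_status, pheno.qc_reasons = apply_qc(series, pheno, qc)
    return pheno


def aggregate_donor(
    phenotypes: Sequence[WellPhenotype],
    wells_required: int = 3,
) -> DonorPhenotype:
    """Mean ± s.e.m. of LD50 and rates over a donor's QC-passing wells.

    Donors with fewer than ``wells_required`` passing wells (default 3)
    are excluded from population analyses.
    """
    passing = [p for p in phenotypes if p.qc_status == "pass"]
    if len(passing) < wells_required:
        raise InsufficientDataError(
            f"donor excluded: {len(passing)} passing wells "
            f"(minimum {wells_required})"
        )
    donor_ids = {p.donor_id for p in passing}
    if len(donor_ids) != 1:
        raise ValueError(f"wells span multiple donors: {sorted(donor_ids)}")

    ld50s = np.array([p.ld50_day for p in passing], dtype=float)
    growth = [p.growth_rate_pct for p in passing if p.growth_rate_pct is not None]
    decline = [p.decline_rate_pct for p in passing if p.decline_rate_pct is not None]
    n = len(ld50s)
    sem = float(np.std(ld50s, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return DonorPhenotype(
        donor_id=passing[0].donor_id,
        group=passing[0].group,
        treatment=passing[0].treatment,
        mean_ld50=float(np.mean(ld50s)),
        sem_ld50=sem,
        n_wells_pass=n,
        mean_growth_rate_pct=float(np.mean(growth)) if growth else None,
        mean_decline_rate_pct=float(np.mean(decline)) if decline else None,
    )
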