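"""Drug-screen analytics on per-donor LD50 phenotypes.

The screen's effect measure is "days of rescue": treated LD50 minus the
matched DMSO LD50 (positive = protection, negative = toxicity). Large
screens are instead expressed relative to the per-donor mean LD50 over all
screened treatments, on the assumption that the average treatment effect
is zero, and are truncated 5 days past the DMSO LD50 because imaging stops
there. Population summaries report per-drug mean rescue ± s.e.m.,
responder fractions, fold ratios against a reference drug, and significance
via a Kruskal–Wallis omnibus with Dunn-style per-drug comparisons against
the DMSO reference (rank formulas implemented here, with tie correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InputError, UndefinedStatisticError


@dataclass
class RescueResult:
    donor_id: str
    drug: str
    dose_uM: float
    days_of_rescue: float
    truncated: bool = False
    mode: str = "vs_dmso"


@dataclass
class ScreenSummary:
    per_drug: pd.DataFrame  # drug, mean_rescue, sem_rescue, n_donors, p_adj, significant
    n_tested: int
    n_effective: int
    percent_failed: int
    omnibus_h: float
    omnibus_p: float


# ---------------------------------------------------------------------------
# rescue arithmetic


def days_of_rescue(treated_ld50: float, dmso_ld50: float) -> float:
    """Treated LD50 − DMSO LD50, in days."""
    if not (math.isfinite(treated_ld50) and math.isfinite(dmso_ld50)):
        raise InputError("LD50 inputs must be finite")
    return treated_ld50 - dmso_ld50


def screen_relative_rescue(donor_ld50s: Mapping[str, float]) -> Dict[str, float]:
    """Per-drug rescue relative to the donor's mean LD50 over all screened
    treatments; the outputs sum to zero by construction."""
    if len(donor_ld50s) < 2:
        raise InsufficientDataError(
            "screen-relative normalization needs ≥2 treatments per donor"
        )
    mean = float(np.mean(list(donor_ld50s.values())))
    return {drug: ld50 - mean for drug, ld50 in donor_ld50s.items()}


def truncate_rescues(
    rescues: Sequence[RescueResult], dmso_ld50: float, cap_days: float = 5.0
) -> List[RescueResult]:
    """Cap positive rescues at ``cap_days`` (imaging stops 5 days past the
    DMSO LD50); negative (toxic) rescues are never truncated."""
    if cap_days <= 0:
        raise InputError("cap_days must be > 0")
    out = []
    for r in rescues:
        if r.days_of_rescue > cap_days:
            out.append(
                RescueResult(
                    r.donor_id, r.drug, r.dose_uM, cap_days, True, r.mode
                )
            )
        else:
            out.append(r)
    return out


def classify_responders(
    rescues: Mapping[str, float], threshold_days: float = 10.0
) -> Tuple[int, float, Dict[str, bool]]:
    """Fraction of donors whose rescue exceeds ``threshold_days``.

    Returns (percent responders rounded to the nearest integer, minimum
    donor rescue, per-donor responder flags).
    """
    if not rescues:
        raise InputError("no donors to classify")
    flags = {d: v > threshold_days for d, v in rescues.items()}
    pct = int(round(100.0 * sum(flags.values()) / len(flags)))
    return pct, min(rescues.values()), flags


def fold_vs_reference(mean_rescue_drug: float, mean_rescue_reference: float) -> float:
    """Rescue ratio against a reference drug, rounded to one decimal."""
    if mean_rescue_reference <= 0:
        raise UndefinedStatisticError(
            "fold change undefined for non-positive reference rescue"
        )
    return round(mean_rescue_drug / mean_rescue_reference, 1)


# ---------------------------------------------------------------------------
# rank tests (implemented from formulas)


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise InputError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        start += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction > 0:
        h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def dunn_vs_reference(
    groups: Mapping[str, Sequence[float]], reference: str
) -> Dict[str, float]:
    """Dunn's z-test of each group against the reference on the pooled
    ranks, Bonferroni-adjusted over the k−1 comparisons."""
    if reference not in groups:
        raise InputError(f"reference group {reference!r} not present")
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: Dict[str, float] = {}
    sizes: Dict[str, int] = {}
    start = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = float(ranks[start : start + arr.size].mean())
        sizes[name] = arr.size
        start += arr.size

    tie_adj = _tie_term(pooled) / (12.0 * (n - 1))
    variance_core = n * (n + 1) / 12.0 - tie_adj
    n_comp = len(names) - 1
    p_adj: Dict[str, float] = {}
    for name in names:
        if name == reference:
            continue
        se = math.sqrt(variance_core * (1.0 / sizes[name] + 1.0 / sizes[reference]))
        z = (mean_ranks[name] - mean_ranks[reference]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj[name] = min(1.0, p * n_comp)
    return p_adj


# ---------------------------------------------------------------------------
# screen summary


def summarize_screen(
    rescue_table: pd.DataFrame,
    effective_drug_calls: Optional[Sequence[str]] = None,
    reference: str = "DMSO",
    alpha: float = 0.05,
) -> ScreenSummary:
    """Population summary of a rescue table (rows = donors, columns = drugs).

    Per-drug mean ± s.e.m. across donors; omnibus Kruskal–Wallis over all
    drugs plus Dunn comparisons against the reference column (when
    present) with Bonferroni control; percent_failed counts the drugs not
    in ``effective_drug_calls`` (defaulting to the significant ones).
    """
    if rescue_table.shape[1] < 1:
        raise InputError("rescue table has no drugs")
    drugs = [c for c in rescue_table.columns if c != reference]

    groups = {c: rescue_table[c].dropna().to_numpy() for c in rescue_table.columns}
    if len(groups) >= 2:
        h, omnibus_p = kruskal_wallis(list(groups.values()))
    else:
        h, omnibus_p = float("nan"), float("nan")
    p_adj = (
        dunn_vs_reference(groups, reference)
        if reference in rescue_table.columns and len(groups) >= 2
        else {d: float("nan") for d in drugs}
    )

    rows = []
    for drug in drugs:
        vals = groups[drug]
        n = vals.size
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        p = p_adj.get(drug, float("nan"))
        rows.append(
            {
                "drug": drug,
                "mean_rescue": float(np.mean(vals)) if n else float("nan"),
                "sem_rescue": sem,
                "n_donors": n,
                "p_adj": p,
                "significant": bool(
                    omnibus_p < alpha and not math.isnan(p) and p < alpha
                ),
            }
        )
    per_drug = pd.DataFrame(rows).sort_values(
        "mean_rescue", ascending=False, ignore_index=True
    )

    if effective_drug_calls is None:
        effective = per_drug.loc[
            per_drug["significant"] & (per_drug["mean_rescue"] > 0), "drug"
        ].tolist()
    else:
        effective = list(effective_drug_calls)
    n_tested = len(drugs)
    n_effective = len([d for d in effective if d in drugs])
    percent_failed = int(round(100.0 * (n_tested - n_effective) / n_tested))
    return ScreenSummary(
        per_drug=per_drug,
        n_tested=n_tested,
        n_effective=n_effective,
        percent_failed=percent_failed,
        omnibus_h=h,
        omnibus_p=omnibus_p,
    )
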