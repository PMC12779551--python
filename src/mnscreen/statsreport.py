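"""Survival, correlation, signature and power statistics.

The LD50 day is treated as a survival time: wells or donors whose neurite
length never dropped to 50% of peak carry the endpoint day and enter the
product-limit estimate as censored. Group survival is compared with the
standard log-rank chi-square (1 df) built from observed-vs-expected events
at each distinct event time. Clinical correlations use Pearson or Spearman
coefficients (optionally on log-transformed clinical variables), gene
signature comparisons use Spearman rho with a permutation null obtained by
randomizing the order of one fold-change vector, and prospective power is
computed from the noncentral-t distribution of the two-sample t-test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import (
    InputError,
    ParameterError,
    UndefinedStatisticError,
)


@dataclass
class SurvivalRecord:
    """One unit's LD50 day; ``event=False`` marks censoring at endpoint
    (the 50% threshold was never reached)."""

    unit_id: str
    ld50_day: float
    event: bool = True
    group: str = ""

    def __post_init__(self) -> None:
        if self.ld50_day <= 0:
            raise InputError("ld50_day must be positive")


@dataclass
class KMCurve:
    """Product-limit survival step function."""

    days: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray

    def at(self, day: float) -> float:
        """S(day), right-continuous."""
        idx = np.searchsorted(self.days, day, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CorrResult:
    r: float
    p: float
    n: int
    method: str
    transform: str = "none"


@dataclass
class SignatureComparison:
    gene_ids: Sequence[str]
    logfc_invitro: np.ndarray
    logfc_reference: np.ndarray
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.logfc_invitro = np.asarray(self.logfc_invitro, dtype=float)
        self.logfc_reference = np.asarray(self.logfc_reference, dtype=float)
        if len(self.logfc_invitro) != len(self.logfc_reference):
            raise InputError("fold-change vectors must have the same length")
        if len(self.logfc_invitro) < 10:
            raise InputError("signature comparison needs ≥10 genes")
        if self.n_perm < 100:
            raise InputError("n_perm must be ≥ 100")


@dataclass
class PowerSpec:
    alpha: float = 0.05
    beta: float = 0.2
    effect_size_d: float = 1.0
    sides: str = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ParameterError("alpha and beta must lie in (0, 1)")
        if self.effect_size_d <= 0:
            raise ParameterError("effect_size_d must be > 0")
        if self.sides not in ("one", "two"):
            raise ParameterError("sides must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# survival


def km_curve(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Units censored at time t remain in the risk set at t and leave it
    afterwards without contributing an event.
    """
    if not records:
        raise InputError("no survival records")
    times = np.array([r.ld50_day for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    event_times = np.unique(times[events])
    days, surv, risks = [], [], []
    s = 1.0
    for t in event_times:
        n_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / n_risk
        days.append(t)
        surv.append(s)
        risks.append(n_risk)
    return KMCurve(np.array(days), np.array(surv), np.array(risks, dtype=int))


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> Tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p-value.

    At each distinct event time, the observed events in group A are
    compared with the hypergeometric expectation given the pooled risk
    set; the statistic is (ΣO − ΣE)²/ΣV.
    """
    t_a = np.array([r.ld50_day for r in group_a], dtype=float)
    e_a = np.array([r.event for r in group_a], dtype=bool)
    t_b = np.array([r.ld50_day for r in group_b], dtype=float)
    e_b = np.array([r.event for r in group_b], dtype=bool)
    all_t = np.concatenate([t_a, t_b])
    all_e = np.concatenate([e_a, e_b])
    if not all_e.any():
        raise UndefinedStatisticError("log-rank undefined: no events in either group")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(all_t[all_e]):
        n_a = int(np.sum(t_a >= t))
        n_b = int(np.sum(t_b >= t))
        n = n_a + n_b
        d = int(np.sum(all_e & (all_t == t)))
        d_a = int(np.sum(e_a & (t_a == t)))
        if n == 0:
            continue
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# correlation


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum((ry - ry.mean()) ** 2))
    rhos = (permuted - ry.mean()) @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_clinical(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    log_transform: bool = False,
) -> CorrResult:
    """Pairwise-complete correlation of a donor statistic against a
    clinical variable, with optional log transform of the clinical values
    (used when they are log-normally distributed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InputError("need at least 3 complete pairs")
    if log_transform:
        if np.any(y <= 0):
            raise InputError("log transform requires positive clinical values")
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        if len(x) < 10:
            p = _spearman_exact_p(x, y, r)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return CorrResult(
        float(r), float(p), len(x), method, "log" if log_transform else "none"
    )


def signature_correlation(
    comparison: SignatureComparison,
) -> Tuple[float, float, Dict[str, float]]:
    """Spearman rho between paired log2 fold-change vectors with a
    randomized-order control.

    The null distribution is built by permuting the reference vector's
    order ``n_perm`` times under the comparison's seed. Returns
    (rho, analytic two-sided p, null summary with the permutation
    quantile).
    """
    x = comparison.logfc_invitro
    y = comparison.logfc_reference
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(comparison.seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum((ry - ry.mean()) ** 2))
    null = np.empty(comparison.n_perm)
    for i in range(comparison.n_perm):
        null[i] = (rng.permutation(ry) - ry.mean()) @ rx_c / denom
    perm_p = (1.0 + np.sum(np.abs(null) >= abs(rho))) / (comparison.n_perm + 1.0)
    summary = {
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "perm_p": float(perm_p),
        "n_perm": comparison.n_perm,
    }
    return float(rho), float(p), summary


# ---------------------------------------------------------------------------
# power


def plot_survival(curves: Dict[str, KMCurve], path) -> None:
    """Step plot of Kaplan–Meier curves per group (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        days = np.concatenate([[0], curve.days])
        surv = np.concatenate([[1.0], curve.survival])
        ax.step(days, surv, where="post", label=label)
    ax.set_xlabel("day")
    ax.set_ylabel("LD50 probability of survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation(x, y, result: CorrResult, path) -> None:
    """Scatter with least-squares fit line, annotated with r and p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18)
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="crimson")
    ax.set_title(f"{result.method} r = {result.r:.2f}, p = {result.p:.3g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def t_test_power(n_per_group: int, spec: PowerSpec) -> float:
    """Power of the two-sample t-test at ``n_per_group`` per arm."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = spec.effect_size_d * math.sqrt(n_per_group / 2.0)
    if spec.sides == "two":
        crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(
            stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
        )
    crit = stats.t.ppf(1.0 - spec.alpha, df)
    return float(stats.nct.sf(crit, df, nc))


def required_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest per-group n whose two-sample t-test power reaches 1 − β."""
    target = 1.0 - spec.beta
    for n in range(2, n_max + 1):
        if t_test_power(n, spec) >= target:
            return n
    raise UndefinedStatisticError(
        f"required sample size exceeds n_max={n_max} for d={spec.effect_size_d}"
    )
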