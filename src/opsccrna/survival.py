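"""Expression-binarized survival analysis.

Quantile binarization (Q3 of TPM for genes, median of raw counts for
miRNAs), the Kaplan-Meier product-limit estimator, the two-group log-rank
test, and restricted mean survival time (RMST) — the area under the KM
curve up to a truncation time tau.

Conventions: the "high" arm is strictly greater than the cutoff (type-7
quantile), which keeps the high group the minority at Q3 under ties;
censored subjects leave the risk set after their time, with events ordered
before censorings at tied times; tau defaults to the smaller of the two
arms' largest observed times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import SurvivalTable


@dataclass
class Binarization:
    labels: pd.Series  # "high"/"low" per sample
    cutoff: float
    n_high: int
    n_low: int


def binarize_by_quantile(values: pd.Series, q: float = 0.75) -> Binarization:
    """Split samples at the type-7 empirical quantile; high = strictly above.

    Raises on a degenerate split (all values identical, or a quantile that
    leaves one side empty).
    """
    v = values.astype(float)
    if len(v) < 4:
        raise ValueError("need at least 4 samples to binarize")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if v.nunique() == 1:
        raise ValueError("degenerate split: all values identical")
    cutoff = float(np.quantile(v.to_numpy(), q, method="linear"))
    labels = pd.Series(np.where(v > cutoff, "high", "low"), index=v.index, name="arm")
    n_high = int((labels == "high").sum())
    n_low = len(labels) - n_high
    if n_high == 0 or n_low == 0:
        raise ValueError("degenerate split: one arm is empty")
    return Binarization(labels, cutoff, n_high, n_low)


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_var: np.ndarray  # variance of S at each event time (reporting only)


def km_estimator(table: SurvivalTable) -> KMCurve:
    """Product-limit survival estimate over the distinct event times."""
    if len(table) == 0:
        raise ValueError("empty survival table")
    t = table.time
    e = table.event
    event_times = np.unique(t[e == 1])
    s = 1.0
    gw = 0.0
    surv, risk, ev, gvar = [], [], [], []
    for tau in event_times:
        n_risk = int(np.sum(t >= tau))  # events precede censorings at ties
        d = int(np.sum((t == tau) & (e == 1)))
        s *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
        surv.append(s)
        risk.append(n_risk)
        ev.append(d)
        gvar.append(s**2 * gw)
    return KMCurve(event_times, np.array(surv), np.array(risk), np.array(ev), np.array(gvar))


def km_survival_at(curve: KMCurve, t: float) -> float:
    """S(t) from a fitted KM curve (right-continuous step function)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(arm_a: SurvivalTable, arm_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, two-sided p).

    At each distinct event time the observed events in arm A are compared
    with the hypergeometric expectation given the pooled risk set.
    """
    if len(arm_a) == 0 or len(arm_b) == 0:
        raise ValueError("both arms must be non-empty")
    ta, ea = arm_a.time, arm_a.event
    tb, eb = arm_b.time, arm_b.event
    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if all_event_times.size == 0:
        raise ValueError("no events in either arm")
    o_minus_e = 0.0
    var = 0.0
    for tau in all_event_times:
        na = np.sum(ta >= tau)
        nb = np.sum(tb >= tau)
        n = na + nb
        da = np.sum((ta == tau) & (ea == 1))
        db = np.sum((tb == tau) & (eb == 1))
        d = da + db
        if n <= 1:
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chisq = o_minus_e**2 / var
    return float(chisq), float(stats.chi2.sf(chisq, df=1))


def rmst_single(table: SurvivalTable, tau: float) -> float:
    """Restricted mean survival time: area under the KM curve on [0, tau]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    curve = km_estimator(table)
    times = np.concatenate([[0.0], curve.times[curve.times < tau], [tau]])
    surv = np.concatenate([[1.0], curve.survival[curve.times < tau]])
    return float(np.sum(surv * np.diff(times)))


@dataclass
class RmstResult:
    tau: float
    rmst_low: float
    rmst_high: float
    difference: float  # low - high
    n_low: int
    n_high: int


def rmst(arm_low: SurvivalTable, arm_high: SurvivalTable, tau: float | None = None) -> RmstResult:
    """Per-arm RMST and the low-minus-high difference.

    tau defaults to the smaller of the two arms' maximum observed times so
    both integrals live on a commonly observed window.
    """
    tau_max = min(arm_low.time.max(), arm_high.time.max())
    if tau is None:
        tau = float(tau_max)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > tau_max + 1e-12:
        raise ValueError(f"tau={tau} exceeds the smaller arm maximum {tau_max}")
    lo = rmst_single(arm_low, tau)
    hi = rmst_single(arm_high, tau)
    return RmstResult(tau, lo, hi, lo - hi, len(arm_low), len(arm_high))


def survival_by_expression(
    values: pd.Series, table: SurvivalTable, q: float = 0.75, tau: float | None = None
) -> dict:
    """Binarize expression, then KM + log-rank + RMST on the two arms.

    Only samples present in both the expression vector and the survival
    table are used (no imputation). Returns a dict with the binarization,
    per-arm tables, the log-rank (chisq, p) and the RmstResult.
    """
    shared = [s for s in values.index if s in table.data.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples with both expression and survival")
    b = binarize_by_quantile(values.loc[shared], q)
    sub = table.subset(shared)
    arm_high = SurvivalTable(sub.data[b.labels == "high"])
    arm_low = SurvivalTable(sub.data[b.labels == "low"])
    chisq, p = logrank_test(arm_low, arm_high)
    r = rmst(arm_low, arm_high, tau)
    return {
        "binarization": b,
        "arm_low": arm_low,
        "arm_high": arm_high,
        "logrank_chisq": chisq,
        "logrank_p": p,
        "rmst": r,
    }
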