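"""Core survival machinery.

Kaplan-Meier product-limit estimation, the two-group log-rank (Mantel-Cox)
test in a *signed z* form, and threshold-based dichotomization of a
continuous covariate (gene expression) into low/high patient groups.

Sign convention
---------------
The log-rank z is defined as ``z = (E_high - O_high) / sqrt(V)`` where
``O_high`` and ``E_high`` are the observed and expected event counts in the
high-covariate group and ``V`` the hypergeometric variance accumulated over
pooled risk sets.  Consequently ``z < 0`` means the high-expression group
experienced *more* deaths than expected (high expression adverse), and
``z > 0`` means high expression is favorable.  ``z**2`` is the usual
chi-square(1) statistic and the two-sided p-value is its upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogRankResult",
    "SplitLabels",
    "km_curve",
    "logrank",
    "dichotomize",
]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class LogRankResult:
    """Signed two-group log-rank test result.

    ``z`` carries the direction of the survival difference (negative when the
    high group dies faster than expected); ``chi_square == z**2``.
    """

    z: float
    chi_square: float
    p_two_sided: float
    n_low: int
    n_high: int
    observed_high: int
    expected_high: float

    def summary_row(self) -> dict:
        return {
            "n_low": self.n_low,
            "n_high": self.n_high,
            "observed_high": self.observed_high,
            "expected_high": self.expected_high,
            "z": self.z,
            "chi_square": self.chi_square,
            "p_two_sided": self.p_two_sided,
        }


@dataclass(frozen=True)
class SplitLabels:
    """One dichotomization of a patient series.

    ``high`` is a boolean array aligned with the input order (True = high
    group); ``threshold`` is the cut value actually applied and ``rule`` the
    rule that produced it (``median``, ``mean`` or ``rank_cut``).
    """

    high: np.ndarray
    threshold: float
    rule: str

    @property
    def n_low(self) -> int:
        return int((~self.high).sum())

    @property
    def n_high(self) -> int:
        return int(self.high.sum())


def _as_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValueError("empty survival sample")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and > 0")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        bad = sorted(set(np.unique(ev)) - {0.0, 1.0})
        raise ValueError(f"event indicator must be 0/1; found {bad}")
    return time, ev.astype(int)


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a step table.

    Returns a DataFrame with one row per distinct event time plus a leading
    time-zero row: columns ``time``, ``at_risk``, ``events``, ``survival``.
    The survival column is right-continuous, nonincreasing and starts at 1.
    """
    time, event = _as_time_event(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size

    rows = [(0.0, n, 0, 1.0)]
    surv = 1.0
    uniq = np.unique(t[e == 1])
    for tj in uniq:
        at_risk = int((t >= tj).sum())
        d = int(((t == tj) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(tj), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def _risk_tables(time, event):
    """Per-distinct-event-time totals: times, n at risk, events."""
    uniq = np.unique(time[event == 1])
    n_j = (time[:, None] >= uniq[None, :]).sum(axis=0)
    d_j = ((time[:, None] == uniq[None, :]) & (event[:, None] == 1)).sum(axis=0)
    return uniq, n_j, d_j


def logrank(time_low, event_low, time_high, event_high) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test with signed z.

    Ties at an event time are pooled within the risk set (standard
    hypergeometric variance); there is no Efron-style correction.  Raises if
    there are no events or the variance degenerates to zero.
    """
    t_lo, e_lo = _as_time_event(time_low, event_low)
    t_hi, e_hi = _as_time_event(time_high, event_high)

    time = np.concatenate([t_lo, t_hi])
    event = np.concatenate([e_lo, e_hi])
    in_high = np.concatenate(
        [np.zeros(t_lo.size, dtype=bool), np.ones(t_hi.size, dtype=bool)]
    )
    if event.sum() < 1:
        raise ValueError("log-rank undefined: no events in either group")

    uniq, n_j, d_j = _risk_tables(time, event)
    at_risk_high = (time[in_high][:, None] >= uniq[None, :]).sum(axis=0)
    events_high = (
        (time[in_high][:, None] == uniq[None, :]) & (event[in_high][:, None] == 1)
    ).sum(axis=0)

    O = float(events_high.sum())
    E = float((d_j * at_risk_high / n_j).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1.0), 0.0)
    V = float((f * (at_risk_high / n_j) * (1.0 - at_risk_high / n_j)).sum())
    if V <= _VAR_TOL:
        raise ValueError("log-rank variance is zero; groups are degenerate")

    z = (E - O) / np.sqrt(V)
    chi2 = z * z
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        z=float(z),
        chi_square=float(chi2),
        p_two_sided=p,
        n_low=t_lo.size,
        n_high=t_hi.size,
        observed_high=int(O),
        expected_high=E,
    )


def all_cut_logrank_z(expr, time, event, k_min: int, k_max: int) -> np.ndarray:
    """Signed log-rank z for every rank cut-point in ``[k_min, k_max]``.

    Patients are ranked by ``expr`` ascending (stable order on ties); cut
    ``k`` places the ``k`` smallest in the low group.  Returns an array of
    z values with NaN where the partition has zero variance.  This is the
    vectorized workhorse behind the IPP score: the at-risk/event counts of
    the high group for every cut are suffix cumulative sums over the
    expression-ordered patient-by-event-time indicator matrices, so all
    ``k_max - k_min + 1`` log-rank statistics cost one pass.
    """
    time, event = _as_time_event(time, event)
    expr = np.asarray(expr, dtype=float)
    n = time.size
    if expr.shape != time.shape:
        raise ValueError("expression and survival arrays must align")
    if not (1 <= k_min <= k_max <= n - 1):
        raise ValueError(f"invalid cut range [{k_min}, {k_max}] for n={n}")
    if event.sum() < 1:
        raise ValueError("log-rank undefined: no events")

    order = np.argsort(expr, kind="stable")
    t, e = time[order], event[order]

    uniq, n_j, d_j = _risk_tables(t, e)
    at_risk = t[:, None] >= uniq[None, :]
    ev = (t[:, None] == uniq[None, :]) & (e[:, None] == 1)
    # suffix sums: row k = counts over patients with expression rank >= k
    sa = np.cumsum(at_risk[::-1], axis=0)[::-1].astype(float)
    sb = np.cumsum(ev[::-1], axis=0)[::-1].astype(float)

    ks = np.arange(k_min, k_max + 1)
    n_hj = sa[ks]  # (n cuts) x (n event times): high-group at risk
    d_hj = sb[ks]
    O = d_hj.sum(axis=1)
    E = (d_j * n_hj / n_j).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1.0), 0.0)
    V = (f * (n_hj / n_j) * (1.0 - n_hj / n_j)).sum(axis=1)

    z = np.full(ks.size, np.nan)
    ok = V > _VAR_TOL
    z[ok] = (E[ok] - O[ok]) / np.sqrt(V[ok])
    return z


def dichotomize(values, rule: str = "median", rank_cut: int | None = None) -> SplitLabels:
    """Split patients into low/high groups by a threshold rule.

    ``median`` / ``mean``: values <= threshold go low (ties at the threshold
    deterministically low).  ``rank_cut``: the ``rank_cut`` smallest values go
    low, ties broken by stable input order.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need >= 2 patients to dichotomize")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")

    if rule in ("median", "mean"):
        threshold = float(np.median(values) if rule == "median" else np.mean(values))
        high = values > threshold
        if high.all() or not high.any():
            raise ValueError(
                f"{rule} split degenerate: all values on one side of {threshold!r}"
            )
    elif rule == "rank_cut":
        n = values.size
        if rank_cut is None or not (1 <= rank_cut <= n - 1):
            raise ValueError("rank_cut must satisfy 1 <= rank_cut <= n-1")
        order = np.argsort(values, kind="stable")
        high = np.ones(n, dtype=bool)
        high[order[:rank_cut]] = False
        threshold = float(values[order[rank_cut - 1]])
    else:
        raise ValueError(f"unknown dichotomization rule: {rule!r}")
    return SplitLabels(high=high, threshold=threshold, rule=rule)
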