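"""Non-parametric competing-risks estimation.

Aalen-Johansen cumulative incidence with a Greenwood-style (Marubini-Valsecchi)
pointwise variance, plus a delta-method standard error for the median event
time using a local-gradient density estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CIFEstimate",
    "MedianEstimate",
    "AalenJohansenEstimator",
    "aalen_johansen",
    "cif_at",
    "median_time",
    "median_estimate",
    "complete_case_filter",
]


@dataclass
class CIFEstimate:
    """Step-function estimate of one cause's cumulative incidence.

    ``jump_times`` are the distinct observed event times (any cause);
    ``values`` and ``ses`` are the estimate and its pointwise SE at each jump;
    ``surv_prev`` is the overall Kaplan-Meier survivor just before each jump.
    """

    cause: int
    jump_times: np.ndarray
    values: np.ndarray
    ses: np.ndarray | None
    n_risk: np.ndarray
    n_event_cause: np.ndarray
    n_event_total: np.ndarray
    surv_prev: np.ndarray

    @property
    def survival(self) -> np.ndarray:
        """Overall Kaplan-Meier survivor S(t) at each jump time."""
        return self.surv_prev * (1.0 - self.n_event_total / self.n_risk)


@dataclass
class MedianEstimate:
    """Median event time with a delta-method SE.

    SE(t50) = SE(F(t50)) / f(t50), with f estimated as the chord slope of F
    between the anchors l50 = max{t_i : F(t_i) <= 0.5 - eps} and
    u50 = min{t_i : F(t_i) >= 0.5 + eps} over observed jump times.
    """

    median: float | None
    se: float | None
    density: float | None
    epsilon: float
    lower_anchor: float | None
    upper_anchor: float | None


def _aj_arrays(times, events, cause: int, compute_se: bool):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty dataset")
    if np.isnan(times).any():
        raise ValueError("input contains missing times; filter or impute first")

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]

    ut, idx_start, counts = np.unique(t, return_index=True, return_counts=True)
    any_event = (e > 0).astype(float)
    cause_event = (e == cause).astype(float)
    d_any = np.add.reduceat(any_event, idx_start)
    d_k = np.add.reduceat(cause_event, idx_start)
    # risk set: everyone with time >= t_j; ties at t_j (events and censorings)
    # are all in the risk set, censorings leave after the events
    n_risk = times.size - np.concatenate(([0], np.cumsum(counts)[:-1]))

    keep = d_any > 0
    ut, d_any, d_k, n_risk = ut[keep], d_any[keep], d_k[keep], n_risk[keep]

    if ut.size == 0:  # all censored
        return (
            np.empty(0), np.empty(0),
            (np.empty(0) if compute_se else None),
            np.empty(0), np.empty(0), np.empty(0), np.empty(0),
        )

    haz = d_any / n_risk
    surv = np.cumprod(1.0 - haz)
    surv_prev = np.concatenate(([1.0], surv[:-1]))
    jumps = surv_prev * d_k / n_risk
    F = np.cumsum(jumps)

    ses = None
    if compute_se:
        ses = _greenwood_se(F, surv_prev, d_any, d_k, n_risk)
    return ut, F, ses, n_risk, d_k, d_any, surv_prev


def _greenwood_se(F, surv_prev, d_any, d_k, n_risk):
    """Marubini-Valsecchi Greenwood-style pointwise SE of the cumulative incidence.

    Var(F(t_i)) = sum_{j<=i} (F(t_i)-F(t_j))^2 d_j / (n_j (n_j - d_j))
                + sum_{j<=i} S(t_{j-1})^2 (n_j - d_kj) d_kj / n_j^3
                - 2 sum_{j<=i} (F(t_i)-F(t_j)) S(t_{j-1}) d_kj / n_j^2

    evaluated with cumulative sums. Where n_j = d_j the first term degenerates;
    the SE is carried forward from the last non-degenerate jump (with a warning
    when later jumps exist).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        a = d_any / (n_risk * (n_risk - d_any))
    degenerate = n_risk == d_any
    if degenerate.any():
        a = np.where(degenerate, 0.0, a)
        first_deg = int(np.argmax(degenerate))
        if first_deg < len(F) - 1:
            warnings.warn(
                "risk set exhausted at an interior event time; SE carried forward"
            )
    b = surv_prev**2 * (n_risk - d_k) * d_k / n_risk**3
    c = surv_prev * d_k / n_risk**2

    cA = np.cumsum(a)
    cAF = np.cumsum(a * F)
    cAF2 = np.cumsum(a * F * F)
    cB = np.cumsum(b)
    cC = np.cumsum(c)
    cCF = np.cumsum(c * F)

    var = F * F * cA - 2.0 * F * cAF + cAF2 + cB - 2.0 * F * cC + 2.0 * cCF
    var = np.clip(var, 0.0, None)
    se = np.sqrt(var)
    if degenerate.any():
        first_deg = int(np.argmax(degenerate))
        if first_deg > 0:
            se[first_deg:] = se[first_deg - 1]
        # else: single degenerate first jump, variance terms vanish anyway
    return se


def aalen_johansen(times, events, cause: int = 1, compute_se: bool = True) -> CIFEstimate:
    """Aalen-Johansen estimate of the cause-specific cumulative incidence.

    ``events`` uses 0 for censored and positive integer cause codes. At tied
    times all events are aggregated before the risk set is updated; censored
    subjects at a tied time leave the risk set after the events.
    """
    ut, F, ses, n_risk, d_k, d_any, surv_prev = _aj_arrays(times, events, cause, compute_se)
    return CIFEstimate(
        cause=cause,
        jump_times=ut,
        values=F,
        ses=ses,
        n_risk=n_risk,
        n_event_cause=d_k,
        n_event_total=d_any,
        surv_prev=surv_prev,
    )


def cif_at(cif: CIFEstimate, t, include_equal: bool = True):
    """Right-continuous step-function lookup: (value, se) at time ``t``.

    ``include_equal=False`` evaluates the left limit F(t-) instead, excluding
    a jump that falls exactly at ``t``.
    """
    t = np.asarray(t, dtype=float)
    if cif.jump_times.size == 0:
        zero = np.zeros_like(t)
        if zero.ndim == 0:
            return 0.0, 0.0
        return zero, zero.copy()
    side = "right" if include_equal else "left"
    idx = np.searchsorted(cif.jump_times, t, side=side) - 1
    value = np.where(idx >= 0, cif.values[np.maximum(idx, 0)], 0.0)
    if cif.ses is not None:
        se = np.where(idx >= 0, cif.ses[np.maximum(idx, 0)], 0.0)
    else:
        se = np.full_like(value, np.nan)
    if value.ndim == 0:
        return float(value), float(se)
    return value, se


def median_time(cif: CIFEstimate) -> float | None:
    """Smallest jump time at which the cumulative incidence reaches 0.5.

    Returns None when the estimate never reaches 0.5 (the median cannot be
    estimated, e.g. under heavy loss of cause-1 events).
    """
    idx = np.searchsorted(cif.values, 0.5, side="left")
    if idx >= len(cif.values):
        return None
    return float(cif.jump_times[idx])


def median_estimate(cif: CIFEstimate, epsilon: float = 0.01) -> MedianEstimate:
    """Median with delta-method SE via a local gradient around the median.

    The density at the median is the chord slope of the estimated cumulative
    incidence between the nearest jump times at least ``epsilon`` below and
    above 0.5. The SE is undefined (None, with a warning) when either anchor
    does not exist or the anchors coincide.
    """
    med = median_time(cif)
    if med is None:
        return MedianEstimate(None, None, None, epsilon, None, None)
    F = cif.values
    tt = cif.jump_times
    upper = np.flatnonzero(F >= 0.5 + epsilon)
    lower = np.flatnonzero(F <= 0.5 - epsilon)
    if upper.size == 0 or lower.size == 0:
        warnings.warn("median SE undefined: no jump time beyond 0.5 +/- epsilon")
        return MedianEstimate(med, None, None, epsilon, None, None)
    u50 = tt[upper[0]]
    l50 = tt[lower[-1]]
    if u50 <= l50:
        warnings.warn("median SE undefined: local-gradient anchors coincide")
        return MedianEstimate(med, None, None, epsilon, float(l50), float(u50))
    density = (F[upper[0]] - F[lower[-1]]) / (u50 - l50)
    _, se_at_med = cif_at(cif, med)
    if cif.ses is None or not np.isfinite(se_at_med):
        return MedianEstimate(med, None, float(density), epsilon, float(l50), float(u50))
    return MedianEstimate(
        median=med,
        se=float(se_at_med / density),
        density=float(density),
        epsilon=epsilon,
        lower_anchor=float(l50),
        upper_anchor=float(u50),
    )


def complete_case_filter(dataset: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose event time is missing; keep all others."""
    return dataset.loc[~dataset["time_missing"].astype(bool)].reset_index(drop=True)


class AalenJohansenEstimator(BaseEstimator):
    """Aalen-Johansen cumulative incidence estimator for one competing cause.

    Parameters
    ----------
    cause : int, default 1
        Event code whose cumulative incidence is estimated.
    compute_se : bool, default True
        Whether to compute the Greenwood-style pointwise SE.
    epsilon : float, default 0.01
        Half-width (on the probability scale) of the local gradient used for
        the delta-method SE of the median.

    Attributes
    ----------
    cif_ : CIFEstimate
    jump_times_, cumulative_incidence_, se_ : ndarray
    """

    def __init__(self, cause: int = 1, compute_se: bool = True, epsilon: float = 0.01):
        self.cause = cause
        self.compute_se = compute_se
        self.epsilon = epsilon

    def fit(self, durations, event_observed=None):
        """Fit from durations and event codes, or from a dataset DataFrame.

        Accepts either ``fit(times, events)`` with array-likes, or a dataset
        frame with ``time``/``event`` columns (which must be complete).
        """
        if event_observed is None:
            if not isinstance(durations, pd.DataFrame):
                raise ValueError("pass (durations, events) arrays or a dataset DataFrame")
            if durations["time_missing"].any():
                raise ValueError("dataset has missing times; filter or impute first")
            times = durations["time"].to_numpy(dtype=float)
            events = durations["event"].to_numpy()
        else:
            times = np.asarray(durations, dtype=float)
            events = np.asarray(event_observed)
        self.cif_ = aalen_johansen(times, events, cause=self.cause, compute_se=self.compute_se)
        self.jump_times_ = self.cif_.jump_times
        self.cumulative_incidence_ = self.cif_.values
        self.se_ = self.cif_.ses
        self.n_ = len(times)
        return self

    def cif_at(self, t, include_equal: bool = True):
        return cif_at(self.cif_, t, include_equal=include_equal)

    def median_estimate(self) -> MedianEstimate:
        return median_estimate(self.cif_, epsilon=self.epsilon)
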