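"""Synthetic registry data for competing-risks studies with bounded event times.

Emulates a stem-cell-transplant registry cohort: each subject experiences one of
three competing events — acute graft-versus-host disease (aGvHD, cause 1), graft
failure before aGvHD (cause 2) or death before aGvHD (cause 3) — at a log-normally
distributed time in days, with administrative censoring at a fixed horizon.
Times of aGvHD may then be set missing under MCAR, MAR or MNAR mechanisms; a
missing time is only known to lie in a fixed interval (L, R], by default
(0, 100] days (the standard clinical window for the acute period).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

CENSORED = 0
CAUSE_AGVHD = 1
CAUSE_GRAFT_FAILURE = 2
CAUSE_DEATH = 3

MECHANISMS = ("MCAR", "MAR", "MNAR")

DATASET_COLUMNS = [
    "id",
    "time",
    "event",
    "aux",
    "time_missing",
    "interval_left",
    "interval_right",
    "time_true",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the data-generating mechanism.

    Event types are drawn from ``event_probs``; the event time for cause *j* is
    the u-quantile of LN(mu_j, sigma_j^2), u ~ Uniform(0, 1), rounded up to a
    whole day. Any time beyond ``admin_censor_day`` is administratively censored.
    ``aux_prob`` is the Bernoulli probability of the auxiliary indicator
    (double vs single cord-blood unit), uncorrelated with event times.
    """

    n_subjects: int = 500
    n_reps: int = 1000
    event_probs: tuple[float, float, float] = (0.65, 0.25, 0.10)
    lognormal_mu: tuple[float, float, float] = (
        math.log(26.0),
        math.log(43.0),
        math.log(77.0),
    )
    lognormal_sigma: tuple[float, float, float] = (
        math.log(2.0),
        math.log(2.0),
        math.log(4.0),
    )
    admin_censor_day: float = 365.0
    aux_prob: float = 0.45
    bounds: tuple[float, float] = (0.0, 100.0)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.event_probs, dtype=float)
        if probs.size != 3 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"event_probs must be 3 nonnegative values summing to 1, got {self.event_probs}"
            )
        if len(self.lognormal_mu) != 3 or len(self.lognormal_sigma) != 3:
            raise ValueError("lognormal_mu and lognormal_sigma must have length 3")
        if any(s <= 0 for s in self.lognormal_sigma):
            raise ValueError("all lognormal_sigma must be > 0")
        left, right = self.bounds
        if not (0 <= left < right <= self.admin_censor_day):
            raise ValueError(
                f"bounds must satisfy 0 <= left < right <= admin_censor_day, got {self.bounds}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class MissingnessSpec:
    """A missing-data mechanism for aGvHD times.

    MCAR flags every record independently with probability ``fraction``
    irrespective of event type. MAR flags each cause-1 (aGvHD) record
    independently with probability ``fraction``; other records are never
    flagged. MNAR deterministically flags the ``floor(fraction * n_agvhd)``
    smallest (or largest, per ``mnar_direction``) observed aGvHD times.
    """

    mechanism: str
    fraction: float
    mnar_direction: str = "smallest"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"fraction must lie in (0, 1), got {self.fraction}")
        if self.mnar_direction not in ("smallest", "largest"):
            raise ValueError(f"mnar_direction must be 'smallest' or 'largest'")


def draw_event_type(config: SimulationConfig, rng: np.random.Generator, size=None):
    """Draw event-type codes (1, 2, 3) from the configured categorical distribution."""
    return rng.choice(np.array([1, 2, 3]), size=size, p=np.asarray(config.event_probs))


def inverse_transform_time(cause, u, config: SimulationConfig):
    """Event time in whole days for ``cause`` from a uniform draw ``u``.

    Returns ceil(exp(mu_j + sigma_j * Phi^-1(u))), the u-quantile of the
    cause's log-normal distribution rounded up to the nearest whole day.
    """
    cause = np.asarray(cause)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    mu = np.asarray(config.lognormal_mu)[cause - 1]
    sigma = np.asarray(config.lognormal_sigma)[cause - 1]
    # tiny slack keeps exact-integer quantiles (e.g. the median exp(mu)) from
    # being pushed up a day by floating-point noise
    t = np.ceil(np.exp(mu + sigma * ndtri(u)) - 1e-9)
    if t.ndim == 0:
        return float(t)
    return t


def simulate_complete(config: SimulationConfig, rng: np.random.Generator):
    """Array core of the generator: (times, events, aux) before any missingness.

    Times are positive whole days; events beyond the administrative horizon are
    replaced by censored records (event 0) at the horizon.
    """
    n = config.n_subjects
    causes = draw_event_type(config, rng, size=n)
    u = rng.uniform(size=n)
    times = inverse_transform_time(causes, u, config)
    events = causes.astype(np.int64)
    censored = times > config.admin_censor_day
    times = np.where(censored, config.admin_censor_day, times)
    events[censored] = CENSORED
    aux = (rng.uniform(size=n) < config.aux_prob).astype(np.int64)
    return times.astype(float), events, aux


def _as_frame(times, events, aux, miss=None, bounds=None, ids=None) -> pd.DataFrame:
    n = len(times)
    if ids is None:
        ids = np.arange(n)
    df = pd.DataFrame(
        {
            "id": np.asarray(ids),
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=np.int64),
            "aux": np.asarray(aux, dtype=np.int64),
            "time_missing": np.zeros(n, dtype=bool) if miss is None else np.asarray(miss),
            "interval_left": np.full(n, np.nan),
            "interval_right": np.full(n, np.nan),
            "time_true": np.asarray(times, dtype=float),
        }
    )
    if miss is not None and bounds is not None:
        df.loc[df["time_missing"], "interval_left"] = bounds[0]
        df.loc[df["time_missing"], "interval_right"] = bounds[1]
        df.loc[df["time_missing"], "time"] = np.nan
    return df


def generate_dataset(config: SimulationConfig, rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate one complete registry-style dataset (no missingness applied).

    Columns: id, time, event (0 censored / 1 aGvHD / 2 graft failure / 3 death),
    aux, time_missing, interval_left, interval_right, time_true. ``time_true``
    duplicates ``time`` here and is retained for truth-tracking after
    missingness is applied.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    times, events, aux = simulate_complete(config, rng)
    return _as_frame(times, events, aux)


def missingness_mask(
    times: np.ndarray,
    events: np.ndarray,
    spec: MissingnessSpec,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Boolean flag per record under the given mechanism.

    MNAR consumes no randomness: the mask is a deterministic function of the
    data, with ties in times broken by record order.
    """
    n = len(times)
    if spec.mechanism == "MCAR":
        return rng.uniform(size=n) < spec.fraction
    if spec.mechanism == "MAR":
        return (np.asarray(events) == CAUSE_AGVHD) & (rng.uniform(size=n) < spec.fraction)
    # MNAR: order-statistics selection among observed aGvHD events
    cand = np.flatnonzero(np.asarray(events) == CAUSE_AGVHD)
    k = int(math.floor(spec.fraction * cand.size))
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        warnings.warn("MNAR selection is empty (fraction * n_events < 1); no records flagged")
        return mask
    key = times[cand] if spec.mnar_direction == "smallest" else -times[cand]
    order = np.lexsort((cand, key))  # ties broken by record order
    mask[cand[order[:k]]] = True
    return mask


def apply_mdm(
    dataset: pd.DataFrame,
    spec: MissingnessSpec,
    rng: np.random.Generator | int | None = None,
    bounds: tuple[float, float] = (0.0, 100.0),
) -> pd.DataFrame:
    """Apply a missing-data mechanism to a complete dataset.

    Flagged records get interval ``bounds`` and a blanked ``time``;
    ``time_true`` retains the generated value for truth-tracking only.
    The input must not already contain missingness. The registry's
    "(0, day-100] or time of death" clause never binds here because flagged
    subjects all experienced aGvHD.
    """
    if dataset["time_missing"].any():
        raise ValueError("dataset already contains missingness")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    times = dataset["time_true"].to_numpy(dtype=float)
    events = dataset["event"].to_numpy()
    mask = missingness_mask(times, events, spec, rng)
    out = dataset.copy()
    out["time_missing"] = mask
    out.loc[mask, "interval_left"] = bounds[0]
    out.loc[mask, "interval_right"] = bounds[1]
    out.loc[mask, "time"] = np.nan
    return out


@dataclass(frozen=True)
class TrueEstimands:
    """Closed-form truth under the generating mechanism.

    ``median`` follows the whole-day convention of the generated data (the
    smallest integer day at which the cause-1 CIF reaches 0.5);
    ``median_root`` is the continuous-time root of CIF(t) = 0.5 before
    rounding, kept for sensitivity analyses of the truth convention.
    """

    cif: float
    median: float | None
    horizon: float
    median_root: float | None = None


def true_cif(config: SimulationConfig, t) -> np.ndarray | float:
    """Analytic cause-1 cumulative incidence P(T <= t, cause 1) = p1 * Phi((log t - mu1)/sigma1)."""
    p1 = config.event_probs[0]
    mu1 = config.lognormal_mu[0]
    s1 = config.lognormal_sigma[0]
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, p1 * ndtr((np.log(np.maximum(t, 1e-300)) - mu1) / s1), 0.0)
    return float(out) if out.ndim == 0 else out


def true_estimands(config: SimulationConfig, horizon: float = 100.0) -> TrueEstimands:
    """Analytic cause-1 CIF at ``horizon`` and the true median event day.

    The median follows the same whole-day convention as the generated data:
    the smallest integer t with CIF_1(t) >= 0.5. Undefined (None) when the
    cause-1 probability never reaches 0.5.
    """
    if horizon > config.admin_censor_day:
        raise ValueError("horizon must not exceed the administrative censoring day")
    cif_h = true_cif(config, horizon)
    p1 = config.event_probs[0]
    if p1 < 0.5:
        return TrueEstimands(cif=cif_h, median=None, horizon=horizon)
    mu1 = config.lognormal_mu[0]
    s1 = config.lognormal_sigma[0]
    root = math.exp(mu1 + s1 * ndtri(0.5 / p1))  # continuous-time median
    med = math.ceil(root)
    while med > 1 and true_cif(config, med - 1) >= 0.5:
        med -= 1
    return TrueEstimands(cif=cif_h, median=float(med), horizon=horizon, median_root=root)
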