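"""Multiple-imputation engines for bounded event times.

Five univariate engines complete a dataset whose aGvHD (cause-1) times are
missing but known to lie in an interval (L, R]:

* ``NormalImputer`` — Bayesian normal linear regression on the raw time scale,
  no restriction on imputed values (mice's "norm").
* ``LogNormalImputer`` — the same model on log(time), back-transformed.
* ``RestrictedNormalImputer`` — normal regression with per-value rejection of
  draws outside (L, R], capped at a fixed number of redraws.
* ``PMMImputer`` — predictive mean matching (types 0/1/2): copies an observed
  donor time whose predicted mean is close to the target's.
* ``CIFSamplingImputer`` — samples observed cause-1 times inside the target's
  bounds with probability proportional to the current Aalen-Johansen
  cumulative-incidence jump, iteratively refreshed (Delord & Genin style).

The imputation model regresses time on an intercept, event-type indicators
(reference: aGvHD) and optionally the auxiliary covariate, fitted to all
records with an observed event time. Administratively censored records are
excluded from the regression: their times are censoring horizons, not event
times. Every engine is a scikit-learn style transformer: ``fit(X)`` then
``transform(X)`` returning a list of m completed DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimators import _aj_arrays
from .simulate import CAUSE_AGVHD, CENSORED

__all__ = [
    "LinearModelDraw",
    "build_design",
    "draw_posterior",
    "pmm_distance",
    "NormalImputer",
    "LogNormalImputer",
    "RestrictedNormalImputer",
    "PMMImputer",
    "CIFSamplingImputer",
    "complete_dataset",
    "make_imputer",
    "METHOD_NAMES",
]


@dataclass
class LinearModelDraw:
    """OLS fit plus one draw from the standard noninformative posterior.

    sigma_star**2 = SSE / chi2(h - q); beta_star ~ N(beta_hat, sigma_star**2 (Z'Z)^-1).
    """

    beta_hat: np.ndarray
    beta_star: np.ndarray
    sigma_star: float
    columns: list[str]


def build_design(events, aux, include_aux: bool, reference: int = CAUSE_AGVHD):
    """Predictor matrix: intercept + event-type indicators + optional aux.

    The reference event level (aGvHD by default) carries no indicator, so a
    record missing its time (always aGvHD here) has all indicators zero.
    Indicator columns for levels absent from the data are dropped with a
    warning. Censored records should be excluded by the caller.
    """
    events = np.asarray(events)
    aux = np.asarray(aux, dtype=float)
    cols = [np.ones(len(events))]
    names = ["intercept"]
    for level in (2, 3):
        if level == reference:
            continue
        col = (events == level).astype(float)
        cols.append(col)
        names.append(f"event_{level}")
    if include_aux:
        cols.append(aux)
        names.append("aux")
    Z = np.column_stack(cols)
    return Z, names


def _drop_empty_levels(Z_obs, Z_mis, names):
    """Drop indicator columns with no observed-outcome rows (degenerate design)."""
    keep = []
    for j, name in enumerate(names):
        if name == "intercept" or Z_obs[:, j].any():
            keep.append(j)
        else:
            warnings.warn(f"design column {name!r} has no observed rows; dropped")
    keep = np.array(keep)
    return Z_obs[:, keep], Z_mis[:, keep], [names[j] for j in keep]


def draw_posterior(y, Z, rng: np.random.Generator, columns=None) -> LinearModelDraw:
    """One draw from the posterior of a normal linear model with flat priors.

    beta_hat is the OLS fit; sigma_star**2 = SSE / chi2_{h-q} and
    beta_star ~ N(beta_hat, sigma_star**2 (Z'Z)^-1). Requires h >= q + 1 rows.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    h, q = Z.shape
    if h < q + 1:
        raise ValueError(f"need at least {q + 1} observed rows for {q} predictors, got {h}")
    ztz = Z.T @ Z
    rank = np.linalg.matrix_rank(ztz)
    if rank < q:
        bad = columns if columns is not None else list(range(q))
        raise np.linalg.LinAlgError(f"singular design; collinear columns among {bad}")
    beta_hat = np.linalg.solve(ztz, Z.T @ y)
    resid = y - Z @ beta_hat
    sse = float(resid @ resid)
    df = h - q
    if sse <= 0.0:
        # degenerate zero-residual posterior
        return LinearModelDraw(beta_hat, beta_hat.copy(), 0.0, list(columns or []))
    sigma_star = float(np.sqrt(sse / rng.chisquare(df)))
    cov_chol = np.linalg.cholesky(np.linalg.inv(ztz))
    beta_star = beta_hat + sigma_star * cov_chol @ rng.standard_normal(q)
    return LinearModelDraw(beta_hat, beta_star, sigma_star, list(columns or []))


def pmm_distance(z_i, z_h, draw: LinearModelDraw, pmm_type: int = 1):
    """Predictive distance between a target and a donor.

    type 0: |beta_hat z_i - beta_hat z_h|; type 1: |beta_star z_i - beta_hat z_h|;
    type 2: |beta_star z_i - beta_star z_h|.
    """
    z_i = np.asarray(z_i, dtype=float)
    z_h = np.asarray(z_h, dtype=float)
    if pmm_type == 0:
        return abs(float(z_i @ draw.beta_hat - z_h @ draw.beta_hat))
    if pmm_type == 1:
        return abs(float(z_i @ draw.beta_star - z_h @ draw.beta_hat))
    if pmm_type == 2:
        return abs(float(z_i @ draw.beta_star - z_h @ draw.beta_star))
    raise ValueError(f"pmm_type must be 0, 1 or 2, got {pmm_type}")


@dataclass
class _ImputationProblem:
    """Array view of one incomplete dataset, shared by all engines."""

    times: np.ndarray        # observed times, NaN where missing
    events: np.ndarray
    aux: np.ndarray
    miss: np.ndarray         # boolean mask of missing times
    left: np.ndarray         # interval bounds, aligned with miss rows
    right: np.ndarray


def _problem_from_frame(X: pd.DataFrame) -> _ImputationProblem:
    miss = X["time_missing"].to_numpy(dtype=bool)
    left = X["interval_left"].to_numpy(dtype=float)
    right = X["interval_right"].to_numpy(dtype=float)
    if miss.any() and (np.isnan(left[miss]).any() or np.isnan(right[miss]).any()):
        raise ValueError("flagged records must carry interval bounds")
    return _ImputationProblem(
        times=X["time"].to_numpy(dtype=float),
        events=X["event"].to_numpy(),
        aux=X["aux"].to_numpy(),
        miss=miss,
        left=left,
        right=right,
    )


def complete_dataset(X: pd.DataFrame, imputed: np.ndarray, allow_nonpositive: bool = False) -> pd.DataFrame:
    """Fill flagged records with imputed times (event set to aGvHD), clear flags.

    Imputed values are left continuous — they are not rounded to whole days.
    Non-positive values are rejected unless ``allow_nonpositive`` (the
    unrestricted normal engine can legitimately produce them; that pathology
    is retained rather than masked).
    """
    miss = X["time_missing"].to_numpy(dtype=bool)
    imputed = np.asarray(imputed, dtype=float)
    if imputed.shape != (int(miss.sum()),):
        raise ValueError("need exactly one imputed value per flagged record")
    if not allow_nonpositive and (imputed <= 0).any():
        raise ValueError("imputed times must be positive for this method")
    out = X.copy()
    out.loc[miss, "time"] = imputed
    out.loc[miss, "event"] = CAUSE_AGVHD
    out["time_missing"] = False
    out.loc[:, ["interval_left", "interval_right"]] = np.nan
    return out


class _BaseTimeImputer(BaseEstimator):
    """Shared fit/transform machinery for the five engines."""

    _allow_nonpositive = False

    def __init__(self, m: int = 5, include_aux: bool = True, random_state=None):
        self.m = m
        self.include_aux = include_aux
        self.random_state = random_state

    def _validate(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")

    def fit(self, X: pd.DataFrame, y=None):
        self._validate()
        prob = _problem_from_frame(X)
        if not (~prob.miss).any() or not np.isfinite(prob.times[~prob.miss]).any():
            raise ValueError("no observed event times to fit the imputation model")
        self.n_missing_ = int(prob.miss.sum())
        self.is_fitted_ = True
        return self

    def transform(self, X: pd.DataFrame) -> list[pd.DataFrame]:
        """Return a list of m completed copies of ``X``."""
        if not getattr(self, "is_fitted_", False):
            self.fit(X)
        prob = _problem_from_frame(X)
        rng = np.random.default_rng(self.random_state)
        draws = self.impute_times(prob, rng)
        return [
            complete_dataset(X, draws[k], allow_nonpositive=self._allow_nonpositive)
            for k in range(self.m)
        ]

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> list[pd.DataFrame]:
        return self.fit(X).transform(X)

    # --- array API used by the simulation harness ---------------------------
    def impute_times(self, prob: _ImputationProblem, rng: np.random.Generator) -> np.ndarray:
        """(m, n_missing) array of imputed times for the flagged records."""
        raise NotImplementedError


class _RegressionImputer(_BaseTimeImputer):
    """Engines built on the normal linear imputation model."""

    def _prepare(self, prob: _ImputationProblem):
        obs = ~prob.miss & (prob.events != CENSORED)
        y = prob.times[obs]
        Z_obs, names = build_design(prob.events[obs], prob.aux[obs], self.include_aux)
        Z_mis, _ = build_design(prob.events[prob.miss], prob.aux[prob.miss], self.include_aux)
        Z_obs, Z_mis, names = _drop_empty_levels(Z_obs, Z_mis, names)
        return y, Z_obs, Z_mis, names, obs


class NormalImputer(_RegressionImputer):
    """Unrestricted normal-model imputation on the raw time scale.

    Each imputation takes one posterior draw (beta_star, sigma_star) and sets
    every missing time to z_i beta_star + sigma_star * e_i with standard-normal
    e_i. Values may be negative or exceed the interval bound — by design.
    """

    _allow_nonpositive = True

    def impute_times(self, prob, rng):
        y, Z_obs, Z_mis, names, _ = self._prepare(prob)
        nm = Z_mis.shape[0]
        out = np.empty((self.m, nm))
        for k in range(self.m):
            draw = draw_posterior(y, Z_obs, rng, columns=names)
            out[k] = Z_mis @ draw.beta_star + draw.sigma_star * rng.standard_normal(nm)
        return out


class LogNormalImputer(_RegressionImputer):
    """Normal-model imputation on log(time), back-transformed by exp.

    Imputed times are strictly positive by construction. Observed times must
    be >= 1 day (guaranteed by the whole-day rounding of the generator).
    """

    def impute_times(self, prob, rng):
        y, Z_obs, Z_mis, names, _ = self._prepare(prob)
        if (y <= 0).any():
            raise ValueError("log-scale imputation requires strictly positive observed times")
        nm = Z_mis.shape[0]
        out = np.empty((self.m, nm))
        for k in range(self.m):
            draw = draw_posterior(np.log(y), Z_obs, rng, columns=names)
            out[k] = np.exp(Z_mis @ draw.beta_star + draw.sigma_star * rng.standard_normal(nm))
        return out


class RestrictedNormalImputer(_RegressionImputer):
    """Normal-model imputation with rejection of values outside (L, R].

    For each missing value the residual is redrawn (keeping beta_star and
    sigma_star for the imputation) until the value falls inside the record's
    bounds or ``rejection_cap`` draws are exhausted, in which case the last
    draw is kept even if out of bounds. ``n_out_of_bounds_`` counts such
    values over the most recent call. Because a kept exhausted draw can fall
    anywhere, positivity is not guaranteed (same documented pathology as the
    unrestricted engine).
    """

    _allow_nonpositive = True

    def __init__(self, m: int = 5, include_aux: bool = True, rejection_cap: int = 200,
                 random_state=None):
        super().__init__(m=m, include_aux=include_aux, random_state=random_state)
        self.rejection_cap = rejection_cap

    def _validate(self):
        super()._validate()
        if self.rejection_cap < 1:
            raise ValueError("rejection_cap must be >= 1")

    def impute_times(self, prob, rng):
        y, Z_obs, Z_mis, names, _ = self._prepare(prob)
        nm = Z_mis.shape[0]
        L = prob.left[prob.miss]
        R = prob.right[prob.miss]
        out = np.empty((self.m, nm))
        self.n_out_of_bounds_ = 0
        for k in range(self.m):
            draw = draw_posterior(y, Z_obs, rng, columns=names)
            mean = Z_mis @ draw.beta_star
            vals = mean + draw.sigma_star * rng.standard_normal(nm)
            oob = (vals <= L) | (vals > R)
            for _ in range(self.rejection_cap - 1):
                if not oob.any():
                    break
                idx = np.flatnonzero(oob)
                vals[idx] = mean[idx] + draw.sigma_star * rng.standard_normal(idx.size)
                oob = (vals <= L) | (vals > R)
            self.n_out_of_bounds_ += int(oob.sum())
            out[k] = vals
        return out


class PMMImputer(_RegressionImputer):
    """Predictive mean matching: copy an observed time from a nearby donor.

    For each missing record the predictive distance to every record with an
    observed event time is computed (``pmm_type`` 0, 1 or 2 selects which of
    beta_hat/beta_star enters each side), the ``donor_pool_size`` closest
    donors form the pool and one is selected uniformly at random. Imputed
    values are therefore a subset of the observed times. Distance ties are
    broken by donor order after a random permutation, so tie-breaking is
    reproducible under a seed but carries no systematic preference.
    """

    def __init__(self, m: int = 5, include_aux: bool = True, pmm_type: int = 1,
                 donor_pool_size: int = 5, random_state=None):
        super().__init__(m=m, include_aux=include_aux, random_state=random_state)
        self.pmm_type = pmm_type
        self.donor_pool_size = donor_pool_size

    def _validate(self):
        super()._validate()
        if self.pmm_type not in (0, 1, 2):
            raise ValueError("pmm_type must be 0, 1 or 2")
        if self.donor_pool_size < 1:
            raise ValueError("donor_pool_size must be >= 1")

    def impute_times(self, prob, rng):
        y, Z_obs, Z_mis, names, _ = self._prepare(prob)
        nm = Z_mis.shape[0]
        h = Z_obs.shape[0]
        pool = self.donor_pool_size
        if h < pool:
            warnings.warn(f"only {h} donors available; shrinking pool from {pool}")
            pool = h
        out = np.empty((self.m, nm))
        for k in range(self.m):
            draw = draw_posterior(y, Z_obs, rng, columns=names)
            target_beta = draw.beta_hat if self.pmm_type == 0 else draw.beta_star
            donor_beta = draw.beta_star if self.pmm_type == 2 else draw.beta_hat
            pred_target = Z_mis @ target_beta
            pred_donor = Z_obs @ donor_beta
            perm = rng.permutation(h)
            dist = np.abs(pred_target[:, None] - pred_donor[perm][None, :])
            nearest = np.argsort(dist, axis=1, kind="stable")[:, :pool]
            pick = rng.integers(pool, size=nm)
            donors = perm[nearest[np.arange(nm), pick]]
            out[k] = y[donors]
        return out


class CIFSamplingImputer(_BaseTimeImputer):
    """Impute by sampling observed cause-1 times from the current CIF.

    Candidates for a missing record are the observed aGvHD event times inside
    its bounds (L, R]; the sampling probability of each candidate is
    proportional to the jump of the current Aalen-Johansen cause-1 cumulative
    incidence at that time, and the estimate is refreshed from the completed
    data over ``n_iterations`` sweeps. Starting values are drawn uniformly
    from the candidate set. Records with an empty candidate set fall back to
    the interval midpoint, with a warning.
    """

    def __init__(self, m: int = 5, include_aux: bool = True, n_iterations: int = 10,
                 random_state=None):
        # include_aux accepted for interface parity; the sampler is
        # covariate-free (candidate sets depend only on bounds)
        super().__init__(m=m, include_aux=include_aux, random_state=random_state)
        self.n_iterations = n_iterations

    def _validate(self):
        super()._validate()
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def impute_times(self, prob, rng):
        miss_idx = np.flatnonzero(prob.miss)
        nm = miss_idx.size
        obs_mask = ~prob.miss
        obs_c1_times = np.unique(
            prob.times[obs_mask & (prob.events == CAUSE_AGVHD)]
        )
        L = prob.left[prob.miss]
        R = prob.right[prob.miss]
        # candidate sets grouped by shared bounds
        groups: dict[tuple[float, float], np.ndarray] = {}
        cand_for: list[np.ndarray] = []
        fallback = np.zeros(nm, dtype=bool)
        for i in range(nm):
            key = (L[i], R[i])
            if key not in groups:
                groups[key] = obs_c1_times[(obs_c1_times > L[i]) & (obs_c1_times <= R[i])]
            cand_for.append(groups[key])
            if groups[key].size == 0:
                fallback[i] = True
        if fallback.any():
            warnings.warn(
                f"{int(fallback.sum())} records have no observed cause-1 time inside "
                "their bounds; imputed at the interval midpoint"
            )
        out = np.empty((self.m, nm))
        times_work = prob.times.copy()
        events_work = prob.events.copy()
        events_work[miss_idx] = CAUSE_AGVHD
        for k in range(self.m):
            vals = np.empty(nm)
            for i in range(nm):
                if fallback[i]:
                    vals[i] = 0.5 * (L[i] + R[i])
                else:
                    vals[i] = rng.choice(cand_for[i])
            for _ in range(self.n_iterations):
                times_work[miss_idx] = vals
                jt, F, _, _, d_k, _, surv_prev = _aj_arrays(
                    times_work, events_work, CAUSE_AGVHD, compute_se=False
                )
                jump = np.diff(np.concatenate(([0.0], F)))
                for key, cand in groups.items():
                    sel = np.flatnonzero((L == key[0]) & (R == key[1]) & ~fallback)
                    if sel.size == 0 or cand.size == 0:
                        continue
                    pos = np.searchsorted(jt, cand)
                    w = np.where(
                        (pos < len(jt)) & (jt[np.minimum(pos, len(jt) - 1)] == cand),
                        jump[np.minimum(pos, len(jt) - 1)],
                        0.0,
                    )
                    if w.sum() <= 0:
                        w = np.ones(cand.size)
                    vals[sel] = rng.choice(cand, size=sel.size, p=w / w.sum())
            out[k] = vals
        return out


METHOD_NAMES = (
    "NORM",
    "NORMNOAUX",
    "LOGNORM",
    "RESNORM",
    "PMM",
    "PMMNOAUX",
    "MICI",
)


def make_imputer(method: str, m: int = 5, random_state=None, **kwargs) -> _BaseTimeImputer:
    """Imputer factory keyed by the study's method labels.

    NORM/NORMNOAUX, LOGNORM, RESNORM, PMM/PMMNOAUX (type 1), MICI
    (CIF-conditional sampling). The NOAUX variants drop the auxiliary
    covariate from the imputation model.
    """
    name = method.upper()
    if name == "NORM":
        return NormalImputer(m=m, include_aux=True, random_state=random_state, **kwargs)
    if name == "NORMNOAUX":
        return NormalImputer(m=m, include_aux=False, random_state=random_state, **kwargs)
    if name == "LOGNORM":
        return LogNormalImputer(m=m, include_aux=True, random_state=random_state, **kwargs)
    if name == "RESNORM":
        return RestrictedNormalImputer(m=m, include_aux=True, random_state=random_state, **kwargs)
    if name == "PMM":
        return PMMImputer(m=m, include_aux=True, random_state=random_state, **kwargs)
    if name == "PMMNOAUX":
        return PMMImputer(m=m, include_aux=False, random_state=random_state, **kwargs)
    if name == "MICI":
        return CIFSamplingImputer(m=m, random_state=random_state, **kwargs)
    raise ValueError(f"unknown imputation method {method!r}; choose from {METHOD_NAMES}")
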