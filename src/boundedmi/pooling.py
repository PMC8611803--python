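"""Rubin's rules: combining per-imputation estimates and standard errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PooledEstimate", "rubin_pool"]


@dataclass
class PooledEstimate:
    """Pooled point estimate and SE across m imputations.

    se**2 = within_var + (1 + 1/m) * between_var, where within_var is the
    mean squared per-imputation SE and between_var the sample variance of the
    per-imputation estimates. ``n_undefined`` counts imputations whose
    estimate was undefined and was dropped before pooling. No small-m
    degrees-of-freedom adjustment is applied (the study reports SEs, not
    confidence intervals).
    """

    estimate: float
    se: float
    m: int
    within_var: float
    between_var: float
    n_undefined: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.estimate)


def rubin_pool(estimates, ses) -> PooledEstimate:
    """Pool per-imputation (estimate, SE) pairs by Rubin's rules.

    Imputations with an undefined (None/NaN) estimate are dropped and counted;
    at least two defined estimates are required, otherwise the pooled result
    is undefined (NaN fields). If any retained imputation lacks a defined SE,
    the pooled SE is undefined while the pooled estimate is still returned.
    """
    est = np.array(
        [np.nan if e is None else float(e) for e in estimates], dtype=float
    )
    se = np.array([np.nan if s is None else float(s) for s in ses], dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    ok = np.isfinite(est)
    n_undef = int((~ok).sum())
    m = int(ok.sum())
    if m < 2:
        return PooledEstimate(np.nan, np.nan, m, np.nan, np.nan, n_undef)
    est = est[ok]
    se = se[ok]
    qbar = float(est.mean())
    between = float(est.var(ddof=1))
    if np.isfinite(se).all():
        within = float(np.mean(se**2))
        total = within + (1.0 + 1.0 / m) * between
        pooled_se = float(np.sqrt(total))
    else:
        within = np.nan
        pooled_se = np.nan
    return PooledEstimate(qbar, pooled_se, m, within, between, n_undef)
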