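"""Monte-Carlo study harness: factorial comparison of missing-data methods.

Runs the full pipeline per replicate — generate a registry-style dataset,
apply a missingness mechanism, handle it (complete-case analysis or multiple
imputation with Rubin pooling), estimate the day-100 cause-1 cumulative
incidence and the median event time — and summarizes each
method x mechanism x fraction cell by standardized bias and average
model-based SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import aalen_johansen, cif_at, median_estimate
from .imputers import _ImputationProblem, make_imputer
from .pooling import rubin_pool
from .simulate import (
    CAUSE_AGVHD,
    MissingnessSpec,
    SimulationConfig,
    missingness_mask,
    simulate_complete,
    true_estimands,
)

__all__ = [
    "StudyDesign",
    "run_replicate",
    "run_study",
    "standardized_bias",
    "avg_model_se",
    "plot_results",
]

ESTIMANDS = ("cif", "median")

_MECH_INDEX = {"NONE": 0, "MCAR": 1, "MAR": 2, "MNAR": 3}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of a simulation study.

    ``methods`` may include FULL (no missingness, calibration arm), CCA and
    the imputation engines NORM/NORMNOAUX/LOGNORM/RESNORM/PMM/PMMNOAUX/MICI.
    MCAR cells run only CCA (and FULL): under MCAR missingness ignores event
    type, so event-type-conditional imputation is out of scope of the design.
    """

    methods: tuple[str, ...] = ("CCA", "PMM")
    mechanisms: tuple[str, ...] = ("MAR",)
    fractions: tuple[float, ...] = (0.1, 0.3, 0.5)
    n_reps: int = 1000
    m: int = 5
    base_seed: int = 0
    epsilon: float = 0.01
    horizon: float = 100.0
    mnar_direction: str = "smallest"
    truth: str = "analytic"  # or "empirical": full-data mean as the truth

    def __post_init__(self):
        if not self.methods or not self.mechanisms or not self.fractions:
            raise ValueError("methods, mechanisms and fractions must be non-empty")
        if self.truth not in ("analytic", "empirical"):
            raise ValueError("truth must be 'analytic' or 'empirical'")


def _estimate_pair(times, events, horizon, epsilon):
    """(cif, cif_se, median, median_se) from one complete sample; NaN when undefined."""
    cif = aalen_johansen(times, events, cause=CAUSE_AGVHD, compute_se=True)
    value, se = cif_at(cif, horizon)
    med = median_estimate(cif, epsilon=epsilon)
    return (
        value,
        se,
        np.nan if med.median is None else med.median,
        np.nan if med.se is None else med.se,
    )


def _method_rng(base_seed, rep, mechanism, fraction, method_idx):
    return np.random.default_rng(
        [base_seed, rep, _MECH_INDEX[mechanism], int(round(fraction * 1000)), method_idx]
    )


def run_replicate(
    config: SimulationConfig,
    mechanism: str | None,
    fraction: float,
    methods,
    rep: int,
    base_seed: int = 0,
    m: int = 5,
    epsilon: float = 0.01,
    horizon: float = 100.0,
    mnar_direction: str = "smallest",
):
    """One replicate of one design cell.

    Returns {method: {"cif": (est, se), "median": (est, se)}}. The generation
    stream is seeded ``base_seed + rep`` so every cell sees the same complete
    data for a given replicate; the missingness stream depends only on the
    cell, so every method within a cell sees the same incomplete data.
    """
    rng_data = np.random.default_rng(base_seed + rep)
    times, events, aux = simulate_complete(config, rng_data)
    n = len(times)

    if mechanism is None or mechanism == "NONE":
        mask = np.zeros(n, dtype=bool)
        mechanism = "NONE"
    else:
        spec = MissingnessSpec(mechanism, fraction, mnar_direction)
        rng_miss = _method_rng(base_seed, rep, mechanism, fraction, 1_000_000)
        mask = missingness_mask(times, events, spec, rng_miss)

    out = {}
    for method_idx, method in enumerate(methods):
        name = method.upper()
        if name == "FULL":
            out[method] = _pack(_estimate_pair(times, events, horizon, epsilon))
        elif name == "CCA":
            keep = ~mask
            out[method] = _pack(_estimate_pair(times[keep], events[keep], horizon, epsilon))
        else:
            imputer = make_imputer(name, m=m)
            prob = _ImputationProblem(
                times=np.where(mask, np.nan, times),
                events=events,
                aux=aux,
                miss=mask,
                left=np.where(mask, config.bounds[0], np.nan),
                right=np.where(mask, config.bounds[1], np.nan),
            )
            rng_m = _method_rng(base_seed, rep, mechanism, fraction, method_idx)
            draws = imputer.impute_times(prob, rng_m)
            ests = {e: ([], []) for e in ESTIMANDS}
            t_work = times.copy()
            e_work = events.copy()
            e_work[mask] = CAUSE_AGVHD
            for k in range(m):
                t_work[mask] = draws[k]
                cv, cs, mv, ms = _estimate_pair(t_work, e_work, horizon, epsilon)
                ests["cif"][0].append(cv)
                ests["cif"][1].append(cs)
                ests["median"][0].append(mv)
                ests["median"][1].append(ms)
            pooled = {e: rubin_pool(*ests[e]) for e in ESTIMANDS}
            out[method] = {
                e: (pooled[e].estimate, pooled[e].se) for e in ESTIMANDS
            }
    return out


def _pack(quad):
    cv, cs, mv, ms = quad
    return {"cif": (cv, cs), "median": (mv, ms)}


def standardized_bias(estimates, truth: float) -> float:
    """(mean - truth) / SD of the replicate estimates (SD with denominator n-1).

    Undefined estimates are dropped; NaN is returned (with a warning) when
    fewer than two remain or the SD is zero.
    """
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size < 2:
        warnings.warn("standardized bias undefined: fewer than 2 defined estimates")
        return np.nan
    sd = est.std(ddof=1)
    if sd == 0.0:
        warnings.warn("standardized bias undefined: zero SD across replicates")
        return np.nan
    return float((est.mean() - truth) / sd)


def avg_model_se(ses) -> float:
    """Root-mean-square of per-replicate model-based SEs (defined ones only)."""
    se = np.asarray(ses, dtype=float)
    se = se[np.isfinite(se)]
    if se.size == 0:
        return np.nan
    return float(np.sqrt(np.mean(se**2)))


def _summarize(method, mechanism, fraction, estimand, est, se, truth, n_reps):
    est = np.asarray(est, dtype=float)
    defined = np.isfinite(est)
    n_used = int(defined.sum())
    row = {
        "method": method,
        "mechanism": mechanism,
        "fraction": fraction,
        "estimand": estimand,
        "mean_estimate": float(est[defined].mean()) if n_used else np.nan,
        "sd_estimates": float(est[defined].std(ddof=1)) if n_used >= 2 else np.nan,
        "std_bias": np.nan,
        "avg_model_se": avg_model_se(se),
        "n_reps_used": n_used,
        "n_undefined": int(n_reps - n_used),
        "truth": truth,
    }
    if n_used >= 2 and truth is not None and np.isfinite(truth):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["std_bias"] = standardized_bias(est, truth)
    return row


def run_study(
    design: StudyDesign,
    config: SimulationConfig | None = None,
    n_jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full factorial study and return the long-format summary table.

    One row per (method, mechanism, fraction, estimand) with mean estimate,
    SD over replicates, standardized bias against the analytic (or empirical
    full-data) truth, average model-based SE and the count of replicates with
    an undefined estimand. Deterministic given ``design.base_seed`` and
    invariant to ``n_jobs``.
    """
    config = config or SimulationConfig()
    truths = true_estimands(config, horizon=design.horizon)
    truth_map = {"cif": truths.cif, "median": truths.median}

    rows = []
    methods = tuple(design.methods)
    has_full = "FULL" in {m.upper() for m in methods}
    cell_list = []
    if has_full:
        cell_list.append(("NONE", 0.0, ("FULL",)))
    core_methods = tuple(m for m in methods if m.upper() != "FULL")
    for mech in design.mechanisms:
        cell_methods = (
            tuple(m for m in core_methods if m.upper() == "CCA")
            if mech == "MCAR"
            else core_methods
        )
        if not cell_methods:
            continue
        for frac in design.fractions:
            cell_list.append((mech, frac, cell_methods))

    from joblib import Parallel, delayed

    iterator = range(design.n_reps)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(iterator)

    for mech, frac, cell_methods in cell_list:
        def _one(rep):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return run_replicate(
                    config, mech, frac, cell_methods, rep,
                    base_seed=design.base_seed, m=design.m,
                    epsilon=design.epsilon, horizon=design.horizon,
                    mnar_direction=design.mnar_direction,
                )

        if n_jobs == 1:
            results = [_one(rep) for rep in iterator]
        else:
            results = Parallel(n_jobs=n_jobs)(delayed(_one)(rep) for rep in iterator)

        if has_full and mech == "NONE" and design.truth == "empirical":
            full_cif = [r["FULL"]["cif"][0] for r in results]
            truth_map = dict(truth_map)
            truth_map["cif"] = float(np.nanmean(full_cif))

        for method in cell_methods:
            for estimand in ESTIMANDS:
                est = [r[method][estimand][0] for r in results]
                se = [r[method][estimand][1] for r in results]
                rows.append(
                    _summarize(
                        method, mech, frac, estimand, est, se,
                        truth_map[estimand], design.n_reps,
                    )
                )
        iterator = range(design.n_reps)  # reset for next cell
    return pd.DataFrame(rows)


def plot_results(summary: pd.DataFrame, path=None):
    """Dot plot of standardized bias and average model SE per method.

    One panel row per estimand, bias on the left, SE on the right; marker
    style encodes the missing fraction. Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    estimands = [e for e in ESTIMANDS if (summary["estimand"] == e).any()]
    fig, axes = plt.subplots(
        len(estimands), 2, figsize=(9, 3 + 1.2 * len(estimands)), squeeze=False
    )
    markers = {0.1: "o", 0.3: "D", 0.5: "s"}
    for i, estimand in enumerate(estimands):
        sub = summary[summary["estimand"] == estimand]
        methods = list(dict.fromkeys(sub["method"]))
        ypos = {mth: j for j, mth in enumerate(methods)}
        for frac, grp in sub.groupby("fraction"):
            y = [ypos[mth] for mth in grp["method"]]
            axes[i][0].scatter(grp["std_bias"], y, label=f"{int(frac*100)}%",
                               marker=markers.get(frac, "o"))
            axes[i][1].scatter(grp["avg_model_se"], y,
                               marker=markers.get(frac, "o"))
        for ax, xlab in zip(axes[i], ("standardized bias", "average model SE")):
            ax.set_yticks(range(len(methods)))
            ax.set_yticklabels(methods)
            ax.set_xlabel(xlab)
            ax.set_title(estimand)
        axes[i][0].axvline(0.0, color="grey", lw=0.8)
    axes[0][0].legend(title="missing", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
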