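# Methods

## Setting and model

Each subject in a simulated transplant-registry cohort experiences exactly one
of three competing events — aGvHD (cause 1), graft failure before aGvHD
(cause 2), or death before aGvHD (cause 3) — with probabilities
p = (0.65, 0.25, 0.10). Conditional on the cause j, the event time is
log-normal, T | j ~ LN(μ_j, σ_j²), with

| cause | μ | σ |
| --- | --- | --- |
| aGvHD | log 26 | log 2 |
| graft failure | log 43 | log 2 |
| death | log 77 | log 4 |

on the log-day scale. Sampling is by inverse transform: a uniform u maps to
the u-quantile of the cause's log-normal distribution, and times are rounded
**up** to whole days, mirroring registry day-resolution. Events beyond 365
days are administratively censored (event code 0, time 365). An auxiliary
binary covariate (double vs single cord-blood unit) is Bernoulli(0.45) and,
by construction, independent of everything else — it exists to measure the
cost of including an uninformative auxiliary variable in imputation models.

The estimands are the cause-1 cumulative incidence at day 100, with analytic
truth F₁(100) = 0.65·Φ(log(100/26)/log 2) = 0.6331, and the median time to
aGvHD. Because generated times are whole days, the true median is taken as
the smallest integer day t with F₁(t) ≥ 0.5, which is 44 (the continuous
root is 43.30 and is exposed as `TrueEstimands.median_root`; see
*Limitations*).

## Missingness mechanisms

Only aGvHD onset dates go missing (competing-event and censoring times are
registry-complete):

* **MCAR** — every record flagged independently with probability q,
  regardless of event type; used only with complete-case analysis, as a
  calibration that CCA is then unbiased.
* **MAR** — each cause-1 record flagged independently with probability
  q ∈ {0.1, 0.3, 0.5}; missingness depends on the (observed) event type only.
* **MNAR** — the ⌊q·n₁⌋ smallest cause-1 times flagged deterministically
  (no randomness consumed; ties broken by record order). A `largest`
  direction implements the reversed sensitivity analysis.

A flagged record keeps its event type but loses its time, which is then only
known to lie in (0, 100] days — the standard clinical window for acute GvHD.
The generated value is retained in a separate oracle column for
truth-tracking and never shown to estimators or imputers.

## Estimation

The cause-k cumulative incidence is the Aalen-Johansen product-limit
estimator F̂_k(t) = Σ_{t_j ≤ t} Ŝ(t_{j−1}) d_kj / n_j, with Ŝ the all-cause
Kaplan-Meier survivor. At tied (integer) times all events are aggregated
before the risk set shrinks, and same-day censorings leave after the events.
The pointwise variance is the Marubini-Valsecchi Greenwood-style estimator

    Var(F̂_k(t_i)) = Σ_{j≤i} (F̂_k(t_i) − F̂_k(t_j))² d_j / (n_j (n_j − d_j))
                  + Σ_{j≤i} Ŝ(t_{j−1})² (n_j − d_kj) d_kj / n_j³
                  − 2 Σ_{j≤i} (F̂_k(t_i) − F̂_k(t_j)) Ŝ(t_{j−1}) d_kj / n_j²

computed with cumulative sums (O(J) per curve). If the final event exhausts
the risk set (n_j = d_j) the first term degenerates; the SE is carried
forward from the previous jump. The implementation agrees with lifelines'
Aalen-Johansen fitter (estimate and variance) to 1e-10 on tie-free fixtures,
with a bootstrap to within 10%, and with the empirical SD of the estimate
across replicates to within a few percent at n = 500.

The median t̂₅₀ is the smallest jump time with F̂ ≥ 0.5 (undefined when F̂
never reaches 0.5, a real occurrence under heavy loss of cause-1 events —
such replicates are counted, not silently dropped). Its SE uses the delta
method, SE(t̂₅₀) = SE(F̂(t̂₅₀)) / f̂, with the density estimated by a local
gradient between the nearest jump times at least ε = 0.01 below and above
0.5; the SE is undefined (and counted) when an anchor does not exist.

Lookups F̂(t) are right-continuous; a jump exactly at the query time (e.g. a
day-100 event when evaluating F̂(100)) is included by default and excludable
via `include_equal=False`.

## Imputation engines

All regression-based engines share one imputation model: time (or log time)
regressed on an intercept, event-type indicators (reference aGvHD) and
optionally the auxiliary covariate, fitted to all records with an *observed
event* time. Administratively censored records are excluded from the
regression — their times are follow-up horizons, not event times, and would
corrupt the residual variance; they are never missingness candidates anyway.
Each imputation takes one draw from the standard noninformative posterior:
σ*² = SSE/χ²_{h−q}, β* ~ N(β̂, σ*²(Z'Z)⁻¹).

* **NormalImputer** (NORM/NORMNOAUX): imputes z_iβ* + σ*e_i with no
  restriction; values below 0 or above 100 are possible and deliberately
  kept — this is the method's documented pathology, and with the pooled
  residual variance dominated by the long-tailed death times it pushes
  imputed aGvHD times upward, under-stating the day-100 incidence.
* **LogNormalImputer** (LOGNORM): the same on log(time), back-transformed;
  strictly positive by construction.
* **RestrictedNormalImputer** (RESNORM): redraws only the residual (keeping
  β*, σ* within an imputation) until the value lands in (L, R], capped at
  200 redraws (500 as a sensitivity switch, after which no out-of-bounds
  values are observed in the study scenarios); on exhaustion the last draw is
  kept and counted in `n_out_of_bounds_`.
* **PMMImputer** (PMM/PMMNOAUX): predictive mean matching. The distance of
  target i to donor h is |β̂z_i − β̂z_h| (type 0), |β*z_i − β̂z_h| (type 1,
  the default), or |β*z_i − β*z_h| (type 2); the 5 nearest donors form the
  pool and one is copied uniformly at random. Donor-pool size 5 is the
  conventional software default. Distance ties are broken by donor order
  after a seeded random permutation — reproducible but with no systematic
  preference. Imputed values are always observed times.
* **CIFSamplingImputer** (MICI): initializes each missing time uniformly from
  the observed cause-1 times inside its bounds, then for 10 sweeps re-samples
  each missing time from that candidate set with probability proportional to
  the current Aalen-Johansen cause-1 jump sizes, refreshing the estimate from
  the completed data between sweeps. The iteration count and uniform start
  are package choices (exposed as parameters); an empty candidate set falls
  back to the interval midpoint with a warning. Within-imputation SEs come
  from the ordinary estimators on the completed data.

Imputed times are left continuous (not re-rounded to whole days): the
estimator handles non-integer times, and rounding imputed values would add a
second, unmodelled discretization.

Per-imputation estimates are combined by Rubin's rules,
T = W̄ + (1 + 1/m) B, with m = 5 by default (one incomplete variable) and 50
as a sensitivity setting. No small-m degrees-of-freedom adjustment is applied
because the study reports SEs, not confidence intervals. Imputations with an
undefined estimand are dropped and counted; fewer than two defined estimates
makes the pooled result undefined.

## Study harness and performance measures

The harness runs each (method × mechanism × fraction) cell over replicates.
Replicate r's complete dataset comes from a stream seeded `base_seed + r`, so
every cell sees identical complete data; the missingness stream is keyed by
(seed, replicate, mechanism, fraction) so all methods within a cell analyze
the same incomplete dataset (paired comparisons); each method gets its own
keyed stream for imputation noise. Results are therefore reproducible and
invariant to the joblib worker count.

Performance per cell and estimand:

* **standardized bias** (β̄̂ − β)/SD(β̂), with SD over replicates (n−1
  denominator) and β the analytic truth (an empirical full-data truth is a
  config switch);
* **average model-based SE** √(Σ_k SE²_k / K), the root-mean-square of the
  per-replicate model SEs.

Defaults are 1000 replicates of n = 500 — the full study scale, which runs in
minutes because the estimator core is vectorized; the acceptance script and
the test suite use this scale unreduced.

## What the generator does and does not emulate

It reproduces the registry's structure: competing events with day-resolution
times, one-year administrative censoring, a shared (0, 100] interval for all
missing cause-1 times, missingness confined to cause 1 (except MCAR), and an
auxiliary covariate *not* associated with event times. It does not emulate
covariate-dependent hazards, calendar-time entry, informative censoring,
subject-specific interval bounds (e.g. truncation by early death), or
missingness in more than one variable — so passing tests say nothing about
chained-equations behavior with multiple incomplete covariates, and real-data
conclusions about auxiliary variables that *are* predictive do not follow
from this generator.

## Numerical choices and degenerate inputs

Quantile ceilings subtract 1e-9 before rounding up so exact-integer quantiles
(e.g. the cause-1 median 26) are not pushed up a day by floating-point noise.
Zero-residual regressions degenerate to a point-mass posterior (σ* = 0).
Design columns for event levels absent from the observed data are dropped
with a warning; collinear designs raise, naming the columns. The MNAR count
uses the floor, so a fraction too small to flag one record warns and flags
none. Empty datasets, boundary uniforms u ∈ {0, 1}, missing bounds on flagged
records, and non-positive times on the log scale all raise immediately.

## Known limitations

* The median truth convention matters at the ±0.15-SD level: standardized
  biases of the median are computed against the whole-day truth (44),
  consistent with the generator's rounding. Against the pre-rounding
  continuous root (43.30) all median biases shift upward by roughly
  0.15–0.19 SD. `TrueEstimands.median_root` supports that sensitivity
  analysis.
* The delta-method median SE averages ≈ 3.4–3.6 days at full data but relies
  on a chord-slope density over a discrete jump grid; with few jumps near the
  median the anchors can fail to exist and the SE is undefined (counted).
* The CIF-conditional sampler is non-parametric and covariate-free; it
  accepts `include_aux` for interface parity but ignores it.
* Complete-case analysis with heavy cause-1 loss can leave the median
  non-estimable by design; summaries then cover the defined replicates with
  the undefined count reported alongside.
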