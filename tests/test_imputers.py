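"""Imputation engines: design, posterior draws, the five methods."""

import numpy as np
import pandas as pd
import pytest

from boundedmi import (
    CIFSamplingImputer,
    LogNormalImputer,
    MissingnessSpec,
    NormalImputer,
    PMMImputer,
    RestrictedNormalImputer,
    SimulationConfig,
    apply_mdm,
    build_design,
    complete_dataset,
    draw_posterior,
    generate_dataset,
    make_imputer,
    pmm_distance,
)
from boundedmi.imputers import LinearModelDraw, _ImputationProblem


@pytest.fixture()
def mar_dataset(default_config):
    df = generate_dataset(default_config, 100)
    return apply_mdm(df, MissingnessSpec("MAR", 0.5), 100, bounds=default_config.bounds)


def _problem(times, events, aux, miss, left=0.0, right=100.0):
    times = np.asarray(times, dtype=float)
    miss = np.asarray(miss, dtype=bool)
    return _ImputationProblem(
        times=np.where(miss, np.nan, times),
        events=np.asarray(events),
        aux=np.asarray(aux),
        miss=miss,
        left=np.where(miss, left, np.nan),
        right=np.where(miss, right, np.nan),
    )


class TestDesign:
    def test_column_counts_with_and_without_aux(self):
        events = np.array([1, 2, 3, 1])
        aux = np.array([0, 1, 0, 1])
        Z, names = build_design(events, aux, include_aux=False)
        assert Z.shape == (4, 3) and names == ["intercept", "event_2", "event_3"]
        Z, names = build_design(events, aux, include_aux=True)
        assert Z.shape == (4, 4) and names[-1] == "aux"

    def test_reference_level_rows_have_zero_indicators(self):
        Z, _ = build_design(np.array([1, 1]), np.array([0, 0]), include_aux=False)
        np.testing.assert_allclose(Z[:, 1:], 0.0)

    def test_empty_level_dropped_with_warning(self):
        # all observed outcomes are cause 1: dummies carry no information
        prob = _problem([10, 12, 14, 11, np.nan], [1, 1, 1, 1, 1],
                        [0, 1, 0, 1, 1], [0, 0, 0, 0, 1])
        imp = NormalImputer(m=2, include_aux=True)
        with pytest.warns(UserWarning, match="dropped"):
            vals = imp.impute_times(prob, np.random.default_rng(0))
        assert vals.shape == (2, 1)


class TestPosteriorDraw:
    def test_posterior_mean_matches_ols(self):
        rng = np.random.default_rng(4)
        n = 200
        Z = np.column_stack([np.ones(n), rng.uniform(size=n)])
        y = Z @ np.array([2.0, -1.0]) + rng.normal(scale=0.5, size=n)
        beta_hat = np.linalg.lstsq(Z, y, rcond=None)[0]
        draws = np.array(
            [draw_posterior(y, Z, rng).beta_star for _ in range(10_000)]
        )
        # flat-prior posterior mean equals OLS; 3 Monte-Carlo SEs of slack
        mc_se = draws.std(axis=0, ddof=1) / 100
        assert np.all(np.abs(draws.mean(axis=0) - beta_hat) < 3 * mc_se)

    def test_zero_residual_data_degenerates_to_point_mass(self):
        Z = np.column_stack([np.ones(5), np.arange(5.0)])
        y = Z @ np.array([1.0, 2.0])
        draw = draw_posterior(y, Z, np.random.default_rng(0))
        assert draw.sigma_star == 0.0
        np.testing.assert_allclose(draw.beta_star, draw.beta_hat)

    def test_single_residual_df_still_finite(self):
        rng = np.random.default_rng(5)
        Z = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        y = np.array([0.0, 1.1, 1.9])
        draws = [draw_posterior(y, Z, rng).sigma_star for _ in range(200)]
        assert np.all(np.isfinite(draws))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="observed rows"):
            draw_posterior([1.0, 2.0], np.ones((2, 2)), np.random.default_rng(0))

    def test_singular_design_names_columns(self):
        Z = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            draw_posterior(np.arange(6.0), Z, np.random.default_rng(0),
                           columns=["intercept", "dup"])


class TestPMMDistance:
    def test_all_types_coincide_when_draw_equals_fit(self):
        draw = LinearModelDraw(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 0.5, [])
        z_i, z_h = np.array([1.0, 3.0]), np.array([1.0, 1.0])
        d = [pmm_distance(z_i, z_h, draw, t) for t in (0, 1, 2)]
        assert d[0] == d[1] == d[2] == pytest.approx(4.0)

    def test_identical_covariates_type0_distance_is_zero(self):
        draw = LinearModelDraw(np.array([1.0, 2.0]), np.array([1.5, 1.0]), 0.5, [])
        z = np.array([1.0, 2.0])
        assert pmm_distance(z, z, draw, 0) == 0.0
        # type 1 compares a posterior-draw prediction with an OLS prediction:
        # |((1.5,1.0)-(1.0,2.0)) . (1,2)| = 1.5
        assert pmm_distance(z, z, draw, 1) == pytest.approx(1.5)


class TestNormalImputer:
    def test_point_mass_when_model_is_deterministic(self):
        # one predictor level, zero residuals: every imputed value equals the level mean
        prob = _problem([10, 10, 10, 10, np.nan], [1, 1, 1, 1, 1],
                        np.zeros(5), [0, 0, 0, 0, 1])
        vals = NormalImputer(m=3, include_aux=False).impute_times(
            prob, np.random.default_rng(0)
        )
        np.testing.assert_allclose(vals, 10.0)

    def test_imputations_differ_across_copies(self, mar_dataset):
        completed = NormalImputer(m=5, random_state=0).fit_transform(mar_dataset)
        assert len(completed) == 5
        t0 = completed[0].loc[mar_dataset["time_missing"], "time"]
        t1 = completed[1].loc[mar_dataset["time_missing"], "time"]
        assert not np.allclose(t0, t1)

    def test_unrestricted_values_can_leave_bounds(self, mar_dataset):
        completed = NormalImputer(m=5, random_state=1).fit_transform(mar_dataset)
        vals = np.concatenate(
            [c.loc[mar_dataset["time_missing"], "time"].to_numpy() for c in completed]
        )
        assert (vals > 100).any() or (vals <= 0).any()


class TestLogNormalImputer:
    def test_back_transformed_values_are_positive(self, mar_dataset):
        completed = LogNormalImputer(m=5, random_state=2).fit_transform(mar_dataset)
        for c in completed:
            assert (c["time"] > 0).all()

    def test_rejects_nonpositive_observed_times(self):
        prob = _problem([0.0, 5.0, 6.0, 7.0, np.nan], [1, 1, 1, 1, 1],
                        np.zeros(5), [0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="positive"):
            LogNormalImputer(m=2, include_aux=False).impute_times(
                prob, np.random.default_rng(0)
            )


class TestRestrictedNormalImputer:
    def test_cap_500_keeps_all_values_in_bounds(self, mar_dataset):
        imp = RestrictedNormalImputer(m=5, rejection_cap=500, random_state=3)
        completed = imp.fit_transform(mar_dataset)
        for c in completed:
            vals = c.loc[mar_dataset["time_missing"], "time"]
            assert ((vals > 0) & (vals <= 100)).all()
        assert imp.n_out_of_bounds_ == 0

    def test_forced_exhaustion_counts_every_missing_value(self):
        # predictive distribution far above the bound: every cap is exhausted
        times = [5000.0, 5100.0, 4900.0, 5050.0, np.nan, np.nan]
        prob = _problem(times, [1] * 6, np.zeros(6), [0, 0, 0, 0, 1, 1])
        imp = RestrictedNormalImputer(m=2, include_aux=False, rejection_cap=50)
        imp.impute_times(prob, np.random.default_rng(0))
        assert imp.n_out_of_bounds_ == 2 * 2  # m imputations x 2 missing

    def test_disabled_bounds_reduce_to_unrestricted_normal(self, mar_dataset):
        miss = mar_dataset["time_missing"].to_numpy()
        base = mar_dataset.copy()
        base.loc[miss, "interval_left"] = -np.inf
        base.loc[miss, "interval_right"] = np.inf
        res = RestrictedNormalImputer(m=5, random_state=4).fit_transform(base)
        norm = NormalImputer(m=5, random_state=4).fit_transform(mar_dataset)
        for a, b in zip(res, norm):
            np.testing.assert_allclose(a["time"], b["time"])


class TestPMMImputer:
    def test_single_donor_pool_copies_the_donor(self):
        prob = _problem([7.0, 9.0, 11.0, 13.0, np.nan], [1, 1, 1, 1, 1],
                        np.zeros(5), [0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="shrinking"):
            vals = PMMImputer(m=2, include_aux=False, donor_pool_size=10).impute_times(
                prob, np.random.default_rng(0)
            )
        assert np.isin(vals, [7, 9, 11, 13]).all()

    def test_subset_property(self, mar_dataset):
        completed = PMMImputer(m=5, random_state=5).fit_transform(mar_dataset)
        observed = set(mar_dataset.loc[~mar_dataset["time_missing"], "time"])
        for c in completed:
            imputed = c.loc[mar_dataset["time_missing"], "time"]
            assert set(imputed) <= observed
            assert (imputed <= max(observed)).all() and (imputed > 0).all()

    def test_imputed_values_mostly_come_from_cause1_donors(self, mar_dataset):
        # event type is in the model, so the nearest predicted means are
        # overwhelmingly cause-1 donors (a posterior draw can occasionally
        # pull in a competing-event donor)
        completed = PMMImputer(m=5, random_state=6).fit_transform(mar_dataset)
        obs = mar_dataset.loc[~mar_dataset["time_missing"]]
        cause1 = set(obs.loc[obs["event"] == 1, "time"])
        vals = np.concatenate(
            [c.loc[mar_dataset["time_missing"], "time"].to_numpy() for c in completed]
        )
        assert np.mean([v in cause1 for v in vals]) > 0.9

    @pytest.mark.parametrize("pmm_type", [0, 1, 2])
    def test_all_types_run_and_respect_subset(self, pmm_type, mar_dataset):
        completed = PMMImputer(m=2, pmm_type=pmm_type, random_state=7).fit_transform(mar_dataset)
        observed = set(mar_dataset.loc[~mar_dataset["time_missing"], "time"])
        assert set(completed[0].loc[mar_dataset["time_missing"], "time"]) <= observed


class TestCIFSamplingImputer:
    def test_single_candidate_forces_its_value(self):
        # only one observed cause-1 time inside (0, 100]
        prob = _problem([50.0, 150.0, 160.0, 170.0, np.nan, np.nan],
                        [1, 1, 1, 1, 1, 1], np.zeros(6), [0, 0, 0, 0, 1, 1])
        vals = CIFSamplingImputer(m=2, n_iterations=3).impute_times(
            prob, np.random.default_rng(0)
        )
        np.testing.assert_allclose(vals, 50.0)

    def test_values_always_inside_bounds(self, mar_dataset):
        completed = CIFSamplingImputer(m=5, random_state=8).fit_transform(mar_dataset)
        for c in completed:
            vals = c.loc[mar_dataset["time_missing"], "time"]
            assert ((vals > 0) & (vals <= 100)).all()

    def test_empty_candidate_set_falls_back_to_midpoint(self):
        prob = _problem([150.0, 160.0, 170.0, 140.0, np.nan],
                        [1, 1, 1, 1, 1], np.zeros(5), [0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="midpoint"):
            vals = CIFSamplingImputer(m=2, n_iterations=2).impute_times(
                prob, np.random.default_rng(0)
            )
        np.testing.assert_allclose(vals, 50.0)


class TestSeedDiscipline:
    @pytest.mark.parametrize("method", ["NORM", "LOGNORM", "RESNORM", "PMM", "MICI"])
    def test_same_seed_same_completions(self, method, mar_dataset):
        a = make_imputer(method, m=3, random_state=11).fit_transform(mar_dataset)
        b = make_imputer(method, m=3, random_state=11).fit_transform(mar_dataset)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestComplete:
    def test_identity_when_nothing_flagged(self, complete_dataset_500):
        out = complete_dataset(complete_dataset_500, np.empty(0))
        pd.testing.assert_frame_equal(out, complete_dataset_500)

    def test_completed_frame_has_no_flags_and_same_size(self, mar_dataset):
        nm = int(mar_dataset["time_missing"].sum())
        out = complete_dataset(mar_dataset, np.full(nm, 33.5))
        assert len(out) == len(mar_dataset)
        assert not out["time_missing"].any()
        assert not out["time"].isna().any()
        assert (out.loc[mar_dataset["time_missing"], "event"] == 1).all()

    def test_nonpositive_values_rejected_unless_allowed(self, mar_dataset):
        nm = int(mar_dataset["time_missing"].sum())
        with pytest.raises(ValueError, match="positive"):
            complete_dataset(mar_dataset, np.full(nm, -1.0))
        out = complete_dataset(mar_dataset, np.full(nm, -1.0), allow_nonpositive=True)
        assert (out.loc[mar_dataset["time_missing"], "time"] == -1.0).all()

    def test_wrong_value_count_rejected(self, mar_dataset):
        with pytest.raises(ValueError, match="one imputed value"):
            complete_dataset(mar_dataset, np.array([1.0]))
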