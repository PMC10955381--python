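"""ordinal_model module: elementary functions, priors, likelihood,
posterior container, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ordcausal.model import (
    BETA_NAMES,
    ModelError,
    ModelSpec,
    PosteriorDraws,
    SingleDraw,
    category_probs,
    diagnostics,
    linear_predictor,
    log_likelihood,
    mo,
    prior_predictive,
    sample_prior_params,
)
from ordcausal.simulate import ScmParams, simulate_population, true_site_effects


class TestMo:
    def test_zero_level_is_zero(self):
        assert mo(0, [0.2, 0.3, 0.5]) == 0.0

    def test_equal_simplex_is_linear(self):
        assert mo(2, (0.25, 0.25, 0.25, 0.25)) == pytest.approx(2.0)

    def test_tilted_simplex(self):
        assert mo(2, (0.5, 0.3, 0.1, 0.1)) == pytest.approx(3.2)

    def test_full_range_is_exactly_d(self):
        rng = np.random.default_rng(0)
        for d in (2, 5, 30):
            zeta = rng.dirichlet(np.full(d, 0.7))
            assert mo(d, zeta) == d

    def test_vectorized(self):
        out = mo(np.array([0, 1, 2]), (0.5, 0.5))
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            mo(4, (0.5, 0.3, 0.2))
        with pytest.raises(ModelError):
            mo(-1, (0.5, 0.5))

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ModelError):
            mo(1, (0.5, 0.6))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 12), st.integers(0, 10**6))
    def test_nondecreasing_in_level(self, d, seed):
        zeta = np.random.default_rng(seed).dirichlet(np.full(d, 2.0))
        values = mo(np.arange(d + 1), zeta)
        assert np.all(np.diff(values) >= -1e-12)


class TestCategoryProbs:
    def test_symmetric_two_category(self):
        np.testing.assert_allclose(category_probs(0.0, [0.0]), [0.5, 0.5])

    def test_against_logistic_cdf_differences(self):
        kappa = np.array([-1.0, 0.0, 1.0, 2.0])
        probs = category_probs(0.0, kappa)
        expected = np.diff(
            np.concatenate(([0.0], expit(kappa), [1.0]))
        )
        np.testing.assert_allclose(probs, expected, atol=1e-12)
        np.testing.assert_allclose(
            probs, [0.2689, 0.2311, 0.2311, 0.1498, 0.1192], atol=1e-4
        )

    def test_extreme_xi_limit(self):
        probs = category_probs(40.0, [-1.0, 0.0, 1.0, 2.0])
        np.testing.assert_allclose(probs, [0, 0, 0, 0, 1], atol=1e-12)

    def test_nonincreasing_kappa_rejected(self):
        with pytest.raises(ModelError, match="increasing"):
            category_probs(0.0, [1.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-8, 8), st.floats(-3, 3))
    def test_sums_to_one_and_shift_invariant(self, xi, shift):
        kappa = np.array([-1.5, -0.2, 0.9, 2.1])
        probs = category_probs(xi, kappa)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        shifted = category_probs(xi + shift, kappa + shift)
        np.testing.assert_allclose(probs, shifted, atol=1e-9)

    def test_batch_shapes(self):
        xi = np.zeros((3, 7))
        out = category_probs(xi, [-1.0, 0.0, 1.0, 2.0])
        assert out.shape == (3, 7, 5)


class TestLinearPredictor:
    def test_reference_point_is_zero(self, toy_spec):
        draw = SingleDraw(
            kappa=np.array([-1.0, 0.0, 1.0, 2.0]),
            beta=np.array([0.5, 0.8, -0.2, 0.1, 0.3]),
            zeta_edu=np.full(5, 0.2), zeta_age=np.full(4, 0.25),
            zeta_children=np.full(3, 1 / 3),
            site_effects=np.zeros((6, 2)), sites=("A", "B"),
        )
        record = {"site": "A", "sex": 0, "food_insecure": 0, "education": 0,
                  "age": 17, "children": 0}
        assert linear_predictor(record, draw, toy_spec) == pytest.approx(0.0)

    def test_indicator_contrast_is_beta_plus_offset(self, toy_draw, toy_spec):
        base = {"site": "A", "sex": 0, "food_insecure": 0, "education": 2,
                "age": 19, "children": 1}
        exposed = dict(base, food_insecure=1)
        delta = (linear_predictor(exposed, toy_draw, toy_spec)
                 - linear_predictor(base, toy_draw, toy_spec))
        # beta_food + site A's food offset
        assert delta == pytest.approx(0.8 + 0.1)

    def test_manual_arithmetic(self, toy_draw, toy_spec):
        record = {"site": "B", "sex": 1, "food_insecure": 1, "education": 3,
                  "age": 20, "children": 2}
        # by hand: intercept(B) + b_sex*1 + (b_food - 0.1)*1
        #   + b_edu * 5*(0.4+0.3+0.1) + b_age * 4*(0.25*3) + b_child * 3*0.8
        expected = (
            -0.3 + 0.5 + (0.8 - 0.1)
            + (-0.2) * 5 * 0.8 + 0.1 * 4 * 0.75 + 0.3 * 3 * 0.8
        )
        assert linear_predictor(record, toy_draw, toy_spec) == pytest.approx(
            expected
        )

    def test_missing_field_rejected(self, toy_draw, toy_spec):
        record = {"site": "A", "sex": np.nan, "food_insecure": 0,
                  "education": 2, "age": 19, "children": 1}
        with pytest.raises(ModelError, match="missing"):
            linear_predictor(record, toy_draw, toy_spec)

    def test_unknown_site_rejected(self, toy_draw, toy_spec):
        record = {"site": "Z", "sex": 0, "food_insecure": 0, "education": 2,
                  "age": 19, "children": 1}
        with pytest.raises(ModelError, match="unknown site"):
            linear_predictor(record, toy_draw, toy_spec)


class TestLogLikelihood:
    def test_single_row_two_categories(self):
        spec = ModelSpec(outcome="think_freq", d_age=2, d_children=2,
                         d_education=2, n_categories=2)
        draw = SingleDraw(
            kappa=np.array([0.0]), beta=np.zeros(5),
            zeta_edu=np.array([0.5, 0.5]), zeta_age=np.array([0.5, 0.5]),
            zeta_children=np.array([0.5, 0.5]),
            site_effects=np.zeros((6, 1)), sites=("A",),
        )
        table = pd.DataFrame({
            "site": ["A"], "sex": [0], "age": [17], "education": [0],
            "children": [0], "food_insecure": [0], "think_freq": [1],
        })
        assert log_likelihood(table, draw, spec) == pytest.approx(
            np.log(0.5)
        )

    def test_empty_table_is_zero(self, toy_draw, toy_spec, toy_table):
        assert log_likelihood(toy_table.iloc[:0], toy_draw, toy_spec) == 0.0

    def test_three_row_matches_per_row_sum(self, toy_draw, toy_spec,
                                           toy_table):
        total = log_likelihood(toy_table, toy_draw, toy_spec)
        per_row = 0.0
        for _, row in toy_table.iterrows():
            xi = linear_predictor(row, toy_draw, toy_spec)
            probs = category_probs(xi, toy_draw.kappa)
            per_row += np.log(probs[int(row["think_freq"]) - 1])
        assert total == pytest.approx(per_row, abs=1e-10)

    def test_outcome_out_of_range_rejected(self, toy_draw, toy_spec,
                                           toy_table):
        bad = toy_table.copy()
        bad.loc[0, "think_freq"] = 6
        with pytest.raises(ModelError):
            log_likelihood(bad, toy_draw, toy_spec)

    def test_truth_beats_decoys_on_large_sample(self):
        """Likelihood self-consistency: generator truth scores higher than
        parameter-permuted decoys."""
        params = ScmParams(n_sites=4, n_per_site=500, seed=33)
        table = simulate_population(params)
        spec = ModelSpec(outcome="think_freq", d_age=params.d_age,
                         d_children=params.d_children, age_min=17)
        site_effects = np.zeros((6, params.n_sites))
        site_effects[0] = true_site_effects(params)
        truth = SingleDraw(
            kappa=np.array(params.cutpoints),
            beta=np.array([
                params.beta_sex_on_y, params.beta_m_on_y,
                params.beta_edu_on_y, params.beta_age_on_y,
                params.beta_children_on_y,
            ]),
            zeta_edu=np.array(params.edu_simplex),
            zeta_age=np.array(params.age_simplex),
            zeta_children=np.array(params.children_simplex),
            site_effects=site_effects,
            sites=params.site_labels,
        )
        ll_truth = log_likelihood(table, truth, spec)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(5)
            if (perm == np.arange(5)).all():
                continue
            decoy = SingleDraw(
                kappa=truth.kappa, beta=truth.beta[perm],
                zeta_edu=truth.zeta_edu, zeta_age=truth.zeta_age,
                zeta_children=truth.zeta_children,
                site_effects=site_effects, sites=truth.sites,
            )
            assert log_likelihood(table, decoy, spec) < ll_truth
        flipped = SingleDraw(
            kappa=truth.kappa, beta=-truth.beta,
            zeta_edu=truth.zeta_edu, zeta_age=truth.zeta_age,
            zeta_children=truth.zeta_children,
            site_effects=site_effects, sites=truth.sites,
        )
        assert log_likelihood(table, flipped, spec) < ll_truth


class TestPriorSampling:
    def test_prior_simplex_means_uniform(self):
        spec = ModelSpec(outcome="think_freq", d_age=10, d_children=4)
        rng = np.random.default_rng(1)
        params = sample_prior_params(spec, n_sites=3, n_draws=4000, rng=rng)
        np.testing.assert_allclose(
            params["zeta_edu"].mean(axis=0), np.full(30, 1 / 30), atol=0.004
        )
        np.testing.assert_allclose(
            params["zeta_children"].mean(axis=0), np.full(4, 0.25),
            atol=0.01
        )

    def test_prior_coefficient_sd(self):
        spec = ModelSpec(outcome="think_freq", d_age=5, d_children=3)
        rng = np.random.default_rng(2)
        params = sample_prior_params(spec, n_sites=3, n_draws=8000, rng=rng)
        sds = params["beta"].std(axis=0)
        np.testing.assert_allclose(sds, 0.5, atol=0.03)

    def test_prior_cutpoints_sorted_and_wide(self):
        spec = ModelSpec(outcome="think_freq", d_age=5, d_children=3)
        rng = np.random.default_rng(3)
        params = sample_prior_params(spec, n_sites=2, n_draws=2000, rng=rng)
        assert (np.diff(params["kappa"], axis=1) >= 0).all()
        pooled_sd = params["kappa"].std()
        assert 5.0 < pooled_sd < 15.0  # Normal(0, 10) order statistics

    def test_prior_correlation_matrices_valid(self):
        spec = ModelSpec(outcome="think_freq", d_age=5, d_children=3)
        rng = np.random.default_rng(4)
        params = sample_prior_params(spec, n_sites=2, n_draws=200, rng=rng)
        corr = params["corr"]
        np.testing.assert_allclose(
            np.diagonal(corr, axis1=1, axis2=2), 1.0, atol=1e-12
        )
        np.testing.assert_allclose(corr, np.swapaxes(corr, 1, 2),
                                   atol=1e-12)
        eigs = np.linalg.eigvalsh(corr)
        assert (eigs > -1e-10).all()

    def test_prior_predictive_covers_all_categories(self):
        params = ScmParams(n_sites=3, n_per_site=80, seed=17)
        covariates = simulate_population(params).drop(
            columns=["think_freq", "ritual_freq"]
        )
        spec = ModelSpec.from_table(covariates, "think_freq")
        outcomes, _ = prior_predictive(spec, covariates, n_draws=400,
                                       seed=5)
        assert outcomes.shape == (400, len(covariates))
        freqs = np.bincount(outcomes.ravel(), minlength=6)[1:]
        share = freqs / freqs.sum()
        assert (share > 0.02).all() and (share < 0.8).all()


class TestDiagnostics:
    @staticmethod
    def _draws_from_arrays(values: np.ndarray, chain_ids: np.ndarray,
                           divergent=None) -> PosteriorDraws:
        m = len(values)
        spec = ModelSpec(outcome="think_freq", d_age=2, d_children=2,
                         d_education=2)
        rng = np.random.default_rng(0)
        base = rng.standard_normal((m, 1)) * 0 + values[:, None]
        kappa = np.sort(rng.standard_normal((m, 4)), axis=1)
        kappa[:, 0] = values  # carry the signal in one parameter
        kappa = np.sort(kappa, axis=1)
        return PosteriorDraws(
            spec=spec, sites=("A", "B"),
            kappa=kappa,
            beta=values[:, None] + 0.01 * rng.standard_normal((m, 5)),
            zeta_edu=np.full((m, 2), 0.5), zeta_age=np.full((m, 2), 0.5),
            zeta_children=np.full((m, 2), 0.5),
            sigma=np.abs(base) + 0.5 + 0.01 * rng.standard_normal((m, 6)),
            corr=np.tile(np.eye(6), (m, 1, 1)),
            site_effects=np.zeros((m, 6, 2)),
            divergent=(divergent if divergent is not None
                       else np.zeros(m, dtype=bool)),
            chain_ids=chain_ids,
        )

    def test_healthy_chains_pass(self):
        rng = np.random.default_rng(11)
        m = 2000
        vals = rng.standard_normal(m)
        draws = self._draws_from_arrays(
            vals, np.repeat([0, 1, 2, 3], m // 4)
        )
        report = diagnostics(draws)
        assert report.max_rhat <= 1.01
        assert not report.flagged
        assert report.ok

    def test_shifted_duplicate_chain_flagged(self):
        rng = np.random.default_rng(12)
        half = rng.standard_normal(500)
        vals = np.concatenate([half, half + 5.0])  # constant offset
        draws = self._draws_from_arrays(vals, np.repeat([0, 1], 500))
        report = diagnostics(draws)
        assert report.max_rhat > 1.5
        assert report.flagged
        assert not report.ok

    def test_divergence_accounting(self):
        rng = np.random.default_rng(13)
        m = 400
        div = rng.uniform(size=m) < 0.1
        draws = self._draws_from_arrays(
            rng.standard_normal(m), np.repeat([0, 1], m // 2), divergent=div
        )
        report = diagnostics(draws)
        assert report.n_divergent == int(div.sum())

    def test_single_chain_warns_and_omits_rhat(self):
        rng = np.random.default_rng(14)
        draws = self._draws_from_arrays(
            rng.standard_normal(200), np.zeros(200, dtype=int)
        )
        with pytest.warns(UserWarning, match="single chain"):
            report = diagnostics(draws)
        assert np.isnan(report.max_rhat)


class TestPosteriorDrawsContainer:
    def test_csv_round_trip(self, small_fit, tmp_path):
        path = tmp_path / "draws.csv"
        small_fit.to_csv(path)
        loaded = PosteriorDraws.from_csv(path)
        assert loaded.spec == small_fit.spec
        assert loaded.sites == small_fit.sites
        np.testing.assert_allclose(loaded.kappa, small_fit.kappa,
                                   rtol=1e-12)
        np.testing.assert_allclose(loaded.beta, small_fit.beta, rtol=1e-12)
        np.testing.assert_allclose(loaded.site_effects,
                                   small_fit.site_effects, rtol=1e-12)
        np.testing.assert_allclose(loaded.corr, small_fit.corr, rtol=1e-9)
        assert (loaded.chain_ids == small_fit.chain_ids).all()

    def test_metadata_header(self, small_fit, tmp_path):
        path = tmp_path / "draws.csv"
        small_fit.to_csv(path)
        first = path.read_text().splitlines()[0]
        assert first.startswith("#")
        assert small_fit.spec.config_hash() in first

    def test_thin(self, small_fit):
        thinned = small_fit.thin(100)
        assert thinned.n_draws == 100
        np.testing.assert_allclose(thinned.kappa[0], small_fit.kappa[0])

    def test_constrained_invariants(self, small_fit):
        assert (np.diff(small_fit.kappa, axis=1) > 0).all()
        for zeta in (small_fit.zeta_edu, small_fit.zeta_age,
                     small_fit.zeta_children):
            assert (zeta >= 0).all()
            np.testing.assert_allclose(zeta.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            np.diagonal(small_fit.corr, axis1=1, axis2=2), 1.0, atol=1e-9
        )
        eigs = np.linalg.eigvalsh(small_fit.corr)
        assert (eigs > -1e-9).all()


class TestModelSpec:
    def test_from_table_domains(self, toy_table):
        spec = ModelSpec.from_table(toy_table, "think_freq")
        assert spec.age_min == 17
        assert spec.d_age == 4
        assert spec.d_children == 3
        assert spec.d_education == 30

    def test_invalid_specs_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(outcome="bogus", d_age=2, d_children=2)
        with pytest.raises(ModelError):
            ModelSpec(outcome="think_freq", d_age=0, d_children=2)
        with pytest.raises(ModelError):
            ModelSpec(outcome="think_freq", d_age=2, d_children=2,
                      coef_scale=-1.0)

    def test_dict_round_trip(self):
        spec = ModelSpec(outcome="ritual_freq", d_age=9, d_children=4)
        assert ModelSpec.from_dict(spec.to_dict()) == spec
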