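"""Measurement-model arithmetic, the log posterior and its gradient."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mgrlmm._posterior import MgrlmmPosterior, chol_from_cpc
from mgrlmm.design import design_matrix
from mgrlmm.model import (
    MgrlmmSpec,
    ParamDraw,
    SamplerSettings,
    _ordinal_matrix,
    category_probs,
    log_likelihood,
)
from mgrlmm.synthetic import generate_cohort, make_default_truth


class TestCategoryProbs:
    def test_hand_evaluated_logistic_arithmetic(self):
        """theta=0, loading 1, thresholds (-1, 1): s(1)=0.7311 splits the triple."""
        probs = category_probs(np.array([0.0]), np.array([1.0]), (-1.0, 1.0))
        np.testing.assert_allclose(probs, [0.2689, 0.4621, 0.2689], atol=1e-4)

    def test_extreme_latent_score_saturates(self):
        probs = category_probs(np.array([40.0]), np.array([1.0]), (-1.0, 1.0))
        np.testing.assert_allclose(probs, [0.0, 0.0, 1.0], atol=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            category_probs(np.zeros(2), np.ones(2), (1.0, -1.0))

    @given(
        theta=st.lists(st.floats(-5, 5), min_size=2, max_size=2),
        a=st.lists(st.floats(-1, 1), min_size=2, max_size=2),
        b1=st.floats(-3, 2),
        gap=st.floats(0.1, 3),
    )
    def test_probabilities_sum_to_one(self, theta, a, b1, gap):
        probs = category_probs(np.array(theta), np.array(a), (b1, b1 + gap))
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_cumulative_monotone_in_positively_loaded_trait(self):
        a = np.array([0.7, 0.2])
        grid = np.linspace(-4, 4, 41)
        thetas = np.column_stack([grid, np.zeros_like(grid)])
        probs = category_probs(thetas, a, (-0.5, 0.9))
        p_ge1 = probs[:, 1] + probs[:, 2]
        p_ge2 = probs[:, 2]
        assert np.all(np.diff(p_ge1) > 0)
        assert np.all(np.diff(p_ge2) > 0)


class TestLogLikelihood:
    @pytest.fixture()
    def small(self):
        truth = make_default_truth(3)
        table = generate_cohort(truth, 25, seed=3)
        rng = np.random.default_rng(0)
        u = {s: rng.normal(size=3) for s in table["subject_id"].unique()}
        params = ParamDraw(
            loadings=truth.loadings,
            thresholds=truth.thresholds,
            gamma=truth.structural_coefs,
            u=u,
            covariates=truth.covariates,
        )
        return table, params

    def test_matches_naive_per_cell_loop(self, small):
        table, params = small
        ll = log_likelihood(table, params)
        X, _ = design_matrix(table, list(params.covariates))
        expected = []
        for r in range(len(table)):
            theta = X[r] @ params.gamma.T + params.u[table["subject_id"].iloc[r]]
            for j, item in enumerate(params.item_names):
                y = table[f"item_{item}"].iloc[r]
                if pd.isna(y):
                    continue
                p = category_probs(theta, params.loadings[j], params.thresholds[j])
                expected.append(np.log(p[int(y)]))
        np.testing.assert_allclose(ll, expected, atol=1e-10)

    def test_half_probability_cell(self):
        table = pd.DataFrame({"subject_id": ["a"], "wave": [1], "item_bmi": [1]})
        params = ParamDraw(
            loadings=np.array([[1.0]]),
            # symmetric thresholds at theta=0: P(1) = s(1) - s(-1) != 1/2, so
            # place them so the middle band has probability exactly 1/2
            thresholds=np.array([[-np.log(3.0), np.log(3.0)]]),
            gamma=np.zeros((1, 0)),
            u={"a": np.zeros(1)},
            covariates=(),
            item_names=("bmi",),
        )
        ll = log_likelihood(table, params)
        assert ll.shape == (1,)
        assert ll[0] == pytest.approx(np.log(0.5), abs=1e-12)

    def test_missing_cells_are_skipped(self, small):
        table, params = small
        table = table.copy()
        table.loc[table.index[0], "item_tg"] = np.nan
        assert len(log_likelihood(table, params)) == len(log_likelihood(*small)) - 1

    def test_invalid_code_rejected(self, small):
        table, params = small
        table = table.copy()
        table.loc[table.index[0], "item_tg"] = 5
        with pytest.raises(ValueError, match="tg"):
            log_likelihood(table, params)


def _make_posterior(n=60, seed=4, **kwargs):
    truth = make_default_truth(3)
    table = generate_cohort(truth, n, seed=seed)
    spec = MgrlmmSpec(n_dims=3, covariates=("dqi", "age", "sex"))
    y = _ordinal_matrix(table, spec.item_names)
    X, _ = design_matrix(table, list(spec.covariates))
    sid, sidx = np.unique(table["subject_id"].to_numpy(), return_inverse=True)
    return MgrlmmPosterior(
        y=y, X=X, subj_idx=sidx, n_subjects=len(sid),
        anchor_rows=spec.anchor_rows(), **kwargs,
    )


class TestPosterior:
    def test_compiled_kernel_matches_reference(self):
        post = _make_posterior()
        rng = np.random.default_rng(0)
        for _ in range(3):
            z = post.initial_point(rng) + 0.3 * rng.standard_normal(post.n_params)
            lp_k, g_k = post.logp_grad(z)
            lp_r, g_r = post.logp_grad_reference(z)
            assert lp_k == pytest.approx(lp_r, rel=1e-10, abs=1e-8)
            np.testing.assert_allclose(g_k, g_r, atol=1e-8)

    def test_gradient_matches_finite_differences(self):
        post = _make_posterior(n=30)
        rng = np.random.default_rng(1)
        z = post.initial_point(rng)
        _, grad = post.logp_grad(z)
        eps = 1e-6
        idx = rng.choice(post.n_params, 50, replace=False)
        for i in idx:
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd = (post.logp(zp) - post.logp(zm)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=5e-4, abs=1e-5)

    def test_reduced_model_gradient(self):
        """Fixed thresholds / sds / identity correlation variant stays exact."""
        post = _make_posterior(
            n=30,
            fixed_thresholds=np.column_stack([np.full(8, -1.0), np.full(8, 1.0)]),
            fixed_re_sd=np.ones(3),
            identity_corr=True,
        )
        rng = np.random.default_rng(2)
        z = post.initial_point(rng)
        lp_k, g_k = post.logp_grad(z)
        lp_r, g_r = post.logp_grad_reference(z)
        assert lp_k == pytest.approx(lp_r, rel=1e-10)
        np.testing.assert_allclose(g_k, g_r, atol=1e-8)

    def test_unpack_satisfies_constraints(self):
        post = _make_posterior(n=30)
        rng = np.random.default_rng(3)
        p = post.unpack(rng.standard_normal(post.n_params))
        assert np.all(p["thresholds"][:, 0] < p["thresholds"][:, 1])
        np.testing.assert_allclose(np.diag(p["re_corr"]), 1.0, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(p["re_corr"]) > 0)
        for d, item in enumerate(("bmi", "tg", "bp")):
            assert p["loadings"][d, d] == 1.0
        free = p["loadings"][3:]
        assert np.all(np.abs(free) < 1.0)


def test_chol_from_cpc_builds_valid_correlation():
    rng = np.random.default_rng(5)
    for D in (2, 3, 4, 5):
        z = np.tanh(rng.standard_normal(D * (D - 1) // 2))
        L = chol_from_cpc(z, D)
        R = L @ L.T
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(R) > 0)
    # D=2: the single partial correlation is the correlation itself
    L2 = chol_from_cpc(np.array([0.42]), 2)
    assert (L2 @ L2.T)[0, 1] == pytest.approx(0.42)


class TestSpecValidation:
    def test_duplicate_anchors_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            MgrlmmSpec(n_dims=2, anchors=("bmi", "bmi"))

    def test_too_many_dims_rejected(self):
        with pytest.raises(ValueError):
            MgrlmmSpec(n_dims=3, item_names=("bmi", "tg"))

    def test_dqi_required_among_covariates(self):
        with pytest.raises(ValueError, match="dqi"):
            MgrlmmSpec(covariates=("age", "sex"))

    def test_default_anchors_are_first_items(self):
        assert MgrlmmSpec(n_dims=4).resolved_anchors() == ("bmi", "tg", "bp", "ldl")

    def test_parameter_count(self):
        # D=3, 8 items: 15 free loadings + 16 thresholds + 3x3 gammas
        # + 3 sds + 3 correlations
        spec = MgrlmmSpec(n_dims=3, covariates=("dqi", "age", "sex"))
        assert spec.n_parameters() == 15 + 16 + 9 + 3 + 3

    def test_sampler_settings_validated(self):
        with pytest.raises(ValueError):
            SamplerSettings(chains=0)
        with pytest.raises(ValueError):
            SamplerSettings(target_accept=1.5)
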