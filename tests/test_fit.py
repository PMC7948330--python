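"""MGRLMM fitting: reductions with exact oracles, recovery, invariants."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from mgrlmm.model import MgrlmmSpec, SamplerSettings, fit_mgrlmm, summarize_fit
from mgrlmm.synthetic import generate_cohort, make_default_truth

_TOY_THRESHOLDS = ((-0.6, 0.8), (-0.4, 1.0))


def _toy_grm_table(n_subjects=5, true_loading=0.7, seed=0):
    """Two-item unidimensional graded-response data, two waves per subject."""
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n_subjects)
    rows = []
    loadings = (1.0, true_loading)
    for i in range(n_subjects):
        for wave in (1, 2):
            row = {"subject_id": f"s{i}", "wave": wave}
            for j, item in enumerate(("bmi", "tg")):
                b1, b2 = _TOY_THRESHOLDS[j]
                c1 = expit(loadings[j] * theta[i] - b1)
                c2 = expit(loadings[j] * theta[i] - b2)
                u = rng.uniform()
                row[f"item_{item}"] = int(u < c1) + int(u < c2)
            rows.append(row)
    return pd.DataFrame(rows)


def _toy_posterior_mean_by_quadrature(table):
    """Posterior mean of the free loading by brute-force integration.

    Uniform prior on the loading over (-1, 1) (the model's own prior),
    standard-normal subject trait integrated on a dense grid.
    """
    grid_a = np.linspace(-0.989, 0.989, 361)
    grid_u = np.linspace(-6, 6, 241)
    w_u = norm.pdf(grid_u)
    w_u /= w_u.sum()
    log_post = np.zeros_like(grid_a)
    for sid, sub in table.groupby("subject_id"):
        # likelihood of this subject's cells on the (a, u) grid
        like = np.ones((grid_a.size, grid_u.size))
        for _, row in sub.iterrows():
            for j, item in enumerate(("bmi", "tg")):
                load = (np.ones_like(grid_a) if j == 0 else grid_a)[:, None]
                b1, b2 = _TOY_THRESHOLDS[j]
                c1 = expit(load * grid_u[None, :] - b1)
                c2 = expit(load * grid_u[None, :] - b2)
                y = int(row[f"item_{item}"])
                p = (1 - c1, c1 - c2, c2)[y]
                like = like * p
        log_post += np.log(like @ w_u)
    post = np.exp(log_post - log_post.max())
    post /= post.sum()
    return float(np.sum(grid_a * post))


def test_unidimensional_reduction_matches_quadrature_oracle():
    """With one dimension, fixed thresholds and unit trait scale, the fitted
    free loading agrees with brute-force numerical integration."""
    table = _toy_grm_table(n_subjects=5, seed=0)
    exact = _toy_posterior_mean_by_quadrature(table)
    spec = MgrlmmSpec(
        n_dims=1,
        item_names=("bmi", "tg"),
        anchors=("bmi",),
        covariates=(),
        fixed_thresholds=_TOY_THRESHOLDS,
        fixed_re_sd=(1.0,),
        identity_corr=True,
        sampler=SamplerSettings(chains=2, warmup=500, draws=1500),
    )
    draws = fit_mgrlmm(table, spec, seed=1)
    a_draws = draws.loadings[:, 1, 0]
    mc_se = a_draws.std(ddof=1) / np.sqrt(a_draws.size / 10.0)  # conservative ESS
    assert a_draws.mean() == pytest.approx(exact, abs=3 * mc_se)


def test_fit_is_reproducible_from_seed():
    truth = make_default_truth(3)
    table = generate_cohort(truth, 40, seed=3)
    spec = MgrlmmSpec(
        n_dims=3,
        covariates=("dqi",),
        sampler=SamplerSettings(chains=1, warmup=100, draws=100),
    )
    a = fit_mgrlmm(table, spec, seed=9)
    b = fit_mgrlmm(table, spec, seed=9)
    np.testing.assert_array_equal(a.gamma, b.gamma)
    np.testing.assert_array_equal(a.u, b.u)
    np.testing.assert_array_equal(a.loglik, b.loglik)


def test_small_fit_satisfies_structural_constraints():
    truth = make_default_truth(3)
    table = generate_cohort(truth, 60, seed=4)
    spec = MgrlmmSpec(
        n_dims=3,
        covariates=("dqi", "age", "sex"),
        sampler=SamplerSettings(chains=2, warmup=200, draws=150),
    )
    draws = fit_mgrlmm(table, spec, seed=2)
    # anchors exactly one / zero in every draw
    for d, item in enumerate(("bmi", "tg", "bp")):
        j = spec.item_names.index(item)
        assert np.all(draws.loadings[:, j, d] == 1.0)
        off = [k for k in range(3) if k != d]
        assert np.all(draws.loadings[:, j, off] == 0.0)
    # ordered thresholds and valid correlation matrices in every draw
    assert np.all(draws.thresholds[:, :, 0] < draws.thresholds[:, :, 1])
    assert np.all(np.abs(draws.loadings[:, 3:, :]) < 1.0)
    for s in range(0, draws.n_draws, 50):
        np.testing.assert_allclose(np.diag(draws.re_corr[s]), 1.0, atol=1e-10)
        assert np.linalg.eigvalsh(draws.re_corr[s])[0] > 0
    # pointwise log likelihood is finite over observed cells
    assert np.all(np.isfinite(draws.loglik))


def test_structural_coefficients_sharpen_with_sample_size():
    """Posterior for the DQI coefficient concentrates as subjects are added."""
    truth = make_default_truth(1)
    sampler = SamplerSettings(chains=2, warmup=300, draws=300)
    spec = MgrlmmSpec(n_dims=1, covariates=("dqi", "age", "sex"), sampler=sampler)
    err = {}
    sd = {}
    for n in (100, 400):
        table = generate_cohort(truth, n, seed=5)
        draws = fit_mgrlmm(table, spec, seed=5)
        gamma = draws.gamma[:, 0, :]  # (S, 3)
        err[n] = np.abs(gamma.mean(axis=0) - truth.structural_coefs[0]).mean()
        sd[n] = gamma.std(axis=0, ddof=1).mean()
    assert sd[400] < sd[100]
    assert err[400] < err[100] + 2 * sd[400]  # bias shrinks up to posterior noise


def test_comparison_recovers_two_profile_truth():
    """Over candidates D in {1, 2, 3} on a two-profile cohort, the
    parsimony-aware comparison selects D = 2."""
    from mgrlmm.selection import compare_models

    truth = make_default_truth(2)
    table = generate_cohort(truth, 400, seed=1)
    fits = []
    for n_dims in (1, 2, 3):
        spec = MgrlmmSpec(
            n_dims=n_dims,
            covariates=("dqi", "age", "sex"),
            sampler=SamplerSettings(chains=2, warmup=250, draws=250),
        )
        fits.append((spec, fit_mgrlmm(table, spec, seed=1)))
    comparison = compare_models(fits)
    assert comparison.selected_n_dims == 2


def test_null_dqi_effect_recovered(null_fit):
    """A cohort generated with zero DQI effect yields CrIs containing zero."""
    truth0, spec, draws = null_fit
    summary = summarize_fit(draws)
    dqi_rows = summary.coefficient("dqi")
    assert len(dqi_rows) == 3
    assert not dqi_rows["excludes_zero"].any()
    assert summary.max_rhat < 1.1


class TestFitValidation:
    def setup_method(self):
        self.truth = make_default_truth(3)
        self.table = generate_cohort(self.truth, 30, seed=6)
        self.spec = MgrlmmSpec(
            n_dims=3,
            covariates=("dqi",),
            sampler=SamplerSettings(chains=1, warmup=10, draws=10),
        )

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            fit_mgrlmm(self.table, self.spec)

    def test_all_missing_item_named_in_error(self):
        table = self.table.copy()
        table["item_hscrp"] = np.nan
        with pytest.raises(ValueError, match="hscrp"):
            fit_mgrlmm(table, self.spec, seed=1)

    def test_single_wave_table_rejected(self):
        table = self.table[self.table["wave"] == 1].drop_duplicates("subject_id")
        with pytest.raises(ValueError, match="random effects"):
            fit_mgrlmm(table, self.spec, seed=1)

    def test_missing_covariate_column_rejected(self):
        table = self.table.drop(columns=["dqi"])
        with pytest.raises(ValueError, match="dqi"):
            fit_mgrlmm(table, self.spec, seed=1)
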