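"""WAIC, PSIS-LOO (against exact leave-one-out on a toy), model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import norm

from mgrlmm.model import MgrlmmSpec, PosteriorDraws
from mgrlmm.selection import compare_models, fit_gpd, psis_loo, waic


class TestWaic:
    def test_zero_variance_draws(self):
        ll = np.tile(np.log([0.3, 0.5, 0.7]), (50, 1))
        w, p_w, lppd = waic(ll)
        assert p_w == pytest.approx(0.0, abs=1e-12)
        assert w == pytest.approx(-2.0 * ll[0].sum())

    def test_single_cell_hand_arithmetic(self):
        ll = np.array([[np.log(0.5)], [np.log(0.25)]])
        _, _, lppd = waic(ll)
        assert lppd == pytest.approx(np.log(0.375))

    def test_matches_naive_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1.2, 0.4, size=(200, 10))
        w, p_w, lppd = waic(ll)
        # naive re-implementation, no log-space tricks
        lppd_naive = sum(np.log(np.mean(np.exp(ll[:, c]))) for c in range(10))
        p_naive = sum(np.var(ll[:, c], ddof=1) for c in range(10))
        assert lppd == pytest.approx(lppd_naive, abs=1e-10)
        assert p_w == pytest.approx(p_naive, abs=1e-10)
        assert w == pytest.approx(-2 * (lppd_naive - p_naive), abs=1e-10)

    def test_all_neg_inf_cell_is_an_error(self):
        ll = np.full((10, 2), -1.0)
        ll[:, 1] = -np.inf
        with pytest.raises(ValueError, match="1"):
            waic(ll)

    @given(st.integers(0, 2**31 - 1))
    def test_penalty_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        ll = rng.normal(size=(30, 5)) * rng.gamma(1.0, size=5)
        w, p_w, lppd = waic(ll)
        assert p_w >= 0.0
        assert w >= -2.0 * lppd


def _toy_posterior_grid(seed: int = 0):
    """Two-item unidimensional graded-response toy with a grid posterior.

    One free loading `a` (uniform grid prior), standard-normal latent trait
    per subject, fixed thresholds.  Returns everything needed to sample
    exact posterior draws and to evaluate exact leave-one-cell-out
    predictive densities by quadrature.
    """
    rng = np.random.default_rng(seed)
    n_subj, true_a = 8, 0.8
    thr = np.array([[-0.6, 0.8], [-0.4, 1.0]])
    loadings = np.array([1.0, true_a])
    theta = rng.standard_normal(n_subj)
    y = np.empty((n_subj, 2), dtype=int)
    for j in range(2):
        c1 = expit(loadings[j] * theta - thr[j, 0])
        c2 = expit(loadings[j] * theta - thr[j, 1])
        u = rng.uniform(size=n_subj)
        y[:, j] = (u < c1).astype(int) + (u < c2).astype(int)

    grid_a = np.linspace(-0.99, 0.99, 199)
    grid_u = np.linspace(-6.0, 6.0, 241)
    w_u = norm.pdf(grid_u)
    w_u /= w_u.sum()

    def cell_prob(a, j, yv, u):
        load = 1.0 if j == 0 else a
        c1 = expit(load * u - thr[j, 0])
        c2 = expit(load * u - thr[j, 1])
        return np.where(yv == 0, 1 - c1, np.where(yv == 1, c1 - c2, c2))

    # like[i, j, ia, iu] = P(y_ij | a, u)
    like = np.empty((n_subj, 2, grid_a.size, grid_u.size))
    for i in range(n_subj):
        for j in range(2):
            for ia, a in enumerate(grid_a):
                like[i, j, ia] = cell_prob(a, j, y[i, j], grid_u)
    return y, grid_a, grid_u, w_u, like


def _exact_loo(y, grid_a, w_u, like):
    """-2 * sum of exact log leave-one-cell-out predictive densities."""
    n_subj = y.shape[0]
    # subject-wise marginal over u with both items / with item j removed
    m_both = np.einsum("iau,u->ia", like[:, 0] * like[:, 1], w_u)  # (n, A)
    m_only = [np.einsum("iau,u->ia", like[:, 1 - j], w_u) for j in range(2)]
    log_z_full = np.log(m_both).sum(axis=0)  # per grid a (uniform prior)
    elpd = 0.0
    for i in range(n_subj):
        for j in range(2):
            log_z_minus = log_z_full - np.log(m_both[i]) + np.log(m_only[j][i])
            num = np.exp(log_z_full - log_z_full.max()).sum()
            den = np.exp(log_z_minus - log_z_full.max()).sum()
            elpd += np.log(num / den)
    return -2.0 * elpd


def _sample_toy_draws(y, grid_a, grid_u, w_u, like, n_draws, rng):
    n_subj = y.shape[0]
    m_both = np.einsum("iau,u->ia", like[:, 0] * like[:, 1], w_u)
    post_a = np.exp(np.log(m_both).sum(axis=0) - np.log(m_both).sum(axis=0).max())
    post_a /= post_a.sum()
    ia_draws = rng.choice(grid_a.size, size=n_draws, p=post_a)
    cond = like[:, 0] * like[:, 1] * w_u[None, None, :]  # (n, A, U)
    cdf = cond.cumsum(axis=2)
    cdf /= cdf[:, :, -1][:, :, None]
    ll = np.empty((n_draws, n_subj * 2))
    for i in range(n_subj):
        u_rand = rng.uniform(size=n_draws)
        iu = (cdf[i, ia_draws] < u_rand[:, None]).sum(axis=1)
        ll[:, 2 * i] = np.log(like[i, 0, ia_draws, iu])
        ll[:, 2 * i + 1] = np.log(like[i, 1, ia_draws, iu])
    return ll


class TestPsisLoo:
    def test_degenerate_weights_reduce_to_waic(self):
        ll = np.tile(np.log([0.2, 0.6, 0.9]), (120, 1))
        loo, p_loo, ks = psis_loo(ll)
        w, _, _ = waic(ll)
        assert loo == pytest.approx(w, abs=1e-10)
        assert np.all(np.isneginf(ks))
        assert p_loo == pytest.approx(0.0, abs=1e-10)

    def test_matches_exact_leave_one_out_on_toy(self):
        """PSIS-LOO sits within Monte-Carlo error of exact cell-deleted refits."""
        y, grid_a, grid_u, w_u, like = _toy_posterior_grid(seed=0)
        exact = _exact_loo(y, grid_a, w_u, like)
        loos = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            ll = _sample_toy_draws(y, grid_a, grid_u, w_u, like, 40000, rng)
            loos.append(psis_loo(ll)[0])
        loos = np.asarray(loos)
        mc_se = loos.std(ddof=1)
        assert abs(loos.mean() - exact) < 3.0 * mc_se + 0.05

    def test_heavy_tailed_cell_flagged(self):
        rng = np.random.default_rng(1)
        S = 2000
        ll = rng.normal(-1.0, 0.05, size=(S, 4))
        ll[:, 0] = -rng.exponential(scale=2.0, size=S)  # ratio tail index 1/2
        loo, p_loo, ks = psis_loo(ll)
        assert ks[0] > 0.7
        assert np.all(ks[1:] < 0.7)

    def test_warns_on_few_draws(self):
        with pytest.warns(UserWarning, match="draws"):
            psis_loo(np.random.default_rng(2).normal(size=(50, 3)))


def test_gpd_shape_recovery():
    """The quantile-anchored tail estimator recovers a known Pareto shape."""
    rng = np.random.default_rng(3)
    k_true, sigma_true = 0.5, 1.0
    u = rng.uniform(size=4000)
    x = sigma_true / k_true * ((1 - u) ** -k_true - 1)
    k_hat, sigma_hat = fit_gpd(x)
    assert k_hat == pytest.approx(k_true, abs=0.08)
    assert sigma_hat == pytest.approx(sigma_true, rel=0.15)


def _stub_draws(spec: MgrlmmSpec, ll: np.ndarray, fingerprint: str) -> PosteriorDraws:
    S = ll.shape[0]
    J, D = len(spec.item_names), spec.n_dims
    return PosteriorDraws(
        spec=spec,
        covariate_cols=["dqi"],
        subject_ids=np.array(["a"]),
        loadings=np.ones((S, J, D)),
        thresholds=np.tile([-1.0, 1.0], (S, J, 1)),
        gamma=np.zeros((S, D, 1)),
        re_sd=np.ones((S, D)),
        re_corr=np.tile(np.eye(D), (S, 1, 1)),
        u=np.zeros((S, 1, D)),
        loglik=ll,
        chain=np.zeros(S),
        cell_rows=np.arange(ll.shape[1]),
        cell_items=np.zeros(ll.shape[1], dtype=int),
        n_divergent=0,
        table_fingerprint=fingerprint,
    )


class TestCompareModels:
    def test_clear_winner_selected(self):
        rng = np.random.default_rng(4)
        ll_good = rng.normal(-1.0, 0.1, size=(200, 50))
        ll_bad = ll_good - 1.0  # uniformly worse fit
        a = _stub_draws(MgrlmmSpec(n_dims=2), ll_good, "t")
        b = _stub_draws(MgrlmmSpec(n_dims=3), ll_bad, "t")
        res = compare_models([(a.spec, a), (b.spec, b)])
        assert res.selected_n_dims == 2
        assert res.table.loc[res.table["n_dims"] == 2, "selected"].item()

    def test_near_tie_resolved_by_parsimony(self):
        rng = np.random.default_rng(3)
        base = rng.normal(-1.0, 0.3, size=(400, 80))
        # the larger model is marginally better, within one SE of the
        # pointwise WAIC difference
        better = base + rng.normal(0.003, 0.08, size=(1, base.shape[1]))
        small = _stub_draws(MgrlmmSpec(n_dims=3), base, "t")
        big = _stub_draws(MgrlmmSpec(n_dims=4), better, "t")
        res = compare_models([(small.spec, small), (big.spec, big)])
        w3 = res.table.loc[res.table["n_dims"] == 3, "waic"].item()
        w4 = res.table.loc[res.table["n_dims"] == 4, "waic"].item()
        assert w4 <= w3  # the big model does fit marginally better
        assert res.selected_n_dims == 3

    def test_mismatched_tables_rejected(self):
        rng = np.random.default_rng(6)
        ll = rng.normal(size=(50, 10))
        a = _stub_draws(MgrlmmSpec(n_dims=2), ll, "table-one")
        b = _stub_draws(MgrlmmSpec(n_dims=3), ll, "table-two")
        with pytest.raises(ValueError, match="different tables"):
            compare_models([(a.spec, a), (b.spec, b)])

    def test_needs_two_fits(self):
        a = _stub_draws(MgrlmmSpec(n_dims=2), np.zeros((10, 4)) - 1.0, "t")
        with pytest.raises(ValueError):
            compare_models([(a.spec, a)])
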