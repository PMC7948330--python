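"""WAIC, Pareto-smoothed importance-sampling LOO, and candidate-model comparison.

Both indices are reported on the deviance scale (-2 x expected log predictive
density) so that *lower is better*.  The comparison over candidate latent
dimensionalities ranks by WAIC but prefers a smaller model whose WAIC lies
within one standard error of the pairwise pointwise difference — a
parsimony-aware selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import MgrlmmSpec, PosteriorDraws

__all__ = ["waic", "psis_loo", "compare_models", "fit_gpd", "ModelComparison"]

PARETO_K_THRESHOLD = 0.7
_TAIL_FRACTION = 0.2


def waic(ll: np.ndarray) -> tuple[float, float, float]:
    """Watanabe–Akaike information criterion from pointwise log likelihood.

    Parameters
    ----------
    ll : (n_draws, n_cells) array
        Log likelihood of each observed cell under each posterior draw.

    Returns
    -------
    (waic, p_waic, lppd)
        ``lppd = sum_cells log mean_draws exp(ll)`` (log pointwise predictive
        density, computed stably), ``p_waic = sum_cells var_draws(ll)`` (the
        effective number of parameters), ``waic = -2 (lppd - p_waic)``.
    """
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("ll must be (n_draws >= 2, n_cells)")
    dead = np.all(np.isneginf(ll), axis=0)
    if dead.any():
        raise ValueError(f"cell(s) {np.nonzero(dead)[0][:5]} have zero likelihood in every draw")
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return -2.0 * (lppd - p_waic), p_waic, lppd


def fit_gpd(exceedances: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto distribution to tail exceedances.

    Uses the quantile-anchored profile-posterior estimator of Zhang &
    Stephens (2009): a grid over the transformed shape parameter weighted by
    profile likelihood.  Returns ``(k, sigma)`` in the (k > 0 heavy-tail)
    convention used by Pareto-smoothed importance sampling.
    """
    x = np.sort(np.asarray(exceedances, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 exceedances to fit the tail")
    prior_scale = x[int(n / 4 + 0.5) - 1]
    m = 30 + int(np.sqrt(n))
    j = np.arange(1, m + 1)
    theta = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (3.0 * prior_scale)
    xi_j = np.mean(np.log1p(-theta[:, None] * x[None, :]), axis=1)
    log_lik = n * (np.log(-theta / xi_j) - xi_j - 1.0)
    w = np.exp(log_lik - log_lik.max())
    w /= w.sum()
    theta_hat = float(np.sum(w * theta))
    k = float(np.mean(np.log1p(-theta_hat * x)))
    sigma = -k / theta_hat
    return k, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * (np.power(1.0 - p, -k) - 1.0)


def _smooth_cell(lw: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth one cell's shifted log importance weights."""
    S = lw.size
    n_tail = int(np.ceil(_TAIL_FRACTION * S))
    if np.ptp(lw) < 1e-12:
        return lw, -np.inf  # degenerate weights: nothing to smooth
    order = np.argsort(lw)
    tail_idx = order[-n_tail:]
    cutoff = lw[order[-n_tail - 1]] if n_tail < S else lw.min()
    exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
    positive = exceed > 0
    if positive.sum() < 5:
        warnings.warn(
            "fewer than 5 usable tail samples; falling back to truncated "
            "importance sampling for this cell",
            stacklevel=3,
        )
        return np.minimum(lw, lw.max()), float("nan")
    try:
        k, sigma = fit_gpd(exceed[positive])
    except ValueError:
        return np.minimum(lw, lw.max()), float("nan")
    out = lw.copy()
    ranks = np.empty(n_tail)
    sub_order = np.argsort(lw[tail_idx])
    ranks[sub_order] = (np.arange(1, n_tail + 1) - 0.5) / n_tail
    smoothed = np.log(np.exp(cutoff) + _gpd_quantile(ranks, k, sigma))
    out[tail_idx] = np.minimum(smoothed, lw.max())
    return out, k


def psis_loo(ll: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Leave-one-out deviance via Pareto-smoothed importance sampling.

    Per cell, importance ratios ``exp(-ll)`` target the leave-that-cell-out
    posterior; the top 20% of weights are replaced by quantiles of a fitted
    generalized Pareto tail and truncated at the raw maximum.  Returns
    ``(loo, p_loo, pareto_k)`` with ``loo`` on the deviance scale and a tail
    shape ``k`` per cell (k > 0.7 flags an unreliable cell; degenerate
    constant-weight cells report -inf).
    """
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("ll must be (n_draws >= 2, n_cells)")
    if ll.shape[0] < 100:
        warnings.warn("fewer than 100 draws: PSIS-LOO will be noisy", stacklevel=2)
    S, C = ll.shape
    elpd_i = np.empty(C)
    ks = np.empty(C)
    for c in range(C):
        lw_raw = -ll[:, c]
        lw = lw_raw - lw_raw.max()
        lw_s, k = _smooth_cell(lw)
        ks[c] = k
        elpd_i[c] = logsumexp(lw_s + ll[:, c]) - logsumexp(lw_s)
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    loo = -2.0 * float(elpd_i.sum())
    p_loo = float((lppd_i - elpd_i).sum())
    return loo, p_loo, ks


@dataclass
class ModelComparison:
    """Fit indices per candidate and the parsimony-aware verdict."""

    table: pd.DataFrame  # n_dims, n_parameters, waic, p_waic, lppd, loo, ...
    selected_n_dims: int

    def to_json_dict(self) -> dict:
        return {
            "selected_n_dims": int(self.selected_n_dims),
            "candidates": self.table.to_dict(orient="records"),
        }


def compare_models(
    fits: list[tuple[MgrlmmSpec, PosteriorDraws]],
    parsimony_se_factor: float = 1.0,
) -> ModelComparison:
    """Compare candidate MGRLMMs fitted to the same table.

    Ranks candidates by WAIC; if a model with fewer free parameters has WAIC
    within ``parsimony_se_factor`` standard errors of the pointwise WAIC
    difference to the minimiser, the smaller model is selected.  PSIS-LOO is
    reported alongside.  Fits on different tables raise.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fingerprints = {draws.table_fingerprint for _, draws in fits}
    if len(fingerprints) != 1:
        raise ValueError("fits were made on different tables; comparison invalid")

    rows = []
    pointwise = []
    for spec, draws in fits:
        w, p_w, lppd = waic(draws.loglik)
        loo, p_loo, ks = psis_loo(draws.loglik)
        S = draws.loglik.shape[0]
        lppd_i = logsumexp(draws.loglik, axis=0) - np.log(S)
        waic_i = -2.0 * (lppd_i - draws.loglik.var(axis=0, ddof=1))
        pointwise.append(waic_i)
        rows.append(
            {
                "n_dims": spec.n_dims,
                "n_parameters": spec.n_parameters(),
                "waic": w,
                "p_waic": p_w,
                "lppd": lppd,
                "loo": loo,
                "p_loo": p_loo,
                "max_pareto_k": float(np.nanmax(ks)) if np.isfinite(ks).any() else float("-inf"),
                "n_bad_k": int(np.sum(ks > PARETO_K_THRESHOLD)),
            }
        )
    tab = pd.DataFrame(rows)

    best = int(tab["waic"].idxmin())
    selected = best
    order = tab.sort_values("n_parameters").index
    for idx in order:
        if idx == best:
            break
        diff_i = pointwise[idx] - pointwise[best]
        se = float(np.sqrt(diff_i.size * diff_i.var(ddof=1)))
        if tab.loc[idx, "waic"] - tab.loc[best, "waic"] <= parsimony_se_factor * se:
            selected = int(idx)
            break
    tab["selected"] = [i == selected for i in tab.index]
    return ModelComparison(table=tab, selected_n_dims=int(tab.loc[selected, "n_dims"]))
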