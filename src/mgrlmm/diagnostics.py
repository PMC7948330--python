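"""Convergence diagnostics and posterior summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["split_rhat", "summarize_draws"]


def split_rhat(chains: np.ndarray) -> float:
    """Split Gelman–Rubin potential scale reduction factor.

    Parameters
    ----------
    chains : (n_chains, n_draws) array
        Post-warmup draws of one scalar parameter, one row per chain.  Each
        chain is split in half before computing the classic between/within
        variance ratio, so intra-chain trends inflate the statistic.

    Returns
    -------
    float
        The split R-hat; values near 1 indicate mixing (< 1.1 is the usual
        convergence bar).  NaN is returned for degenerate draws (zero within-
        chain variance, e.g. a constant parameter) — a documented sentinel.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    if n < 4:
        raise ValueError("split R-hat needs at least 4 draws per chain")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    k, n2 = split.shape
    within = split.var(axis=1, ddof=1)
    W = within.mean()
    if W <= 0.0 or not np.isfinite(W):
        return float("nan")
    B = n2 * split.mean(axis=1).var(ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_hat / W))


def summarize_draws(
    values: np.ndarray, chain: np.ndarray, names: list[str]
) -> pd.DataFrame:
    """Posterior mean, sd, equal-tailed 95% CrI and split R-hat per column.

    ``values`` is (n_draws_total, n_params) stacked across chains with the
    chain index of each draw in ``chain``.  Parameters whose credible
    interval excludes zero are flagged (the significance rule used for the
    structural coefficients); constant parameters (anchors) are flagged too.
    """
    values = np.asarray(values, dtype=float)
    chain = np.asarray(chain)
    chain_ids = np.unique(chain)
    rows = []
    for j, name in enumerate(names):
        col = values[:, j]
        lo, hi = np.quantile(col, [0.025, 0.975])
        constant = bool(np.ptp(col) == 0.0)
        per_chain_n = min((chain == c).sum() for c in chain_ids)
        if constant or chain_ids.size < 2 or per_chain_n < 4:
            rhat = float("nan")
        else:
            per_chain = np.asarray([col[chain == c] for c in chain_ids])
            rhat = split_rhat(per_chain)
        rows.append(
            {
                "parameter": name,
                "mean": col.mean(),
                "sd": col.std(ddof=1),
                "q2.5": lo,
                "q97.5": hi,
                "rhat": rhat,
                "excludes_zero": bool(lo > 0.0 or hi < 0.0),
                "constant": constant,
            }
        )
    return pd.DataFrame(rows)
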