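"""Exploratory dimensionality screen on the ordinal indicators.

Polychoric correlations (the correlation of the latent bivariate normal
assumed to underlie two ordinal variables) are estimated pairwise by the
standard two-step method — thresholds from inverse-normal cumulative
marginals, then the correlation by maximising the bivariate-normal
contingency likelihood.  The eigenvalues of the 8x8 polychoric matrix and
the Kaiser rule (eigenvalues > 1) screen the number of latent factors; the
screen's only job is to reject unidimensionality, so no rotation or loading
interpretation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .risk_coding import ITEM_NAMES

__all__ = [
    "PolychoricEstimate",
    "polychoric_corr",
    "polychoric_matrix",
    "eigen_screen",
    "scree_plot",
]

_RHO_BOUND = 0.999


@dataclass(frozen=True)
class PolychoricEstimate:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    loglik: float
    converged: bool
    at_boundary: bool = False


def _marginal_thresholds(x: np.ndarray, n_cat: int) -> np.ndarray:
    n = x.size
    cum = np.array([(x <= c).sum() / n for c in range(n_cat - 1)])
    cum = np.clip(cum, 1.0 / (n + 1), 1.0 - 1.0 / (n + 1))
    return norm.ppf(cum)


def _cell_counts(x: np.ndarray, y: np.ndarray, kx: int, ky: int) -> np.ndarray:
    counts = np.zeros((kx, ky))
    for a in range(kx):
        for b in range(ky):
            counts[a, b] = np.sum((x == a) & (y == b))
    return counts


def _cell_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal on the threshold grid."""
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])

    def cdf(a: float, b: float) -> float:
        if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
            return 0.0
        if np.isinf(a) and np.isinf(b):
            return 1.0
        if np.isinf(a):
            return norm.cdf(b)
        if np.isinf(b):
            return norm.cdf(a)
        return float(bvn.cdf([a, b]))

    kx, ky = tx.size + 1, ty.size + 1
    cum = np.array([[cdf(gx[i], gy[j]) for j in range(ky + 1)] for i in range(kx + 1)])
    probs = cum[1:, 1:] - cum[:-1, 1:] - cum[1:, :-1] + cum[:-1, :-1]
    return np.clip(probs, 1e-12, None)


def polychoric_corr(x, y) -> PolychoricEstimate:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds come from the inverse-normal cumulative marginals of each
    variable; the latent correlation maximises the contingency-table
    likelihood over (-1, 1) by bounded scalar optimisation (tolerance 1e-6).
    Variables must share length >= 30 and each show at least two categories.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 30:
        raise ValueError("need at least 30 paired observations")
    kx, ky = np.unique(x).size, np.unique(y).size
    if kx < 2 or ky < 2:
        raise ValueError("each variable needs at least 2 observed categories")
    n_cat_x, n_cat_y = int(x.max()) + 1, int(y.max()) + 1
    tx = _marginal_thresholds(x, n_cat_x)
    ty = _marginal_thresholds(y, n_cat_y)
    counts = _cell_counts(x, y, n_cat_x, n_cat_y)

    def nll(rho: float) -> float:
        return -float(np.sum(counts * np.log(_cell_probs(tx, ty, rho))))

    res = minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    at_boundary = abs(rho) > 0.95
    return PolychoricEstimate(
        rho=rho,
        thresholds_x=tx,
        thresholds_y=ty,
        loglik=-float(res.fun),
        converged=bool(res.success),
        at_boundary=at_boundary,
    )


def polychoric_matrix(table: pd.DataFrame, items: tuple[str, ...] = ITEM_NAMES) -> np.ndarray:
    """Pairwise polychoric correlation matrix of the coded items."""
    cols = [table[f"item_{item}"].to_numpy(dtype=int) for item in items]
    J = len(cols)
    R = np.eye(J)
    for a in range(J):
        for b in range(a + 1, J):
            R[a, b] = R[b, a] = polychoric_corr(cols[a], cols[b]).rho
    return R


def eigen_screen(corr_matrix: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Eigenvalues (descending) and the Kaiser factor count of a correlation matrix.

    The matrix must be symmetric with unit diagonal; if pairwise estimation
    left it indefinite, the nearest-PSD repair (eigenvalue clipping at 1e-8
    with diagonal renormalisation) is applied and flagged in the third
    return value.  The Kaiser count is the number of eigenvalues strictly
    greater than 1.
    """
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    vals = np.linalg.eigvalsh(R)
    repaired = False
    if vals[0] < 1e-8:
        repaired = True
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 1e-8, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        vals = np.linalg.eigvalsh(R)
    eigenvalues = np.sort(vals)[::-1]
    n_kaiser = int(np.sum(eigenvalues > 1.0))
    return eigenvalues, n_kaiser, repaired


def scree_plot(eigenvalues: np.ndarray, path) -> None:
    """Write a scree plot of the eigenvalue profile with the Kaiser line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, len(eigenvalues) + 1), eigenvalues, "o-")
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title("Scree of polychoric correlations")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
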