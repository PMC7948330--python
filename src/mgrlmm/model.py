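"""The Bayesian multidimensional graded-response linear mixed model (MGRLMM).

Measurement part: the eight ATP-III-coded risk factors are ordinal indicators
of D continuous latent profiles.  Item j has a loading row ``a_j`` (anchor
items fixed one-hot to identify scale and sign) and ordered thresholds
``b_j1 < b_j2`` on the logit scale:

    P(Y_rj >= k) = logistic(a_j . theta_r - b_jk),   k in {1, 2}.

Structural part: per subject-wave row r, the latent profile is

    theta_r = Gamma x_r + u_{subject(r)},   u_i ~ N_D(0, diag(sd) R diag(sd)),

with time-varying covariates x (the diet quality index plus confounders) and
correlated subject random effects.  Higher theta means more impaired risk
factors.  Missing ordinal cells simply drop out of the likelihood
(missing-at-random), which is how the unbalanced longitudinal panel is
handled.

Fitting is by NUTS-class Hamiltonian MCMC over the joint posterior with
analytic gradients (:mod:`mgrlmm._posterior`, :mod:`mgrlmm.sampler`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._posterior import MgrlmmPosterior
from .design import design_matrix, expanded_names
from .diagnostics import summarize_draws
from .risk_coding import ITEM_NAMES
from .sampler import nuts_chain

__all__ = [
    "MgrlmmSpec",
    "SamplerSettings",
    "PriorSettings",
    "ParamDraw",
    "PosteriorDraws",
    "FitSummary",
    "category_probs",
    "log_likelihood",
    "fit_mgrlmm",
    "summarize_fit",
]


def category_probs(
    theta: np.ndarray, loadings_j: np.ndarray, thresholds_j: Sequence[float]
) -> np.ndarray:
    """Graded-response category probabilities for one item.

    With ``eta = loadings_j . theta`` and ordered thresholds ``(b1, b2)``,
    the cumulative probabilities are ``P(Y>=1) = s(eta - b1)`` and
    ``P(Y>=2) = s(eta - b2)`` (s = logistic), giving

        P(0) = 1 - s(eta - b1),  P(1) = s(eta - b1) - s(eta - b2),
        P(2) = s(eta - b2).

    ``theta`` may be a single D-vector or an (..., D) stack; the result has a
    trailing axis of length 3 and sums to one.
    """
    b1, b2 = float(thresholds_j[0]), float(thresholds_j[1])
    if not b1 < b2:
        raise ValueError(f"thresholds must be strictly increasing, got ({b1}, {b2})")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    loadings_j = np.asarray(loadings_j, dtype=float)
    eta = theta @ loadings_j if theta.ndim > 1 else float(theta @ loadings_j)
    c1 = expit(eta - b1)
    c2 = expit(eta - b2)
    return np.stack([1.0 - c1, c1 - c2, c2], axis=-1)


@dataclass(frozen=True)
class PriorSettings:
    """Weakly informative prior scales (all positive).

    Free loadings are uniform on (-1, 1); thresholds are N(0, threshold_scale²)
    under an ordered transform; structural coefficients N(0, coef_scale²);
    random-effect sds half-normal(re_sd_scale); the random-effect correlation
    matrix gets independent uniform canonical partial correlations.
    """

    threshold_scale: float = 5.0
    coef_scale: float = 5.0
    re_sd_scale: float = 2.5

    def __post_init__(self) -> None:
        for name in ("threshold_scale", "coef_scale", "re_sd_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError("invalid sampler settings")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass(frozen=True)
class MgrlmmSpec:
    """Model definition: dimensionality, anchors, covariates, priors, sampler.

    ``anchors`` assigns one item per latent dimension whose loading is fixed
    at 1 on that dimension and 0 elsewhere; the default takes the first D of
    (bmi, tg, bp, ...), matching the three printed anchors for D=3.
    ``covariates`` are logical names expanded to reference-coded design
    columns; the diet quality index must be among them (an empty list is
    allowed only for measurement-only reductions used in validation).
    """

    n_dims: int = 3
    item_names: tuple[str, ...] = ITEM_NAMES
    anchors: tuple[str, ...] | None = None
    covariates: tuple[str, ...] = ("dqi",)
    priors: PriorSettings = field(default_factory=PriorSettings)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    # validation-only reductions (fix parts of the model):
    fixed_thresholds: tuple | None = None
    fixed_re_sd: tuple | None = None
    identity_corr: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.n_dims <= 6:
            raise ValueError("n_dims must be between 1 and 6")
        if self.n_dims > len(self.item_names):
            raise ValueError("more latent dimensions than items")
        anchors = self.resolved_anchors()
        if len(set(anchors)) != len(anchors):
            raise ValueError(f"anchor items must be distinct, got {anchors}")
        for a in anchors:
            if a not in self.item_names:
                raise ValueError(f"anchor {a!r} is not an item")
        if self.covariates and "dqi" not in self.covariates:
            raise ValueError("the diet quality index ('dqi') must be a covariate")

    def resolved_anchors(self) -> tuple[str, ...]:
        if self.anchors is not None:
            if len(self.anchors) != self.n_dims:
                raise ValueError("need exactly one anchor per dimension")
            return tuple(self.anchors)
        return tuple(self.item_names[: self.n_dims])

    def anchor_rows(self) -> np.ndarray:
        """(J, D) matrix of fixed loading rows; NaN marks a free loading."""
        rows = np.full((len(self.item_names), self.n_dims), np.nan)
        for d, item in enumerate(self.resolved_anchors()):
            j = self.item_names.index(item)
            rows[j, :] = 0.0
            rows[j, d] = 1.0
        return rows

    def n_parameters(self) -> int:
        """Free parameters excluding subject effects (for parsimony ranking)."""
        J, D = len(self.item_names), self.n_dims
        n_free_load = (J - D) * D
        n_thr = 0 if self.fixed_thresholds is not None else 2 * J
        n_gamma = D * len(expanded_names(list(self.covariates)))
        n_sd = 0 if self.fixed_re_sd is not None else D
        n_corr = 0 if (self.identity_corr or D == 1) else D * (D - 1) // 2
        return n_free_load + n_thr + n_gamma + n_sd + n_corr


@dataclass(frozen=True)
class ParamDraw:
    """One parameter draw, on the natural scale."""

    loadings: np.ndarray  # (J, D)
    thresholds: np.ndarray  # (J, 2)
    gamma: np.ndarray  # (D, P)
    u: Mapping[str, np.ndarray]  # subject_id -> (D,)
    covariates: tuple[str, ...]  # logical covariate names
    item_names: tuple[str, ...] = ITEM_NAMES


def _ordinal_matrix(table: pd.DataFrame, item_names: Sequence[str]) -> np.ndarray:
    y = np.full((len(table), len(item_names)), -1, dtype=int)
    for j, item in enumerate(item_names):
        col = table[f"item_{item}"]
        vals = col.to_numpy(dtype=float, na_value=np.nan)
        obs = ~np.isnan(vals)
        bad = obs & ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError(
                f"item {item!r} has codes outside {{0,1,2}} at rows {np.nonzero(bad)[0][:5]}"
            )
        y[obs, j] = vals[obs].astype(int)
    return y


def log_likelihood(table: pd.DataFrame, params: ParamDraw) -> np.ndarray:
    """Pointwise log likelihood of one draw, per observed (row, item) cell.

    Cells are ordered row-major (table row, then item).  Missing item codes
    contribute no cell.  Matches a naive per-cell lookup of
    :func:`category_probs` at ``theta = Gamma x + u``.
    """
    y = _ordinal_matrix(table, params.item_names)
    X, _ = design_matrix(table, list(params.covariates))
    U = np.asarray([params.u[s] for s in table["subject_id"]], dtype=float)
    theta = X @ params.gamma.T + U
    eta = theta @ params.loadings.T
    b1 = params.thresholds[:, 0][None, :]
    b2 = params.thresholds[:, 1][None, :]
    c1 = expit(eta - b1)
    c2 = expit(eta - b2)
    probs = np.stack([1.0 - c1, c1 - c2, c2], axis=-1)
    rows, items = np.nonzero(y >= 0)
    return np.log(probs[rows, items, y[rows, items]])


@dataclass
class PosteriorDraws:
    """Stacked MCMC draws of an MGRLMM fit, on the natural scale."""

    spec: MgrlmmSpec
    covariate_cols: list[str]
    subject_ids: np.ndarray
    loadings: np.ndarray  # (S, J, D)
    thresholds: np.ndarray  # (S, J, 2)
    gamma: np.ndarray  # (S, D, P)
    re_sd: np.ndarray  # (S, D)
    re_corr: np.ndarray  # (S, D, D)
    u: np.ndarray  # (S, N, D)
    loglik: np.ndarray  # (S, n_cells)
    chain: np.ndarray  # (S,)
    cell_rows: np.ndarray
    cell_items: np.ndarray
    n_divergent: int
    table_fingerprint: str

    @property
    def n_draws(self) -> int:
        return self.loadings.shape[0]

    def _monitored(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Flattened monitored parameters: loadings, thresholds, gamma, RE."""
        J, D = len(self.spec.item_names), self.spec.n_dims
        cols, names, blocks = [], [], []
        for j, item in enumerate(self.spec.item_names):
            for d in range(D):
                cols.append(self.loadings[:, j, d])
                names.append(f"loading[{item},{d + 1}]")
                blocks.append("loadings")
        for j, item in enumerate(self.spec.item_names):
            for k in range(2):
                cols.append(self.thresholds[:, j, k])
                names.append(f"threshold[{item},{k + 1}]")
                blocks.append("thresholds")
        for d in range(D):
            for p, cov in enumerate(self.covariate_cols):
                cols.append(self.gamma[:, d, p])
                names.append(f"gamma[{d + 1},{cov}]")
                blocks.append("gamma")
        for d in range(D):
            cols.append(self.re_sd[:, d])
            names.append(f"re_sd[{d + 1}]")
            blocks.append("re")
        for d1 in range(D):
            for d2 in range(d1 + 1, D):
                cols.append(self.re_corr[:, d1, d2])
                names.append(f"re_corr[{d1 + 1},{d2 + 1}]")
                blocks.append("re")
        return np.column_stack(cols), names, blocks

    def draw(self, s: int) -> ParamDraw:
        u = {sid: self.u[s, i] for i, sid in enumerate(self.subject_ids)}
        return ParamDraw(
            loadings=self.loadings[s],
            thresholds=self.thresholds[s],
            gamma=self.gamma[s],
            u=u,
            covariates=self.spec.covariates,
            item_names=self.spec.item_names,
        )


@dataclass
class FitSummary:
    """Per-parameter posterior summaries with convergence diagnostics."""

    table: pd.DataFrame  # parameter, mean, sd, CrI, rhat, flags, block
    max_rhat: float  # over non-constant loadings, thresholds and coefficients
    n_divergent: int

    def coefficient(self, cov_col: str) -> pd.DataFrame:
        """Rows for one structural design column across latent profiles."""
        mask = self.table["parameter"].str.contains(f",{cov_col}]", regex=False)
        return self.table[mask].reset_index(drop=True)


def summarize_fit(draws: PosteriorDraws) -> FitSummary:
    """Posterior mean, sd, 95% CrI and split R-hat for every parameter."""
    values, names, blocks = draws._monitored()
    tab = summarize_draws(values, draws.chain, names)
    tab["block"] = blocks
    core = tab[tab["block"].isin(["loadings", "thresholds", "gamma"]) & ~tab["constant"]]
    max_rhat = float(core["rhat"].max()) if len(core) else float("nan")
    return FitSummary(table=tab, max_rhat=max_rhat, n_divergent=draws.n_divergent)


def _validate_fit_inputs(table: pd.DataFrame, spec: MgrlmmSpec) -> None:
    problems = []
    for item in spec.item_names:
        col = f"item_{item}"
        if col not in table.columns:
            problems.append(f"missing item column {col!r}")
        elif table[col].notna().sum() == 0:
            problems.append(f"item {item!r} is entirely missing")
    if "subject_id" not in table.columns:
        problems.append("missing subject_id column")
    if problems:
        raise ValueError("; ".join(problems))
    waves_per_subject = table.groupby("subject_id").size()
    if (waves_per_subject >= 2).sum() == 0:
        raise ValueError(
            "no subject observed at 2+ waves: subject random effects unidentifiable"
        )


def fit_mgrlmm(
    table: pd.DataFrame, spec: MgrlmmSpec, seed: int | None = None
) -> PosteriorDraws:
    """Fit the MGRLMM by NUTS and return stacked posterior draws.

    ``seed`` (or ``spec.sampler.seed``) is required: chains use deterministic
    sub-streams of it, so a fit is fully reproducible from the spec, the
    table and the seed.  Anchor loadings are fixed at 1, thresholds are
    ordered by construction, and the pointwise log likelihood of every draw
    is stored for WAIC / PSIS-LOO.
    """
    if seed is None:
        seed = spec.sampler.seed
    if seed is None:
        raise ValueError("a seed is required for a reproducible fit")
    _validate_fit_inputs(table, spec)

    y = _ordinal_matrix(table, spec.item_names)
    X, cov_cols = design_matrix(table, list(spec.covariates))
    subject_ids, subj_idx = np.unique(table["subject_id"].to_numpy(), return_inverse=True)

    post = MgrlmmPosterior(
        y=y,
        X=X,
        subj_idx=subj_idx,
        n_subjects=len(subject_ids),
        anchor_rows=spec.anchor_rows(),
        threshold_scale=spec.priors.threshold_scale,
        coef_scale=spec.priors.coef_scale,
        re_sd_scale=spec.priors.re_sd_scale,
        fixed_thresholds=(
            None if spec.fixed_thresholds is None else np.asarray(spec.fixed_thresholds)
        ),
        fixed_re_sd=None if spec.fixed_re_sd is None else np.asarray(spec.fixed_re_sd),
        identity_corr=spec.identity_corr,
    )

    st = spec.sampler
    all_draws, chain_idx, n_div = [], [], 0
    for c in range(st.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c,)))
        z0 = post.initial_point(rng)
        res = nuts_chain(
            post.logp_grad,
            z0,
            n_warmup=st.warmup,
            n_draws=st.draws,
            rng=rng,
            target_accept=st.target_accept,
            max_treedepth=st.max_treedepth,
        )
        all_draws.append(res.draws)
        chain_idx.append(np.full(st.draws, c))
        n_div += res.n_divergent
    z = np.concatenate(all_draws, axis=0)
    chain = np.concatenate(chain_idx)

    S = z.shape[0]
    J, D, P, N = post.J, post.D, post.P, post.N
    out = PosteriorDraws(
        spec=spec,
        covariate_cols=cov_cols,
        subject_ids=subject_ids,
        loadings=np.empty((S, J, D)),
        thresholds=np.empty((S, J, 2)),
        gamma=np.empty((S, D, P)),
        re_sd=np.empty((S, D)),
        re_corr=np.empty((S, D, D)),
        u=np.empty((S, N, D)),
        loglik=np.empty((S, post.n_cells)),
        chain=chain,
        cell_rows=post.cell_rows,
        cell_items=post.cell_items,
        n_divergent=n_div,
        table_fingerprint=_table_fingerprint(table, spec),
    )
    for s in range(S):
        p = post.unpack(z[s])
        out.loadings[s] = p["loadings"]
        out.thresholds[s] = p["thresholds"]
        out.gamma[s] = p["gamma"]
        out.re_sd[s] = p["re_sd"]
        out.re_corr[s] = p["re_corr"]
        out.u[s] = p["u"]
        out.loglik[s] = post.pointwise_loglik(p)
    return out


def _table_fingerprint(table: pd.DataFrame, spec: MgrlmmSpec) -> str:
    import hashlib

    y = _ordinal_matrix(table, spec.item_names)
    h = hashlib.sha256()
    h.update(y.tobytes())
    h.update(table["subject_id"].astype(str).str.cat(sep="|").encode())
    return h.hexdigest()[:16]
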