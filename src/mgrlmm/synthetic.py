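"""Synthetic longitudinal cohorts with the statistical structure the MGRLMM assumes.

The generator emulates a three-wave adult cohort: eight three-category
ordinal risk indicators driven by D correlated latent profiles, a
time-varying diet quality index (DQI) with a declining secular trend and a
positive structural effect on every profile, fixed and time-varying
confounders, and per-wave inclusion matching the unbalanced panel of the
motivating study (wave record counts proportional to 2817 / 2840 / 1464 out
of 4390 subjects).  The default parameter set for three dimensions is the
published posterior: the factor-loading matrix with its three unit anchors
(BMI, TG, BP) and DQI structural coefficients (0.26, 0.14, 0.24).

Hidden ``truth_theta_*`` columns carry the generating latent profile scores
for parameter-recovery tests; they are never used in fitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .design import design_matrix
from .risk_coding import ITEM_NAMES
from .scoring import assign_tertiles

__all__ = [
    "CovariateModel",
    "SimTruth",
    "make_default_truth",
    "generate_cohort",
    "write_cohort",
    "read_truth",
]

#: Published per-wave record counts and the subject total they refer to.
WAVE_COUNTS = (2817, 2840, 1464)
N_SUBJECTS_REFERENCE = 4390

# Table-style marginal category shares at baseline, (P(normal), P(impaired))
# per item, used to place the default thresholds on the logit scale.
_BASELINE_MARGINALS: dict[str, tuple[float, float]] = {
    "bmi": (0.395, 0.207),
    "tg": (0.439, 0.316),
    "bp": (0.619, 0.220),
    "ldl": (0.517, 0.228),
    "fbg": (0.912, 0.057),
    "hdl": (0.102, 0.268),
    "wc": (0.346, 0.460),
    "hscrp": (0.041, 0.477),
}

# Posterior-mean loading matrix for the three-profile model
# (rows in ITEM_NAMES order; columns FPMS, DLCO, ILIS).
_LOADINGS_3D = np.array(
    [
        [1.00, 0.00, 0.00],  # bmi (anchor, profile 1)
        [0.00, 1.00, 0.00],  # tg (anchor, profile 2)
        [0.00, 0.00, 1.00],  # bp (anchor, profile 3)
        [0.06, -0.19, 0.22],  # ldl
        [-0.10, 0.66, 0.98],  # fbg
        [-0.11, 0.99, -0.32],  # hdl
        [0.98, -0.99, 0.91],  # wc
        [-0.03, 0.17, -0.09],  # hscrp
    ]
)

_DQI_EFFECT_3D = (0.26, 0.14, 0.24)


@dataclass(frozen=True)
class CovariateModel:
    """Distributions for the simulated covariates.

    Continuous parameters mirror the cohort's baseline summaries (age
    50.09 ± 11.21 years, 49.5% male, DQI wave means 1.02 / 0.74 / 0.67);
    binary and categorical prevalences follow the per-wave tabulated shares.
    ``dqi_age_slope`` (DQI units per year of age) is zero by default and
    exists to construct confounded scenarios.
    """

    age_mean: float = 50.09
    age_sd: float = 11.21
    male_p: float = 0.495
    dqi_wave_means: tuple[float, float, float] = (1.02, 0.74, 0.67)
    dqi_subject_sd: float = 0.15
    dqi_resid_sd: float = 0.22
    dqi_age_slope: float = 0.0
    urban_p: float = 0.72
    married_p: float = 0.922
    education_p: tuple[float, float, float] = (0.703, 0.235, 0.062)
    smoking_p: float = 0.219
    med_dyslipidemia_p: tuple[float, float, float] = (0.080, 0.155, 0.238)
    med_hypertension_p: tuple[float, float, float] = (0.114, 0.213, 0.268)
    med_diabetes_p: tuple[float, float, float] = (0.040, 0.107, 0.153)
    family_history_p: tuple[float, float, float] = (0.390, 0.689, 0.842)


@dataclass(frozen=True)
class SimTruth:
    """Generating parameter set; the ground truth for recovery tests."""

    n_dims: int
    loadings: np.ndarray  # (8, D); anchor rows one-hot
    anchors: tuple[str, ...]  # item anchoring each dimension
    thresholds: np.ndarray  # (8, 2), strictly increasing per item
    covariates: tuple[str, ...]  # logical structural covariates (incl. dqi)
    structural_coefs: np.ndarray  # (D, P expanded)
    re_sd: np.ndarray  # (D,)
    re_corr: np.ndarray  # (D, D)
    retention: tuple[float, float, float] = tuple(
        c / N_SUBJECTS_REFERENCE for c in WAVE_COUNTS
    )
    monotone: bool = False
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    item_names: tuple[str, ...] = ITEM_NAMES

    @property
    def dqi_effect(self) -> np.ndarray:
        """Structural coefficient of DQI per latent dimension."""
        from .design import expanded_names

        cols = expanded_names(list(self.covariates))
        return self.structural_coefs[:, cols.index("dqi")]

    def validate(self) -> None:
        problems = []
        D = self.n_dims
        if self.loadings.shape != (len(self.item_names), D):
            problems.append("loadings must be (n_items, n_dims)")
        else:
            for d, item in enumerate(self.anchors):
                j = self.item_names.index(item)
                row = np.zeros(D)
                row[d] = 1.0
                if not np.array_equal(self.loadings[j], row):
                    problems.append(
                        f"anchor {item!r} must load 1 on dimension {d + 1} and 0 elsewhere"
                    )
        if len(set(self.anchors)) != D:
            problems.append("anchors must be one distinct item per dimension")
        if not np.all(self.thresholds[:, 0] < self.thresholds[:, 1]):
            problems.append("thresholds must be strictly increasing within item")
        if not (np.all(self.re_sd > 0)):
            problems.append("random-effect sds must be positive")
        if self.re_corr.shape != (D, D) or not np.allclose(self.re_corr, self.re_corr.T):
            problems.append("re_corr must be a symmetric DxD matrix")
        elif not np.allclose(np.diag(self.re_corr), 1.0):
            problems.append("re_corr must have unit diagonal")
        elif np.linalg.eigvalsh(self.re_corr)[0] <= 0:
            problems.append("re_corr must be positive-definite")
        if not all(0 < r <= 1 for r in self.retention):
            problems.append("retention probabilities must lie in (0, 1]")
        if self.monotone and any(
            self.retention[t] > self.retention[t - 1] for t in (1, 2)
        ):
            problems.append(
                "monotone dropout needs non-increasing retention fractions"
            )
        if "dqi" not in self.covariates:
            problems.append("structural covariates must include 'dqi'")
        if problems:
            raise ValueError("invalid SimTruth: " + "; ".join(problems))


def _default_thresholds() -> np.ndarray:
    thr = np.empty((len(ITEM_NAMES), 2))
    for j, item in enumerate(ITEM_NAMES):
        p0, p2 = _BASELINE_MARGINALS[item]
        thr[j, 0] = logit(p0)
        thr[j, 1] = -logit(p2)
    return thr


def make_default_truth(n_dims: int) -> SimTruth:
    """The documented default generating truth for D latent dimensions.

    For ``n_dims=3`` the loading matrix and the per-dimension DQI
    coefficients are the published three-profile posterior means, with
    thresholds placed from the baseline marginal category shares.  For other
    D the anchors are the first D items, each remaining item loads 0.6 on one
    dimension in rotation, and the DQI effect is 0.25 per dimension.
    """
    if not isinstance(n_dims, (int, np.integer)) or not 1 <= n_dims <= 6:
        raise ValueError("n_dims must be an integer between 1 and 6")
    D = int(n_dims)
    J = len(ITEM_NAMES)
    anchors = ITEM_NAMES[:D]
    if D == 3:
        loadings = _LOADINGS_3D.copy()
        dqi_effect = np.array(_DQI_EFFECT_3D)
    else:
        loadings = np.zeros((J, D))
        for d in range(D):
            loadings[d, d] = 1.0
        for j in range(D, J):
            loadings[j, (j - D) % D] = 0.6
        dqi_effect = np.full(D, 0.25)
    covariates = ("dqi", "age", "sex")
    coefs = np.column_stack(
        [
            dqi_effect,
            np.full(D, 0.01),  # per year of (centred) age
            0.10 * (-1.0) ** np.arange(D),  # male vs female contrast
        ]
    )
    re_corr = np.full((D, D), 0.3)
    np.fill_diagonal(re_corr, 1.0)
    truth = SimTruth(
        n_dims=D,
        loadings=loadings,
        anchors=anchors,
        thresholds=_default_thresholds(),
        covariates=covariates,
        structural_coefs=coefs,
        re_sd=np.ones(D),
        re_corr=re_corr,
    )
    truth.validate()
    return truth


def _calibrate_logistic_intercept(shift: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + shift)) equals the target."""

    def f(a: float) -> float:
        return float(np.mean(expit(a + shift))) - target

    if target >= 1.0:
        return 30.0
    return brentq(f, -30.0, 30.0)


def generate_cohort(truth: SimTruth, n_subjects: int, seed: int) -> pd.DataFrame:
    """Draw one long-format cohort table from the generating truth.

    Subject random effects come from the D-variate normal implied by
    ``re_sd`` / ``re_corr``; latent profiles are the structural linear
    predictor plus the subject effect; ordinal items are drawn from the
    graded-response category probabilities; per-wave inclusion follows
    ``retention`` (independent per wave by default, or a monotone logistic
    dropout model depending on age and the previous wave's mean profile
    score when ``truth.monotone`` is set).  Fully reproducible from the seed;
    named sub-streams keep covariates, effects, items and retention draws
    independent.
    """
    truth.validate()
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    root = np.random.SeedSequence(entropy=seed)
    rng_cov, rng_re, rng_item, rng_ret = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    cm = truth.covariate_model
    D = truth.n_dims
    n = int(n_subjects)

    age = np.clip(rng_cov.normal(cm.age_mean, cm.age_sd, n), 35.0, 95.0)
    sex = np.where(rng_cov.uniform(size=n) < cm.male_p, "male", "female")
    education = rng_cov.choice([1, 2, 3], size=n, p=cm.education_p)
    residence = np.where(rng_cov.uniform(size=n) < cm.urban_p, "urban", "rural")
    marital = np.where(rng_cov.uniform(size=n) < cm.married_p, "married", "other")
    smoking = np.where(rng_cov.uniform(size=n) < cm.smoking_p, "ever", "never")
    dqi_int = rng_cov.normal(0.0, cm.dqi_subject_sd, n)
    # latent uniforms give within-subject monotone onset of meds/family history
    v_med = rng_cov.uniform(size=(4, n))

    L = np.linalg.cholesky(truth.re_corr)
    U = (rng_re.standard_normal((n, D)) @ L.T) * truth.re_sd[None, :]

    frames = []
    theta_prev_mean = np.zeros(n)
    present = np.ones(n, dtype=bool)
    for t in range(3):
        wave = t + 1
        dqi = (
            cm.dqi_wave_means[t]
            + dqi_int
            + cm.dqi_age_slope * (age - 50.0)
            + rng_cov.normal(0.0, cm.dqi_resid_sd, n)
        )
        dqi = np.clip(dqi, 0.0, 2.0)
        pa_met = rng_cov.lognormal(mean=6.5 - 0.15 * t, sigma=0.6, size=n)
        cop_ad = 100.0 * rng_cov.beta(2.0, 2.0, size=n)
        cop_mal = 100.0 * rng_cov.beta(1.5, 2.5, size=n)
        med_dys = (v_med[0] < cm.med_dyslipidemia_p[t]).astype(int)
        med_hyp = (v_med[1] < cm.med_hypertension_p[t]).astype(int)
        med_dia = (v_med[2] < cm.med_diabetes_p[t]).astype(int)
        famhist = (v_med[3] < cm.family_history_p[t]).astype(int)

        wave_df = pd.DataFrame(
            {
                "subject_id": [f"S{i:06d}" for i in range(n)],
                "wave": wave,
                "age": age + 6.0 * t,  # survey waves are ~6 years apart
                "sex": sex,
                "education": education,
                "residence": residence,
                "marital": marital,
                "smoking": smoking,
                "dqi": dqi,
                "pa_met": pa_met,
                "coping_adaptive_pct": cop_ad,
                "coping_maladaptive_pct": cop_mal,
                "med_dyslipidemia": med_dys,
                "med_hypertension": med_hyp,
                "med_diabetes": med_dia,
                "family_history": famhist,
            }
        )
        wave_df["pa_tertile"] = assign_tertiles(pa_met).labels
        wave_df["coping_adaptive_tertile"] = assign_tertiles(cop_ad).labels
        wave_df["coping_maladaptive_tertile"] = assign_tertiles(cop_mal).labels

        X, _ = design_matrix(wave_df, list(truth.covariates))
        theta = X @ truth.structural_coefs.T + U  # (n, D)
        eta = theta @ truth.loadings.T  # (n, J)
        c1 = expit(eta - truth.thresholds[:, 0][None, :])
        c2 = expit(eta - truth.thresholds[:, 1][None, :])
        u01 = rng_item.uniform(size=eta.shape)
        codes = (u01 < c1).astype(int) + (u01 < c2).astype(int)
        for j, item in enumerate(truth.item_names):
            wave_df[f"item_{item}"] = codes[:, j]
        for d in range(D):
            wave_df[f"truth_theta_{d + 1}"] = theta[:, d]

        if truth.monotone:
            target = truth.retention[t] / (truth.retention[t - 1] if t else 1.0)
            shift = 0.02 * (50.0 - age) + (-0.1) * theta_prev_mean
            alpha = _calibrate_logistic_intercept(shift[present], target)
            keep = rng_ret.uniform(size=n) < expit(alpha + shift)
            present = present & keep
            included = present.copy()
        else:
            included = rng_ret.uniform(size=n) < truth.retention[t]
        frames.append(wave_df[included])
        theta_prev_mean = theta.mean(axis=1)

    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["subject_id", "wave"], kind="stable").reset_index(drop=True)


def write_cohort(table: pd.DataFrame, truth: SimTruth, path: str | Path) -> None:
    """Write the cohort CSV plus a JSON sidecar holding the generating truth."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = path.with_suffix(".truth.json")
    payload = asdict(truth)
    for key in ("loadings", "thresholds", "structural_coefs", "re_sd", "re_corr"):
        payload[key] = np.asarray(payload[key]).tolist()
    sidecar.write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> SimTruth:
    """Load a truth sidecar written by :func:`write_cohort`."""
    payload = json.loads(Path(path).read_text())
    payload["covariate_model"] = CovariateModel(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload["covariate_model"].items()
        }
    )
    for key in ("loadings", "thresholds", "structural_coefs", "re_sd", "re_corr"):
        payload[key] = np.asarray(payload[key])
    for key in ("anchors", "covariates", "item_names"):
        payload[key] = tuple(payload[key])
    payload["retention"] = tuple(payload["retention"])
    return SimTruth(**payload)
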