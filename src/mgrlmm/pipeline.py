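"""End-to-end analysis orchestration.

Reads or simulates a long-format cohort, tabulates the ordinal risk-factor
categories the way the descriptive tables print them, runs the exploratory
dimensionality screen, fits the candidate MGRLMMs, compares them by
WAIC / PSIS-LOO, and runs the five-model covariate-adjustment ladder for the
diet-quality coefficient.  Every stage is deterministic given the config and
seed; outputs are plain CSV/JSON plus a manifest.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import expanded_names
from .efa import eigen_screen, polychoric_matrix, scree_plot
from .model import (
    MgrlmmSpec,
    PosteriorDraws,
    SamplerSettings,
    fit_mgrlmm,
    summarize_fit,
)
from .risk_coding import ITEM_NAMES, code_frame, count_impaired
from .selection import compare_models
from .synthetic import generate_cohort, make_default_truth

__all__ = [
    "LADDER",
    "CohortRead",
    "CategoryTabulation",
    "PipelineStageError",
    "read_cohort_csv",
    "tabulate_categories",
    "run_adjustment_ladder",
    "run_full_pipeline",
]

#: The five nested covariate-adjustment sets for the structural model.
LADDER: dict[int, tuple[str, ...]] = {
    1: ("dqi",),
    2: ("dqi", "age", "sex", "education", "marital", "residence"),
    3: (
        "dqi", "age", "sex", "education", "marital", "residence",
        "smoking", "physical_activity", "coping_adaptive", "coping_maladaptive",
    ),
    4: (
        "dqi", "age", "sex", "education", "marital", "residence",
        "smoking", "physical_activity", "coping_adaptive", "coping_maladaptive",
        "med_dyslipidemia", "med_hypertension", "med_diabetes",
    ),
    5: (
        "dqi", "age", "sex", "education", "marital", "residence",
        "smoking", "physical_activity", "coping_adaptive", "coping_maladaptive",
        "med_dyslipidemia", "med_hypertension", "med_diabetes", "family_history",
    ),
}

_REQUIRED_COLUMNS = ("subject_id", "wave") + tuple(f"item_{i}" for i in ITEM_NAMES)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CohortRead:
    """A validated cohort table plus the row-level rejection report."""

    table: pd.DataFrame
    rejects: pd.DataFrame  # original row index, reason


def read_cohort_csv(path: str | Path) -> CohortRead:
    """Read and validate a long-format cohort CSV.

    Schema errors (missing required column, empty file) raise; row-level
    problems (unknown wave, out-of-range ordinal code or DQI, duplicated
    subject-wave, negative measurement) reject the offending rows into the
    report instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} is empty or not a CSV") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    reasons: dict[int, str] = {}

    def reject(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask]:
            reasons.setdefault(idx, reason)

    reject(~df["wave"].isin([1, 2, 3]), "unknown wave")
    for item in ITEM_NAMES:
        col = pd.to_numeric(df[f"item_{item}"], errors="coerce")
        reject(df[f"item_{item}"].notna() & ~col.isin([0, 1, 2]), f"invalid code for {item}")
    if "dqi" in df.columns:
        dqi = pd.to_numeric(df["dqi"], errors="coerce")
        reject(df["dqi"].notna() & ~dqi.between(0.0, 2.0), "DQI outside [0, 2]")
    for col in ("sbp", "dbp", "bmi", "wc", "fbg", "tg", "ldl", "hdl", "hscrp"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            reject(df[col].notna() & (vals < 0), f"negative {col}")
    reject(df.duplicated(subset=["subject_id", "wave"], keep="first"), "duplicate subject-wave")

    reject_idx = sorted(reasons)
    rejects = pd.DataFrame(
        {"row": reject_idx, "reason": [reasons[i] for i in reject_idx]}
    )
    table = df.drop(index=reject_idx).reset_index(drop=True)
    for item in ITEM_NAMES:
        table[f"item_{item}"] = pd.array(
            pd.to_numeric(table[f"item_{item}"], errors="coerce"), dtype="Int64"
        )
    return CohortRead(table=table, rejects=rejects)


def _round_half_away(x: float, ndigits: int) -> float:
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass
class CategoryTabulation:
    """Per-wave category counts/percentages and the impaired-count distribution."""

    items: pd.DataFrame  # wave, item, category, count, pct (1 dp)
    impaired: pd.DataFrame  # wave, n_impaired, count, pct (2 dp)


def tabulate_categories(table: pd.DataFrame) -> CategoryTabulation:
    """Tabulate the coded items per wave the way descriptive tables print them.

    Per wave and item the three category counts use the wave's non-missing
    total as denominator with percentages rounded half-away-from-zero to one
    decimal; the distribution of the number of impaired factors (code 2,
    over rows with all eight items observed) is printed to two decimals.
    """
    item_rows = []
    impaired_rows = []
    for wave, wdf in table.groupby("wave"):
        for item in ITEM_NAMES:
            col = wdf[f"item_{item}"].dropna().astype(int)
            n = len(col)
            for cat, label in enumerate(("normal", "borderline", "impaired")):
                count = int((col == cat).sum())
                pct = _round_half_away(100.0 * count / n, 1) if n else float("nan")
                item_rows.append(
                    {"wave": wave, "item": item, "category": label,
                     "count": count, "pct": pct}
                )
        complete = wdf[[f"item_{i}" for i in ITEM_NAMES]].dropna()
        counts = np.zeros(9, dtype=int)
        for _, row in complete.iterrows():
            counts[count_impaired([int(v) for v in row])] += 1
        total = counts.sum()
        for k in range(9):
            if counts[k] == 0 and k > 5:
                continue
            pct = _round_half_away(100.0 * counts[k] / total, 2) if total else float("nan")
            impaired_rows.append(
                {"wave": wave, "n_impaired": k, "count": int(counts[k]), "pct": pct}
            )
    return CategoryTabulation(
        items=pd.DataFrame(item_rows), impaired=pd.DataFrame(impaired_rows)
    )


@dataclass
class LadderReport:
    """DQI coefficients per latent profile across the adjustment ladder."""

    coefficients: pd.DataFrame  # model, dimension, mean, sd, q2.5, q97.5, excludes_zero
    max_rhat: dict[int, float] = field(default_factory=dict)


def run_adjustment_ladder(
    table: pd.DataFrame,
    spec: MgrlmmSpec,
    seed: int,
    models: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> LadderReport:
    """Fit the nested covariate-adjustment ladder and report DQI coefficients.

    All covariates of the largest requested model must be present before any
    fitting starts (pre-flight check).  Model k's covariate set strictly
    contains model k-1's; each fit reports the DQI coefficient posterior
    (mean, sd, equal-tailed 95% CrI) per latent profile, flagging intervals
    that exclude zero.
    """
    models = tuple(sorted(models))
    for k in models:
        if k not in LADDER:
            raise ValueError(f"unknown ladder model {k}")
    # structural nesting check + pre-flight covariate availability
    for a, b in zip(models, models[1:]):
        if not set(LADDER[a]) < set(LADDER[b]):
            raise ValueError("ladder covariate sets must be strictly nested")
    try:
        expanded = expanded_names(list(LADDER[models[-1]]))
        from .design import design_matrix

        design_matrix(table.head(5), list(LADDER[models[-1]]))
    except ValueError as exc:
        raise ValueError(f"ladder pre-flight failed: {exc}") from exc

    rows = []
    rhats: dict[int, float] = {}
    for k in models:
        spec_k = replace(spec, covariates=LADDER[k])
        draws = fit_mgrlmm(table, spec_k, seed=seed + k)
        summ = summarize_fit(draws)
        rhats[k] = summ.max_rhat
        dqi_rows = summ.coefficient("dqi")
        for d, (_, r) in enumerate(dqi_rows.iterrows(), start=1):
            rows.append(
                {
                    "model": k,
                    "profile": d,
                    "mean": r["mean"],
                    "sd": r["sd"],
                    "q2.5": r["q2.5"],
                    "q97.5": r["q97.5"],
                    "excludes_zero": r["excludes_zero"],
                }
            )
    return LadderReport(coefficients=pd.DataFrame(rows), max_rhat=rhats)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def run_full_pipeline(config) -> Path:
    """Run simulate/load -> code -> EFA -> candidate fits -> comparison -> ladder.

    ``config`` is a mapping or a YAML path; see the bundled demo config for
    the schema.  Writes all tables, diagnostics and a manifest (seed,
    versions, stage timings) under ``output_dir`` and returns that path.
    Idempotent: identical config and seed give identical outputs.
    """
    cfg = _load_config(config)
    if "output_dir" not in cfg:
        raise ValueError("config needs an output_dir")
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": {},
        "config": {k: v for k, v in cfg.items() if k != "output_dir"},
    }

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - halt with stage-named error
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 2),
        }
        return result

    # --- input ----------------------------------------------------------
    def stage_input() -> pd.DataFrame:
        if "input_csv" in cfg:
            return read_cohort_csv(cfg["input_csv"]).table
        if "simulate" in cfg:
            sim = cfg["simulate"]
            truth = make_default_truth(int(sim.get("n_dims", 3)))
            table = generate_cohort(truth, int(sim["n_subjects"]), seed=seed)
            table.to_csv(out / "cohort.csv", index=False)
            return table
        raise ValueError("config needs either input_csv or a simulate block")

    table = run_stage("input", stage_input)

    def stage_code() -> pd.DataFrame:
        has_items = all(f"item_{i}" in table.columns for i in ITEM_NAMES)
        if has_items:
            return table
        return code_frame(table)

    table = run_stage("coding", stage_code)

    def stage_tabulate() -> CategoryTabulation:
        tab = tabulate_categories(table)
        tab.items.to_csv(out / "category_tabulation.csv", index=False)
        tab.impaired.to_csv(out / "impaired_distribution.csv", index=False)
        return tab

    run_stage("tabulate", stage_tabulate)

    def stage_efa():
        wave = int(cfg.get("efa", {}).get("wave", 1))
        base = table[table["wave"] == wave]
        R = polychoric_matrix(base)
        eigenvalues, n_kaiser, repaired = eigen_screen(R)
        pd.DataFrame(
            {"component": np.arange(1, len(eigenvalues) + 1), "eigenvalue": eigenvalues}
        ).to_csv(out / "efa_eigenvalues.csv", index=False)
        scree_plot(eigenvalues, out / "scree.png")
        manifest["efa"] = {"n_kaiser": n_kaiser, "psd_repaired": repaired}
        return n_kaiser

    run_stage("efa", stage_efa)

    sampler_cfg = cfg.get("sampler", {})
    sampler = SamplerSettings(
        chains=int(sampler_cfg.get("chains", 4)),
        warmup=int(sampler_cfg.get("warmup", 1000)),
        draws=int(sampler_cfg.get("draws", 1000)),
        target_accept=float(sampler_cfg.get("target_accept", 0.9)),
    )
    fit_covariates = tuple(cfg.get("fit_covariates", ("dqi", "age", "sex")))

    def stage_candidates():
        fits = []
        for D in cfg.get("candidates", [2, 3, 4, 5]):
            spec = MgrlmmSpec(n_dims=int(D), covariates=fit_covariates, sampler=sampler)
            draws = fit_mgrlmm(table, spec, seed=seed + 100 + int(D))
            summ = summarize_fit(draws)
            manifest.setdefault("fits", {})[f"D{D}"] = {
                "max_rhat": summ.max_rhat,
                "n_divergent": summ.n_divergent,
            }
            summ.table.to_csv(out / f"fit_D{D}_summary.csv", index=False)
            fits.append((spec, draws))
        return fits

    fits = run_stage("candidate_fits", stage_candidates)

    def stage_compare():
        comparison = compare_models(fits)
        comparison.table.to_csv(out / "model_comparison.csv", index=False)
        (out / "model_selection.json").write_text(
            json.dumps(comparison.to_json_dict(), indent=2)
        )
        return comparison

    comparison = run_stage("comparison", stage_compare)

    def stage_ladder():
        models = tuple(cfg.get("ladder_models", (1, 2, 3, 4, 5)))
        spec = MgrlmmSpec(
            n_dims=comparison.selected_n_dims, covariates=("dqi",), sampler=sampler
        )
        report = run_adjustment_ladder(table, spec, seed=seed + 500, models=models)
        report.coefficients.to_csv(out / "ladder_dqi_coefficients.csv", index=False)
        manifest["ladder_max_rhat"] = report.max_rhat
        return report

    run_stage("ladder", stage_ladder)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
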