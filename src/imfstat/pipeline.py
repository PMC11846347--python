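"""End-to-end orchestration: simulate -> preprocess -> match ->
classify -> ROC-GLM -> learning curves -> survival.

Two entry points mirror the two study arms:

* :func:`run_case_control` — per-stage matched designs, differential
  fingerprints, CV ROC/AUC, pooled ROC-GLM stage-effect regression
  with bootstrap Wald inference, and learning curves for the
  non-metastatic vs metastatic strata.
* :func:`run_survival` — KM curves and pairwise log-rank tests by
  sex/operability/stage/histology, nested-CV C-index of the ridge Cox
  model on spectra (and on each optional clinical marker column),
  censored-vs-deceased differential fingerprints at 1/2/3-year death
  horizons, and hazard-score associations.

Reports are plain dicts (JSON-serializable) embedding the seed, a
configuration hash, and the package version; every subject exclusion
is counted and logged with a reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .classify import fit_logistic_l2_cv, fit_inverse_power_law, learning_curve, svm_loocv_scores
from .fingerprint import differential_fingerprint
from .matching import match
from .preprocess import PreprocessConfig, SpectraMatrix, preprocess
from .rocglm import bootstrap_inference
from .survival import hazard_associations, km_fit, logrank, nested_cv_cindex
from .synthetic import (
    STAGES,
    SyntheticConfig,
    simulate_cohort,
    water_reference_spectrum,
)

logger = logging.getLogger(__name__)

__all__ = ["default_preprocess_config", "run_case_control", "run_survival"]


def _config_hash(config: SyntheticConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_preprocess_config(wavenumbers: np.ndarray, water_scale: float) -> PreprocessConfig:
    """Preprocessing config whose water correction exactly undoes the
    generator's overcompensation."""
    return PreprocessConfig(
        water_reference=water_reference_spectrum(wavenumbers),
        water_scale=water_scale,
    )


def _stage_tables(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    controls = cohort[cohort["group"] == "control"]
    per_stage = {
        s: cohort[(cohort["group"] == "case") & (cohort["stage"] == s)] for s in STAGES
    }
    return controls, per_stage


def run_case_control(
    config: SyntheticConfig,
    seed: int | None = None,
    n_boot: int = 1000,
    cv_folds: int = 10,
    learning_sizes: tuple[int, ...] | None = None,
    min_pairs: int = 10,
    with_learning: bool = True,
) -> dict[str, Any]:
    """Full case-control arm on a synthetic cohort.

    Per stage: matched design, differential fingerprint and mean
    effect size, cross-validated ROC/AUC.  Pooled over matched
    subjects: SVM leave-one-out scores feeding the ROC-GLM regression
    of the ROC curve on centered ordinal stage, with stratified
    bootstrap Wald inference.  Learning curves are fitted separately
    for the non-metastatic (stages I-III) and metastatic (stage IV)
    strata when the requested sizes are feasible.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng_seed = config.seed
    matrix, cohort = simulate_cohort(config)
    pp = default_preprocess_config(matrix.wavenumbers, config.water_overcompensation)
    spectra = preprocess(matrix, pp)
    controls, per_stage = _stage_tables(cohort)

    report: dict[str, Any] = {
        "seed": rng_seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_wavenumbers": spectra.n_wavenumbers,
        "stages": {},
        "exclusions": {},
    }
    pooled_case_ids: list[str] = []
    pooled_control_ids: list[str] = []
    pooled_stage: list[int] = []
    for s in STAGES:
        cases = per_stage[s]
        if len(cases) == 0:
            report["exclusions"][f"stage_{s}"] = "no cases"
            continue
        design = match(cases, controls)
        if design.n_pairs < min_pairs:
            logger.warning("stage %d skipped: only %d matched pairs", s, design.n_pairs)
            report["exclusions"][f"stage_{s}"] = f"only {design.n_pairs} matched pairs"
            continue
        case_ids = design.pairs["case_id"].tolist()
        control_ids = design.pairs["control_id"].tolist()
        case_spec = spectra.select_subjects(case_ids)
        ctrl_spec = spectra.select_subjects(control_ids)
        fp = differential_fingerprint(case_spec, ctrl_spec)
        X = np.vstack([case_spec.absorbance, ctrl_spec.absorbance])
        y = np.r_[np.ones(len(case_ids), int), np.zeros(len(control_ids), int)]
        folds = min(cv_folds, len(case_ids))
        cv = fit_logistic_l2_cv(X, y, folds=folds, seed=rng_seed)
        report["stages"][str(s)] = {
            "n_pairs": design.n_pairs,
            "n_unmatched_cases": len(design.unmatched_cases),
            "mean_auc": cv.mean_auc,
            "sd_auc": cv.sd_auc,
            "mean_effect_size": fp.mean_effect_size,
            "balance_smd_after": design.balance["smd_after"].to_dict(),
        }
        pooled_case_ids.extend(case_ids)
        pooled_stage.extend([s] * len(case_ids))
        for cid in control_ids:  # controls may recur across stage designs
            if cid not in pooled_control_ids:
                pooled_control_ids.append(cid)

    # pooled ROC-GLM: SVM LOOCV scores, Z = centered ordinal stage of cases
    if pooled_case_ids:
        case_spec = spectra.select_subjects(pooled_case_ids)
        ctrl_spec = spectra.select_subjects(pooled_control_ids)
        X = np.vstack([case_spec.absorbance, ctrl_spec.absorbance])
        y = np.r_[np.ones(len(pooled_case_ids), int), np.zeros(len(pooled_control_ids), int)]
        scores = svm_loocv_scores(X, y)
        case_scores = scores[: len(pooled_case_ids)]
        control_scores = scores[len(pooled_case_ids):]
        z = np.asarray(pooled_stage, dtype=float)
        z = z - z.mean()
        glm = bootstrap_inference(
            case_scores, control_scores, z, n_boot=n_boot, seed=rng_seed
        )
        report["roc_glm"] = {
            "coefficients": glm.coefficients(),
            "bootstrap_se": glm.bootstrap_se,
            "wald_z": glm.wald_z,
            "wald_p": glm.wald_p,
            "n_boot": glm.n_boot,
            "n_cases": glm.n_cases,
            "n_controls": glm.n_controls,
        }

        if not with_learning:
            return report
        # learning curves: non-metastatic (I-III) and metastatic (IV) strata
        report["learning_curves"] = {}
        strata = {
            "non_metastatic": [i for i, s in enumerate(pooled_stage) if s < 4],
            "stage_iv": [i for i, s in enumerate(pooled_stage) if s == 4],
        }
        for name, idx in strata.items():
            n_cases = len(idx)
            n_ctrl = len(pooled_control_ids)
            cap = 2 * min(n_cases, n_ctrl)
            sizes = (
                learning_sizes
                if learning_sizes is not None
                else tuple(int(v) for v in np.linspace(40, cap, 4) if v >= 40)
            )
            sizes = tuple(s for s in sizes if 20 <= s <= cap)
            if len(sizes) < 3:
                report["exclusions"][f"learning_{name}"] = "too few feasible sizes"
                continue
            sub_cases = case_spec.absorbance[idx]
            Xs = np.vstack([sub_cases, ctrl_spec.absorbance])
            ys = np.r_[np.ones(len(idx), int), np.zeros(n_ctrl, int)]
            aucs = learning_curve(Xs, ys, np.asarray(sizes), repeats=5, seed=rng_seed)
            fit = fit_inverse_power_law(np.asarray(sizes), aucs)
            report["learning_curves"][name] = {
                "sizes": list(map(int, sizes)),
                "mean_aucs": [float(a) for a in aucs],
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
            }
    return report


def _pairwise_logrank(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> dict[str, dict[str, float]]:
    """All pairwise log-rank p-values, raw and Holm-adjusted."""
    labels = [g for g in pd.unique(group) if g == g and g != ""]
    raw: dict[str, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            mask = (group == a) | (group == b)
            res = logrank(times[mask], events[mask], group[mask])
            raw[f"{a}_vs_{b}"] = res.p
    order = sorted(raw, key=raw.get)
    holm: dict[str, float] = {}
    m = len(order)
    running = 0.0
    for rank, key in enumerate(order):
        running = max(running, min(1.0, (m - rank) * raw[key]))
        holm[key] = running
    return {"raw": raw, "holm": holm}


def run_survival(
    config: SyntheticConfig,
    seed: int | None = None,
    outer: int = 10,
    inner: int = 3,
) -> dict[str, Any]:
    """Full survival arm on a synthetic case cohort.

    The cohort is the generated case population (controls carry no
    follow-up).  Subjects with missing stage are excluded from the
    stage-stratified analyses only, and every exclusion is counted.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng_seed = config.seed
    matrix, cohort = simulate_cohort(config)
    pp = default_preprocess_config(matrix.wavenumbers, config.water_overcompensation)
    spectra = preprocess(matrix, pp)
    cases = cohort[cohort["group"] == "case"].reset_index(drop=True)
    case_spec = spectra.select_subjects(cases["id"].tolist())
    times = cases["time_days"].to_numpy(float)
    events = cases["event"].to_numpy(int)

    report: dict[str, Any] = {
        "seed": rng_seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_patients": len(cases),
        "n_events": int(events.sum()),
        "exclusions": {},
        "km": {},
        "logrank": {},
    }

    strat_vars = {
        "sex": cases["sex"].astype(str).to_numpy(),
        "operable": cases["operable"].astype(str).to_numpy(),
        "stage": cases["stage"].to_numpy(float),
        "histology": cases["histology"].astype(str).to_numpy(),
    }
    for var, g in strat_vars.items():
        if var == "stage":
            keep = np.isfinite(g)
            report["exclusions"][f"km_{var}"] = int((~keep).sum())
            glab = np.array([f"stage{int(v)}" for v in g[keep]])
            t, e = times[keep], events[keep]
        else:
            keep = g != ""
            report["exclusions"][f"km_{var}"] = int((~keep).sum())
            glab, t, e = g[keep], times[keep], events[keep]
        if pd.unique(glab).size < 2:
            continue
        curves = km_fit(t, e, glab)
        report["km"][var] = {
            k: {"times": v.event_times.tolist(), "surv": v.survival_prob.tolist()}
            for k, v in curves.items()
        }
        report["logrank"][var] = _pairwise_logrank(t, e, glab)

    # nested-CV concordance of the ridge Cox model on the fingerprint
    cv = nested_cv_cindex(
        case_spec.absorbance, times, events, outer=outer, inner=inner, seed=rng_seed
    )
    report["cindex_imf"] = {
        "mean": cv.mean,
        "sd": cv.sd,
        "folds": cv.fold_cindices.tolist(),
        "n": len(cases),
    }
    # same protocol on each optional clinical marker column
    report["cindex_markers"] = {}
    for marker in config.marker_names:
        if marker not in cases.columns:
            continue
        col = cases[marker].to_numpy(float)
        usable = np.isfinite(col)
        report["exclusions"][f"marker_{marker}"] = int((~usable).sum())
        mcv = nested_cv_cindex(
            col[usable][:, None], times[usable], events[usable],
            outer=outer, inner=inner, seed=rng_seed,
        )
        report["cindex_markers"][marker] = {
            "mean": mcv.mean, "sd": mcv.sd, "n": int(usable.sum()),
        }

    # censored-vs-deceased differential fingerprints at death horizons
    report["death_horizon_fingerprints"] = {}
    censored_ids = cases.loc[events == 0, "id"].tolist()
    if len(censored_ids) >= 2:
        ctrl_spec = case_spec.select_subjects(censored_ids)
        for years in (1, 2, 3):
            mask = (events == 1) & (times <= years * 365.25)
            ids = cases.loc[mask, "id"].tolist()
            if len(ids) < 2:
                report["exclusions"][f"horizon_{years}y"] = "fewer than 2 deaths"
                continue
            fp = differential_fingerprint(case_spec.select_subjects(ids), ctrl_spec)
            report["death_horizon_fingerprints"][f"{years}y"] = {
                "n_deceased": len(ids),
                "n_censored": len(censored_ids),
                "mean_effect_size": fp.mean_effect_size,
            }

    # hazard-score associations, using honest out-of-fold risk scores;
    # the "hazard rate" is the Cox relative risk exp(linear predictor)
    hazard = np.exp(cv.oof_linear_predictor)
    assoc = hazard_associations(hazard, cases)
    report["associations"] = {
        k: {"statistic": v.statistic, "p": v.p, "n": v.n} for k, v in assoc.items()
    }
    return report
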