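"""Stage-stratified matched case-control design construction.

Cases are paired 1:1 to controls on (age, sex, BMI) by *optimal* pair
matching: minimum-total-Mahalanobis-distance assignment restricted to
pairs whose logit-propensity difference lies within a caliper
(default 0.2 SD of the logit propensity, the standard convention).
Optimality is a minimum-cost bipartite assignment, not greedy
nearest-neighbour.  Cases with no admissible control are reported
unmatched rather than failing the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = ["MatchedDesign", "estimate_propensity", "match", "balance_report"]

COVARIATES = ("age", "sex", "bmi")
_INADMISSIBLE = 1e12


@dataclass(frozen=True)
class MatchedDesign:
    """1:1 matched pairs with caliper bookkeeping and balance tables."""

    pairs: pd.DataFrame          # columns case_id, control_id, distance
    caliper_width: float         # in logit-propensity units
    unmatched_cases: list[str]
    balance: pd.DataFrame        # per-covariate SMD before/after

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def total_distance(self) -> float:
        return float(self.pairs["distance"].sum())


def estimate_propensity(
    covariates: pd.DataFrame, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-of-case score from a logit model on age, sex, BMI.

    Returns ``(score, logit_score)``.  Complete separation is surfaced
    as an error suggesting a caliper-free fallback.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("need at least one case and one control")
    raw = covariates[list(COVARIATES)].to_numpy(dtype=float)
    # zero-variance covariates carry no information and make the
    # Hessian singular; drop them (intercept-only fit if all constant)
    varying = raw.std(axis=0) > 0
    X = sm.add_constant(raw[:, varying], has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(labels, X).fit(disp=False, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(
            "propensity logit failed (possibly complete separation); "
            "consider matching without a caliper"
        ) from exc
    logit = X @ fit.params
    if not np.all(np.isfinite(logit)) or np.max(np.abs(logit)) > 30.0:
        raise ValueError(
            "propensity scores degenerate (complete separation?); "
            "consider matching without a caliper"
        )
    score = 1.0 / (1.0 + np.exp(-logit))
    return score, logit


def _mahalanobis_matrix(cases: pd.DataFrame, controls: pd.DataFrame) -> np.ndarray:
    """Pairwise Mahalanobis distances on (age, sex, bmi), pooled covariance."""
    xc = cases[list(COVARIATES)].to_numpy(dtype=float)
    xk = controls[list(COVARIATES)].to_numpy(dtype=float)
    pooled = np.vstack([xc, xk])
    cov = np.cov(pooled, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        vi = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        vi = np.linalg.inv(cov + 1e-8 * np.eye(cov.shape[0]))
    delta = xc[:, None, :] - xk[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", delta, vi, delta)
    return np.sqrt(np.maximum(d2, 0.0))


def match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    caliper_multiplier: float = 0.2,
) -> MatchedDesign:
    """Optimal caliper-constrained 1:1 matching of cases to controls.

    Parameters
    ----------
    cases, controls : DataFrame
        Must carry ``id`` plus the covariates age, sex (0/1), bmi.
    caliper_multiplier : float
        Caliper = multiplier x SD of the pooled logit propensity.
    """
    for name, df in (("cases", cases), ("controls", controls)):
        missing = [c for c in ("id", *COVARIATES) if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks columns {missing}")
    pooled = pd.concat([cases, controls], ignore_index=True)
    labels = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
    dist = _mahalanobis_matrix(cases, controls)
    try:
        _, logit = estimate_propensity(pooled, labels)
    except ValueError:
        # separation (common in tiny strata): fall back to caliper-free
        # optimal matching rather than failing the design
        logger.warning("propensity separation; matching without a caliper")
        caliper = np.inf
        admissible = np.ones(dist.shape, dtype=bool)
    else:
        sd_logit = float(np.std(logit, ddof=1)) if len(logit) > 1 else 0.0
        caliper = caliper_multiplier * sd_logit
        logit_c, logit_k = logit[: len(cases)], logit[len(cases):]
        admissible = np.abs(logit_c[:, None] - logit_k[None, :]) <= caliper
    cost = np.where(admissible, dist, _INADMISSIBLE)

    case_ids = cases["id"].tolist()
    control_ids = controls["id"].tolist()
    if not admissible.any():
        logger.warning("no admissible case-control pairs under caliper %.4g", caliper)
        empty = pd.DataFrame(columns=["case_id", "control_id", "distance"])
        bal = _balance_table(cases, controls, empty)
        return MatchedDesign(empty, caliper, list(case_ids), bal)

    row_ind, col_ind = linear_sum_assignment(cost)
    rows = []
    matched_cases = set()
    for i, j in zip(row_ind, col_ind):
        if admissible[i, j]:
            rows.append((case_ids[i], control_ids[j], float(dist[i, j])))
            matched_cases.add(case_ids[i])
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    unmatched = [c for c in case_ids if c not in matched_cases]
    if unmatched:
        logger.warning("%d cases left unmatched (caliper %.4g)", len(unmatched), caliper)
    bal = _balance_table(cases, controls, pairs)
    return MatchedDesign(pairs, caliper, unmatched, bal)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute standardized mean difference with the usual pooled-variance scale."""
    va = np.var(a, ddof=1) if len(a) > 1 else 0.0
    vb = np.var(b, ddof=1) if len(b) > 1 else 0.0
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0.0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf
    return float(abs(np.mean(a) - np.mean(b)) / denom)


def _balance_table(
    cases: pd.DataFrame, controls: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    rows = {}
    mc = cases.set_index("id").loc[pairs["case_id"]] if len(pairs) else cases.iloc[:0]
    mk = controls.set_index("id").loc[pairs["control_id"]] if len(pairs) else controls.iloc[:0]
    for cov in COVARIATES:
        before = _smd(cases[cov].to_numpy(float), controls[cov].to_numpy(float))
        after = (
            _smd(mc[cov].to_numpy(float), mk[cov].to_numpy(float))
            if len(pairs)
            else np.nan
        )
        rows[cov] = {"smd_before": before, "smd_after": after}
    return pd.DataFrame(rows).T


def balance_report(design: MatchedDesign) -> pd.DataFrame:
    """Per-covariate absolute SMD before vs after matching."""
    if design.n_pairs == 0:
        raise ValueError("empty design: no matched pairs to report balance for")
    return design.balance.copy()
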