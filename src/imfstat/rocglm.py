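"""Binormal ROC curves and covariate-adjusted ROC-GLM regression.

The binormal model writes the ROC curve as

    ROC(t) = Phi(alpha0 + alpha1 * Phi^-1(t)),

with Phi the standard normal CDF, t the false-positive rate, alpha0
the intercept and alpha1 the slope; its AUC is
Phi(alpha0 / sqrt(1 + alpha1^2)).  When case and control scores are
normal with means mu1, mu0 and SDs sigma1, sigma0, the parameters are
alpha0 = (mu1 - mu0)/sigma1 and alpha1 = sigma0/sigma1.

The covariate extension (ROC-GLM) models g(ROC_Z(t)) = h0(t) + beta*Z
with both the link g and the baseline h0 probit, so the baseline
curve stays binormal.  It is fitted semiparametrically through
*placement values*: each case score s is mapped to
PV = 1 - F0(s), with F0 the empirical control-score CDF; the binary
indicators U_it = 1{PV_i <= t} over an FPR grid have mean ROC_Z(t),
so a probit GLM of U on {1, Phi^-1(t), Z, Z*Phi^-1(t)} estimates
(alpha0, alpha1, beta_intercept, beta_slope).

Point estimates ignore the within-case correlation of the U_it; all
inference therefore comes from a case/control-stratified bootstrap
with Wald statistics, exactly as the design prescribes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import mannwhitneyu, norm

__all__ = [
    "BinormalROC",
    "RocGlmFit",
    "empirical_roc",
    "binormal_roc",
    "binormal_auc",
    "placement_values",
    "fit_roc_glm",
    "bootstrap_inference",
    "DEFAULT_FPR_GRID",
]

# 99 interior grid points; the endpoints 0/1 are excluded because
# Phi^-1 diverges there.
DEFAULT_FPR_GRID = np.linspace(0.01, 0.99, 99)


@dataclass(frozen=True)
class BinormalROC:
    alpha0: float
    alpha1: float

    def __post_init__(self) -> None:
        if not self.alpha1 > 0:
            raise ValueError("alpha1 must be positive for a proper ROC curve")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return norm.cdf(self.alpha0 + self.alpha1 * norm.ppf(t))

    @property
    def auc(self) -> float:
        return float(norm.cdf(self.alpha0 / np.sqrt(1.0 + self.alpha1**2)))


@dataclass(frozen=True)
class RocGlmFit:
    alpha0: float
    alpha1: float
    beta_intercept: float | None    # covariate effect on the intercept
    beta_slope: float | None        # covariate effect on the slope
    fpr_grid: np.ndarray
    n_cases: int
    n_controls: int
    bootstrap_se: dict[str, float] | None = None
    wald_z: dict[str, float] | None = None
    wald_p: dict[str, float] | None = None
    n_boot: int = 0

    @property
    def has_covariate(self) -> bool:
        return self.beta_intercept is not None

    def roc(self, t: np.ndarray, z: float = 0.0) -> np.ndarray:
        """Modeled ROC curve at covariate value ``z``."""
        eta = self.alpha0 + self.alpha1 * norm.ppf(t)
        if self.has_covariate:
            eta = eta + self.beta_intercept * z + self.beta_slope * z * norm.ppf(t)
        return norm.cdf(eta)

    def coefficients(self) -> dict[str, float]:
        out = {"alpha0": self.alpha0, "alpha1": self.alpha1}
        if self.has_covariate:
            out["beta_intercept"] = self.beta_intercept
            out["beta_slope"] = self.beta_slope
        return out


def binormal_roc(alpha0: float, alpha1: float) -> BinormalROC:
    return BinormalROC(alpha0, alpha1)


def binormal_auc(alpha0: float, alpha1: float) -> float:
    return BinormalROC(alpha0, alpha1).auc


def empirical_roc(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Step-function ROC over all thresholds plus ties-1/2 AUC.

    Returns (fpr, tpr, auc); the AUC equals the normalized
    Mann-Whitney U statistic with ties counted one half.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score groups must be non-empty")
    scores = np.r_[cases, controls]
    labels = np.r_[np.ones(cases.size), np.zeros(controls.size)]
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    distinct = np.r_[np.diff(scores) != 0, True]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    tpr = np.r_[0.0, tps / cases.size]
    fpr = np.r_[0.0, fps / controls.size]
    u = mannwhitneyu(cases, controls, alternative="two-sided").statistic
    auc = float(u / (cases.size * controls.size))
    return fpr, tpr, auc


def placement_values(case_scores: np.ndarray, control_scores: np.ndarray) -> np.ndarray:
    """PV_i = 1 - F0(s_i): the case score's upper tail in the control ECDF.

    Antitone in the case score; uniform on [0, 1] when cases follow
    the control distribution.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.sort(np.asarray(control_scores, dtype=float))
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score groups must be non-empty")
    cdf = np.searchsorted(controls, cases, side="right") / controls.size
    return 1.0 - cdf


def _probit_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """Probit-link binomial GLM by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    eps = 1e-10
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -8.0, 8.0)
        mu = np.clip(norm.cdf(eta), eps, 1 - eps)
        phi = norm.pdf(eta)
        w = phi**2 / (mu * (1.0 - mu))
        z = eta + (y - mu) / np.maximum(phi, eps)
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, WX.T @ z)
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            break
    return beta


def fit_roc_glm(
    case_scores: np.ndarray,
    control_scores: np.ndarray,
    case_covariates: np.ndarray | None = None,
    fpr_grid: np.ndarray | None = None,
) -> RocGlmFit:
    """Semiparametric ROC-GLM fit through placement values.

    ``case_covariates`` is the per-case covariate Z (e.g. centered
    ordinal tumor stage); a constant Z is dropped with a warning,
    reducing to the plain binormal fit.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size < 10 or controls.size < 10:
        raise ValueError("need at least 10 cases and 10 controls")
    grid = DEFAULT_FPR_GRID if fpr_grid is None else np.asarray(fpr_grid, dtype=float)
    if grid.min() <= 0.0 or grid.max() >= 1.0:
        raise ValueError("fpr_grid must lie strictly inside (0, 1)")
    z = None
    if case_covariates is not None:
        z = np.asarray(case_covariates, dtype=float)
        if z.shape != cases.shape:
            raise ValueError("case_covariates must have one value per case")
        if not np.all(np.isfinite(z)):
            raise ValueError("case_covariates must be finite")
        if np.ptp(z) == 0.0:
            warnings.warn("constant covariate Z; dropping beta terms", stacklevel=2)
            z = None

    pv = placement_values(cases, controls)
    qt = norm.ppf(grid)                       # Phi^-1(t) per grid point
    u = (pv[:, None] <= grid[None, :]).astype(float).ravel()
    n, m = cases.size, grid.size
    qt_full = np.tile(qt, n)
    cols = [np.ones(n * m), qt_full]
    if z is not None:
        z_full = np.repeat(z, m)
        cols += [z_full, z_full * qt_full]
    X = np.column_stack(cols)
    beta = _probit_irls(X, u)
    return RocGlmFit(
        alpha0=float(beta[0]),
        alpha1=float(beta[1]),
        beta_intercept=float(beta[2]) if z is not None else None,
        beta_slope=float(beta[3]) if z is not None else None,
        fpr_grid=grid,
        n_cases=n,
        n_controls=controls.size,
    )


def bootstrap_inference(
    case_scores: np.ndarray,
    control_scores: np.ndarray,
    case_covariates: np.ndarray | None = None,
    fpr_grid: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> RocGlmFit:
    """Stratified bootstrap SEs and Wald tests for the ROC-GLM fit.

    Cases (with their covariates) and controls are resampled with
    replacement *separately*; each resample is refitted.  SE is the SD
    of the coefficient draws; wald_z = estimate/SE and the two-sided p
    comes from the standard normal.  Failed refits are skipped and
    counted; more than 10% failures aborts.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit = fit_roc_glm(case_scores, control_scores, case_covariates, fpr_grid)
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    z = None if not fit.has_covariate else np.asarray(case_covariates, dtype=float)
    rng = np.random.default_rng(seed)
    names = list(fit.coefficients())
    draws: list[list[float]] = []
    failures = 0
    for _ in range(n_boot):
        ci = rng.integers(0, cases.size, cases.size)
        ki = rng.integers(0, controls.size, controls.size)
        try:
            bfit = fit_roc_glm(
                cases[ci],
                controls[ki],
                None if z is None else z[ci],
                fit.fpr_grid,
            )
            coefs = bfit.coefficients()
            if len(coefs) != len(names) or not all(np.isfinite(v) for v in coefs.values()):
                raise ValueError("degenerate bootstrap refit")
            draws.append([coefs[k] for k in names])
        except (ValueError, np.linalg.LinAlgError, UserWarning):
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    arr = np.asarray(draws)
    se = {k: float(arr[:, j].std(ddof=1)) for j, k in enumerate(names)}
    est = fit.coefficients()
    wald_z = {k: (est[k] / se[k] if se[k] > 0 else np.inf) for k in names}
    wald_p = {k: float(2.0 * norm.sf(abs(wz))) for k, wz in wald_z.items()}
    return replace(
        fit, bootstrap_se=se, wald_z=wald_z, wald_p=wald_p, n_boot=len(draws)
    )
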