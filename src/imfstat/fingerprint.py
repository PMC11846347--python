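"""Differential fingerprints and effect-size summaries.

A differential fingerprint is the per-wavenumber mean absorbance
difference between two groups of preprocessed spectra (cases minus
controls), displayed against the per-wavenumber standard deviation of
the controls.  The standardized companion is a per-wavenumber Cohen's
d with pooled SD; the scalar "mean effect size" is the mean of |d|
across wavenumbers — the differential pattern oscillates in sign, so
a signed mean would cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SpectraMatrix

__all__ = ["DifferentialFingerprint", "differential_fingerprint", "effect_size_curve"]


@dataclass(frozen=True)
class DifferentialFingerprint:
    wavenumbers: np.ndarray
    mean_diff: np.ndarray       # cases - controls, a.u.
    control_sd: np.ndarray      # sample SD of controls per wavenumber
    effect_size: np.ndarray     # Cohen's d per wavenumber
    mean_effect_size: float     # mean |d| across wavenumbers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber": self.wavenumbers,
                "mean_diff": self.mean_diff,
                "control_sd": self.control_sd,
                "effect_size": self.effect_size,
            }
        )


def _check_groups(cases: SpectraMatrix, controls: SpectraMatrix) -> None:
    if cases.wavenumbers.shape != controls.wavenumbers.shape or not np.array_equal(
        cases.wavenumbers, controls.wavenumbers
    ):
        raise ValueError("case and control spectra are on different wavenumber grids")
    if cases.n_subjects < 2 or controls.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")


def effect_size_curve(
    cases: SpectraMatrix, controls: SpectraMatrix
) -> tuple[np.ndarray, float]:
    """Per-wavenumber Cohen's d (pooled SD) and the scalar mean |d|.

    Wavenumbers where the pooled SD is zero get d = 0 with a warning;
    if the pooled SD vanishes everywhere the inputs are degenerate and
    an error is raised.
    """
    _check_groups(cases, controls)
    x, y = cases.absorbance, controls.absorbance
    n1, n0 = x.shape[0], y.shape[0]
    diff = x.mean(axis=0) - y.mean(axis=0)
    s1 = x.var(axis=0, ddof=1)
    s0 = y.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2))
    zero = pooled == 0.0
    if zero.all():
        raise ValueError("pooled SD is zero at every wavenumber (constant inputs)")
    if zero.any():
        warnings.warn(
            f"pooled SD is zero at {int(zero.sum())} wavenumbers; effect set to 0",
            stacklevel=2,
        )
    d = np.zeros_like(diff)
    np.divide(diff, pooled, out=d, where=~zero)
    return d, float(np.mean(np.abs(d)))


def differential_fingerprint(
    cases: SpectraMatrix, controls: SpectraMatrix
) -> DifferentialFingerprint:
    """Mean difference per wavenumber plus control SD and effect sizes."""
    _check_groups(cases, controls)
    mean_diff = cases.absorbance.mean(axis=0) - controls.absorbance.mean(axis=0)
    control_sd = controls.absorbance.std(axis=0, ddof=1)
    d, mean_d = effect_size_curve(cases, controls)
    return DifferentialFingerprint(
        wavenumbers=cases.wavenumbers.copy(),
        mean_diff=mean_diff,
        control_sd=control_sd,
        effect_size=d,
        mean_effect_size=mean_d,
    )
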