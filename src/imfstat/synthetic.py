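"""Synthetic FTIR serum cohort generator.

No patient-level data accompany the study design this package
implements, so every downstream stage is exercised on synthetic
cohorts with the statistical structure the analyses assume:

* mid-IR absorbance spectra on a uniform wavenumber grid (default
  950-3050 cm^-1 at 4 cm^-1 steps), built from a fixed smooth serum
  baseline of Gaussian bands (amide I ~1650, amide II ~1545,
  carbohydrate 1000-1200, lipid CH stretches 2850-2960 cm^-1);
* a disease signature — a fixed, unit-L2-norm band pattern
  concentrated in the informative 1000-1700 cm^-1 range — whose
  amplitude grows with tumor stage while its shape stays constant;
* instrument water overcompensation: a scaled reference water
  spectrum subtracted from every subject, so the preprocessing
  correction can be tested exactly;
* demographics (age, sex, BMI) as truncated normals per group, with
  per-stage parameters mirroring a realistic lung-cancer case-control
  cohort (e.g. stage IV: n=151, age 68+-9, 52% female, BMI 25+-5);
* right-censored overall survival from a Weibull proportional-hazards
  model whose log-hazard is linear in stage and in signature
  amplitude, with independent exponential dropout and administrative
  censoring at ~4 years.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SpectraMatrix

__all__ = [
    "Demographics",
    "SyntheticConfig",
    "DiseaseSignature",
    "water_reference_spectrum",
    "make_disease_signature",
    "generate_spectra",
    "generate_survival",
    "simulate_cohort",
]

STAGES = (1, 2, 3, 4)

# Smooth serum-like absorbance baseline: (center cm^-1, width cm^-1, height a.u.)
# Five broad overlapping protein/carbohydrate humps span 1000-1700 cm^-1
# (ending in amide II ~1560 and amide I ~1660) plus two lipid CH-stretch
# bands near 2900 cm^-1.  The same bands act as the subject-level
# variation components: each subject's band heights fluctuate
# independently, giving structured between-subject covariance.
DEFAULT_BASELINE_BANDS: tuple[tuple[float, float, float], ...] = (
    (1080.0, 90.0, 0.45),   # carbohydrate / phosphate envelope
    (1250.0, 80.0, 0.35),   # amide III region
    (1420.0, 80.0, 0.35),
    (1560.0, 70.0, 0.70),   # amide II
    (1660.0, 60.0, 1.00),   # amide I
    (2880.0, 40.0, 0.18),   # lipid CH symmetric stretch
    (2935.0, 35.0, 0.25),   # lipid CH asymmetric stretch
)

# Disease signature: an alternating-sign mixture of the same broad
# protein/carbohydrate components, so the disease shift lives inside
# the subspace of natural between-subject variation (a classifier must
# compete with biology, not just detector noise).  Unit L2 norm after
# summation.
DEFAULT_SIGNATURE_BANDS: tuple[tuple[float, float, float], ...] = (
    (1080.0, 90.0, 0.50),
    (1250.0, 80.0, -0.45),
    (1420.0, 80.0, 0.40),
    (1560.0, 70.0, -0.50),
    (1660.0, 60.0, 0.60),
)

# Reference liquid-water absorbance: OH bending ~1640, association band
# ~2130, OH stretch shoulder entering from >3050, libration tail from below.
_WATER_BANDS: tuple[tuple[float, float, float], ...] = (
    (700.0, 220.0, 0.50),
    (1643.0, 80.0, 1.00),
    (2130.0, 150.0, 0.15),
    (3400.0, 260.0, 1.20),
)


@dataclass(frozen=True)
class Demographics:
    """Truncated-normal demographics for one cohort group."""

    age_mean: float
    age_sd: float
    pct_female: float
    bmi_mean: float
    bmi_sd: float


DEFAULT_DEMOGRAPHICS: dict[str, Demographics] = {
    "control": Demographics(69.0, 9.0, 46.0, 26.0, 5.0),
    "stage1": Demographics(70.0, 9.0, 44.0, 26.0, 6.0),
    "stage2": Demographics(69.0, 8.0, 36.0, 25.0, 4.0),
    "stage3": Demographics(68.0, 10.0, 44.0, 26.0, 5.0),
    "stage4": Demographics(68.0, 9.0, 52.0, 25.0, 5.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study conditions of the target design: grid
    950-3050 cm^-1 at 4 cm^-1, per-stage case counts 39/33/94/151 with
    184 controls, signature amplitude nondecreasing in stage, ~4-year
    administrative censoring horizon.
    """

    n_controls: int = 184
    n_cases_per_stage: Mapping[int, int] = field(
        default_factory=lambda: {1: 39, 2: 33, 3: 94, 4: 151}
    )
    grid_start: float = 950.0
    grid_stop: float = 3050.0
    grid_step: float = 4.0
    baseline_bands: tuple[tuple[float, float, float], ...] = DEFAULT_BASELINE_BANDS
    signature_bands: tuple[tuple[float, float, float], ...] = DEFAULT_SIGNATURE_BANDS
    stage_amplitude: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.025, 2: 0.085, 3: 0.14, 4: 0.22}
    )
    n_cases_unknown_stage: int = 0    # staged disease, stage not recorded
    subject_sd: float = 0.05          # relative per-band height variation
    noise_sd: float = 0.003           # additive per-channel noise, a.u.
    water_overcompensation: float = 0.05  # a.u. multiplier on the water reference
    demographics: Mapping[str, Demographics] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    # Weibull proportional-hazards survival; the scale is the baseline
    # (zero linear predictor) characteristic time — all subjects carry
    # a positive stage/signature linear predictor, so observed medians
    # land within the ~4-year follow-up with roughly half the cohort
    # experiencing the event
    weibull_shape: float = 1.2
    weibull_scale_days: float = 26000.0
    beta_stage: float = 0.35          # log-hazard per stage unit
    beta_signature: float = 16.0      # log-hazard per unit signature amplitude
    admin_censor_days: float = 1460.0
    dropout_rate: float = 5e-5        # per-day exponential dropout hazard
    marker_names: tuple[str, ...] = ()
    marker_noise_sd: float = 1.0      # noise on synthetic clinical markers
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_stop <= self.grid_start:
            raise ValueError("grid_stop must exceed grid_start")
        if self.n_controls < 0 or any(v < 0 for v in self.n_cases_per_stage.values()):
            raise ValueError("subject counts must be nonnegative")
        if self.weibull_shape <= 0 or self.weibull_scale_days <= 0:
            raise ValueError("Weibull parameters must be positive")
        if any(a < 0 for a in self.stage_amplitude.values()):
            raise ValueError("stage amplitudes must be nonnegative")

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class DiseaseSignature:
    """Unit-L2-norm spectral pattern added to case spectra."""

    wavenumbers: np.ndarray
    delta_absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        da = np.asarray(self.delta_absorbance, dtype=float)
        if wn.shape != da.shape:
            raise ValueError("signature and grid lengths differ")
        if abs(np.linalg.norm(da) - 1.0) > 1e-9:
            raise ValueError("signature must have unit L2 norm")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "delta_absorbance", da)


def _gaussian_bands(wavenumbers: np.ndarray, bands) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    out = np.zeros_like(wn)
    for center, width, height in bands:
        out += height * np.exp(-0.5 * ((wn - center) / width) ** 2)
    return out


def water_reference_spectrum(wavenumbers: np.ndarray) -> np.ndarray:
    """Fixed reference water absorbance evaluated on a grid (a.u.)."""
    return _gaussian_bands(wavenumbers, _WATER_BANDS)


def make_disease_signature(config: SyntheticConfig) -> DiseaseSignature:
    """Sum the configured signature bands on the grid and L2-normalize.

    Deterministic given the configuration.
    """
    if not config.signature_bands:
        raise ValueError("signature_bands must be non-empty")
    wn = config.wavenumbers
    raw = _gaussian_bands(wn, config.signature_bands)
    norm = np.linalg.norm(raw)
    if norm == 0.0:
        raise ValueError("signature bands sum to zero on this grid")
    return DiseaseSignature(wn, raw / norm)


def _draw_demographics(
    rng: np.random.Generator, demo: Demographics, n: int
) -> pd.DataFrame:
    # truncated normals keep age within [18, 95] and BMI within [15, 50]
    def trunc(mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    return pd.DataFrame(
        {
            "age": trunc(demo.age_mean, demo.age_sd, 18.0, 95.0, n),
            "sex": (rng.random(n) < demo.pct_female / 100.0).astype(int),  # 1 = female
            "bmi": trunc(demo.bmi_mean, demo.bmi_sd, 15.0, 50.0, n),
        }
    )


_HISTOLOGIES = ("AC", "SCC", "LCC", "other")
_HISTOLOGY_PROBS = (0.65, 0.275, 0.045, 0.03)
_P_OPERABLE_BY_STAGE = {1: 0.90, 2: 0.80, 3: 0.50, 4: 0.15}


def generate_spectra(config: SyntheticConfig) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Draw the full cross-sectional cohort: spectra plus clinical table.

    Per subject the raw absorbance is

        baseline * (1 + u_i) + amplitude_i * signature + noise
        - water_overcompensation * water_reference

    with ``u_i ~ N(0, subject_sd)`` a subject-level baseline scale
    effect and amplitude 0 for controls, ``stage_amplitude[stage]``
    for cases.  The cohort table carries id, group, stage, signature
    amplitude, demographics, histology and operability.
    """
    rng = np.random.default_rng(config.seed)
    wn = config.wavenumbers
    baseline = _gaussian_bands(wn, config.baseline_bands)
    signature = make_disease_signature(config)
    water = water_reference_spectrum(wn)

    # (demographics key, true stage or None for controls, stage recorded?, n)
    groups: list[tuple[str, int | None, bool, int]] = [
        ("control", None, True, config.n_controls)
    ]
    for stage in STAGES:
        groups.append(
            (f"stage{stage}", stage, True, int(config.n_cases_per_stage.get(stage, 0)))
        )
    if config.n_cases_unknown_stage > 0:
        # staged disease whose stage was never recorded: draw the latent
        # stage uniformly, mark the table entry as missing
        unknown_counts = rng.multinomial(
            config.n_cases_unknown_stage, [0.25] * len(STAGES)
        )
        for stage, n_unknown in zip(STAGES, unknown_counts):
            groups.append((f"stage{stage}", stage, False, int(n_unknown)))

    frames = []
    spectra_blocks = []
    ids: list[str] = []
    counter = 0
    for group_name, stage, recorded, n in groups:
        if n == 0:
            continue
        demo = config.demographics[group_name]
        tab = _draw_demographics(rng, demo, n)
        amplitude = 0.0 if stage is None else float(config.stage_amplitude[stage])
        tab.insert(0, "id", [f"S{counter + i:04d}" for i in range(n)])
        counter += n
        tab["group"] = "control" if stage is None else "case"
        tab["stage"] = np.nan if (stage is None or not recorded) else stage
        tab["stage_latent"] = np.nan if stage is None else stage  # generator truth
        tab["amplitude"] = amplitude
        tab["histology"] = (
            [""] * n
            if stage is None
            else rng.choice(_HISTOLOGIES, size=n, p=_HISTOLOGY_PROBS)
        )
        tab["operable"] = (
            np.zeros(n, dtype=int)
            if stage is None
            else (rng.random(n) < _P_OPERABLE_BY_STAGE[stage]).astype(int)
        )
        # subject-level biology: each baseline band's height varies
        # independently by ~subject_sd (relative), producing structured
        # between-subject covariance that survives L2 normalization
        band_shapes = np.stack(
            [_gaussian_bands(wn, [band]) for band in config.baseline_bands]
        )
        band_effects = rng.normal(0.0, config.subject_sd, size=(n, band_shapes.shape[0]))
        noise = rng.normal(0.0, config.noise_sd, size=(n, wn.size))
        block = (
            baseline[None, :]
            + band_effects @ band_shapes
            + amplitude * signature.delta_absorbance[None, :]
            + noise
            - config.water_overcompensation * water[None, :]
        )
        frames.append(tab)
        spectra_blocks.append(block)
        ids.extend(tab["id"])

    if not ids:
        raise ValueError("configuration yields zero subjects")
    cohort = pd.concat(frames, ignore_index=True)
    matrix = SpectraMatrix(ids, wn, np.vstack(spectra_blocks))
    return matrix, cohort


def generate_survival(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Attach right-censored survival to a cohort table.

    Event times follow a Weibull proportional-hazards model: with
    baseline survivor S0(t) = exp(-(t/scale)^shape) and linear
    predictor lp = beta_stage*stage + beta_signature*amplitude, the
    event time is ``scale * (-log U / exp(lp))**(1/shape)``.  Observed
    time is the minimum of event time, exponential dropout, and the
    administrative horizon; the event indicator is set accordingly.
    """
    if config.admin_censor_days <= 0:
        raise ValueError("admin_censor_days must be positive (degenerate horizon)")
    for col in ("stage", "amplitude"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1_000_003
    )
    n = len(cohort)
    stage_col = "stage_latent" if "stage_latent" in cohort.columns else "stage"
    stage = cohort[stage_col].to_numpy(dtype=float)
    stage_term = np.where(
        np.isfinite(stage), stage, np.nanmean(stage) if np.isfinite(stage).any() else 0.0
    )
    lp = config.beta_stage * stage_term + config.beta_signature * cohort["amplitude"].to_numpy(dtype=float)
    u = rng.uniform(size=n)
    event_time = config.weibull_scale_days * (-np.log(u) / np.exp(lp)) ** (1.0 / config.weibull_shape)
    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    observed = np.minimum.reduce([event_time, dropout, np.full(n, config.admin_censor_days)])
    observed = np.maximum(observed, 1e-9)  # times strictly positive
    event = (event_time <= np.minimum(dropout, config.admin_censor_days)).astype(int)
    out = cohort.copy()
    out["time_days"] = observed
    out["event"] = event
    if config.marker_names:
        for k, name in enumerate(config.marker_names):
            mrng = np.random.default_rng(
                None if config.seed is None else config.seed + 7_000_019 + k
            )
            out[name] = lp + mrng.normal(0.0, config.marker_noise_sd, size=n)
    return out


def simulate_cohort(config: SyntheticConfig) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Spectra plus clinical table including survival, in one call."""
    matrix, cohort = generate_spectra(config)
    cohort = generate_survival(cohort, config)
    return matrix, cohort


def survival_arm_config(seed: int | None = None, **overrides) -> SyntheticConfig:
    """Default configuration of the survival study arm.

    160 therapy-naive cancer patients (no healthy controls), stage
    recorded for 95 of them (17/9/32/37 across stages I-IV) and
    missing for 65, followed for up to four years, with three
    synthetic clinical marker columns for head-to-head concordance
    comparisons.
    """
    params = dict(
        n_controls=0,
        n_cases_per_stage={1: 17, 2: 9, 3: 32, 4: 37},
        n_cases_unknown_stage=65,
        marker_names=("nse", "cea", "cyfra211"),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)
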