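"""Synthetic stroke cohorts and ADC/DWI lesion phantoms.

Real acute-stroke imaging with 90-day outcomes is not publicly
redistributable, so every downstream stage is exercised on synthetic data
with known ground truth:

* :func:`generate_clinical_cohort` draws a patient table whose covariate
  marginals, TOAST subtype mix and outcome prevalence default to a large
  single-center acute-ischemic-stroke cohort (n = 1003, 16.3% unfavorable
  90-day outcome, mRS > 2).  Covariate-outcome associations are injected
  through a logistic model whose intercept is calibrated so the expected
  unfavorable fraction equals ``p_unfavorable`` exactly; the default
  log-odds are all zero (marginals only), matching the mostly null clinical
  differences seen in such cohorts.
* :func:`generate_lesion_phantom` builds a 3D ellipsoidal lesion whose
  interior intensities are a stationary Gaussian random field (white noise
  convolved with an isotropic Gaussian kernel) plus unsmoothed voxel noise.
  The field's correlation length and contrast depend on the outcome class,
  so texture features carry a recoverable class signal: unfavorable lesions
  are rougher (shorter correlation length, higher contrast), the analogue of
  "more heterogeneous" infarcts.  Outcome class drives texture by
  construction — there is no latent model — which keeps signal-recovery
  tests interpretable.

No attempt is made to simulate brain anatomy, scanner physics or b-value
diffusion decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .errors import ConfigurationError
from .volumes import Volume, VOIMask

__all__ = [
    "TOAST_SUBTYPES",
    "CLINICAL_COLUMNS",
    "CohortConfig",
    "TextureEffect",
    "PhantomConfig",
    "generate_clinical_cohort",
    "generate_lesion_phantom",
    "write_cohort_csv",
    "read_cohort_csv",
]

TOAST_SUBTYPES = ("LAA", "CE", "SAO", "Other", "Undetermined")

#: Exact column order of the cohort table.
CLINICAL_COLUMNS = (
    "id",
    "age",
    "sex",
    "smoking",
    "drinking",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "atrial_fibrillation",
    "toast_subtype",
    "nihss",
    "ldl_c",
    "discharge_statin",
    "discharge_antiplatelet",
    "discharge_anticoagulant",
    "stroke_volume",
    "mrs_90d",
)

_BINARY_COVARIATES = (
    "sex",
    "smoking",
    "drinking",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "atrial_fibrillation",
    "discharge_statin",
    "discharge_antiplatelet",
    "discharge_anticoagulant",
)

# Pooled cohort marginals (prevalences, means/SDs) of the emulated
# 1003-patient population; "sex" codes male = 1.
_DEFAULT_MARGINALS: dict[str, object] = {
    "sex": 682 / 1003,
    "smoking": 378 / 1003,
    "drinking": 134 / 1003,
    "hypertension": 676 / 1003,
    "hyperlipidemia": 277 / 1003,
    "diabetes": 350 / 1003,
    "atrial_fibrillation": 113 / 1003,
    "discharge_statin": 634 / 1003,
    "discharge_antiplatelet": 897 / 1003,
    "discharge_anticoagulant": 45 / 1003,
    "age": (65.90, 12.44),
    "ldl_c": (3.02, 0.96),
    # log-scale (mu, sigma) for lognormal NIHSS and stroke volume, chosen to
    # match the printed medians/IQRs (median 3, IQR 1-4; median 1.68 ml,
    # IQR 0.70-7.12 ml)
    "nihss_log": (np.log(3.0), 0.9),
    "stroke_volume_log": (np.log(1.68), 1.35),
}

_DEFAULT_SUBTYPE_PROBS = (544 / 1003, 80 / 1003, 298 / 1003, 13 / 1003, 68 / 1003)

# Conditional mRS distributions: favorable over {0,1,2}; unfavorable over
# {3,4,5,6} matching the reported 74/47/28/14 split of 163 patients.
_MRS_FAVORABLE_P = (0.35, 0.40, 0.25)
_MRS_UNFAVORABLE_P = (74 / 163, 47 / 163, 28 / 163, 14 / 163)


@dataclass
class CohortConfig:
    """Study-condition knobs for the clinical table generator."""

    n_total: int = 1003
    p_unfavorable: float = 163 / 1003
    subtype_probs: tuple[float, ...] = _DEFAULT_SUBTYPE_PROBS
    covariate_marginals: dict = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    association_spec: dict = field(default_factory=dict)  # covariate -> log-odds shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ConfigurationError("n_total must be >= 2")
        if not 0.0 <= self.p_unfavorable <= 1.0:
            raise ConfigurationError("p_unfavorable must be in [0, 1]")
        sp = np.asarray(self.subtype_probs, dtype=float)
        if sp.size != 5 or (sp < 0).any() or (sp > 1).any():
            raise ConfigurationError("subtype_probs must be 5 probabilities")
        if abs(sp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subtype_probs must sum to 1")
        for prob_name in _BINARY_COVARIATES:
            p = self.covariate_marginals.get(prob_name, 0.5)
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigurationError(f"prevalence of {prob_name} must be in [0, 1]")
        for cov in self.association_spec:
            if cov not in _BINARY_COVARIATES:
                raise ConfigurationError(
                    f"association_spec only supports binary covariates, got {cov!r}"
                )


def _calibrated_intercept(lp: np.ndarray, p_target: float) -> float:
    """Intercept b0 with mean(sigmoid(b0 + lp)) == p_target."""
    if p_target <= 0.0:
        return -np.inf
    if p_target >= 1.0:
        return np.inf
    if np.ptp(lp) == 0:
        return float(special.logit(p_target) - lp[0])
    fun = lambda b0: special.expit(b0 + lp).mean() - p_target
    return float(optimize.brentq(fun, -40.0, 40.0))


def generate_clinical_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table; identical seeds give bit-identical tables.

    Covariates are sampled independently from their marginals, the 90-day
    outcome from a logistic model ``logit P(unfavorable) = b0 + sum_j
    beta_j x_j`` with ``beta`` from ``association_spec`` and ``b0``
    calibrated so the expected unfavorable fraction equals
    ``p_unfavorable``.  The mRS score is then drawn conditional on the
    outcome group (favorable over 0-2, unfavorable over 3-6).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    marg = cfg.covariate_marginals

    cols: dict[str, np.ndarray] = {"id": np.array([f"P{k:05d}" for k in range(n)])}
    age_mu, age_sd = marg.get("age", _DEFAULT_MARGINALS["age"])
    cols["age"] = np.round(np.clip(rng.normal(age_mu, age_sd, n), 18.0, 100.0), 1)
    for name in _BINARY_COVARIATES:
        p = float(marg.get(name, _DEFAULT_MARGINALS.get(name, 0.5)))
        cols[name] = (rng.random(n) < p).astype(np.int64)
    cols["toast_subtype"] = rng.choice(TOAST_SUBTYPES, size=n, p=np.asarray(cfg.subtype_probs))
    nihss_mu, nihss_sd = marg.get("nihss_log", _DEFAULT_MARGINALS["nihss_log"])
    cols["nihss"] = np.round(rng.lognormal(nihss_mu, nihss_sd, n)).astype(np.int64)
    ldl_mu, ldl_sd = marg.get("ldl_c", _DEFAULT_MARGINALS["ldl_c"])
    cols["ldl_c"] = np.round(np.clip(rng.normal(ldl_mu, ldl_sd, n), 0.3, None), 2)
    vol_mu, vol_sd = marg.get("stroke_volume_log", _DEFAULT_MARGINALS["stroke_volume_log"])
    cols["stroke_volume"] = np.round(rng.lognormal(vol_mu, vol_sd, n), 3)

    lp = np.zeros(n)
    for cov, beta in cfg.association_spec.items():
        lp += float(beta) * cols[cov].astype(float)
    b0 = _calibrated_intercept(lp, cfg.p_unfavorable)
    p_unfav = special.expit(b0 + lp) if np.isfinite(b0) else np.full(n, float(b0 > 0))
    unfavorable = rng.random(n) < p_unfav

    mrs = np.empty(n, dtype=np.int64)
    n_unfav = int(unfavorable.sum())
    mrs[unfavorable] = rng.choice([3, 4, 5, 6], size=n_unfav, p=_MRS_UNFAVORABLE_P)
    mrs[~unfavorable] = rng.choice([0, 1, 2], size=n - n_unfav, p=_MRS_FAVORABLE_P)
    cols["mrs_90d"] = mrs

    return pd.DataFrame({c: cols[c] for c in CLINICAL_COLUMNS})


@dataclass
class TextureEffect:
    """Class-dependent second-order structure of the lesion random field.

    ``corr_length_*`` is the Gaussian smoothing sigma in voxels (spatial
    correlation length); ``contrast_*`` multiplies the smooth-field standard
    deviation.  Equal values for both classes give a null effect.
    """

    corr_length_favorable: float = 1.8
    corr_length_unfavorable: float = 0.9
    contrast_favorable: float = 1.0
    contrast_unfavorable: float = 1.4

    @classmethod
    def none(cls) -> "TextureEffect":
        return cls(1.8, 1.8, 1.0, 1.0)

    def params(self, outcome_class: int) -> tuple[float, float]:
        if outcome_class not in (0, 1):
            raise ConfigurationError(f"outcome_class must be 0 or 1, got {outcome_class}")
        if outcome_class:
            return self.corr_length_unfavorable, self.contrast_unfavorable
        return self.corr_length_favorable, self.contrast_favorable

    def __post_init__(self) -> None:
        if min(self.corr_length_favorable, self.corr_length_unfavorable) <= 0:
            raise ConfigurationError("correlation lengths must be > 0")


@dataclass
class PhantomConfig:
    """Geometry and intensity model of one lesion phantom.

    Defaults emulate a small-to-medium acute infarct on a 1 mm isotropic
    grid: ellipsoid semi-axes drawn uniformly from ``lesion_axes_range`` mm
    (volumes roughly 0.07-1.4 ml), reduced-ADC interior around
    ``base_adc_mean`` (1e-6 mm^2/s units) with hyperintense DWI counterpart.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_axes_range: tuple[float, float] = (2.5, 7.0)
    base_adc_mean: float = 600.0
    base_adc_sd: float = 100.0
    base_dwi_mean: float = 1100.0
    base_dwi_sd: float = 120.0
    background_adc_mean: float = 900.0
    noise_sd: float = 30.0
    texture_effect: TextureEffect = field(default_factory=TextureEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 4 for g in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 integers >= 4")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing must be positive")
        lo, hi = self.lesion_axes_range
        if not 0 < lo <= hi:
            raise ConfigurationError("lesion_axes_range must satisfy 0 < lo <= hi")
        # the largest semi-axis (in voxels) must fit inside the grid half-extent
        for g, sp in zip(self.grid_shape, self.voxel_spacing):
            if hi / sp > (g - 1) / 2.0:
                raise ConfigurationError(
                    f"lesion semi-axis {hi} mm does not fit in grid extent {g} voxels @ {sp} mm"
                )


def _smooth_unit_field(shape, sigma, rng) -> np.ndarray:
    """White Gaussian noise convolved with an isotropic Gaussian kernel,
    rescaled to unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_lesion_phantom(
    config: PhantomConfig,
    outcome_class: int,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, Volume, VOIMask]:
    """One paired (ADC, DWI, mask) phantom for the given outcome class.

    The mask is a single connected ellipsoid; interior ADC intensities are
    ``base_adc_mean + contrast * base_adc_sd * field + noise``, with
    ``field`` a unit-variance Gaussian random field of class-dependent
    correlation length.  The DWI volume shares the grid and the field
    (negated: low ADC corresponds to bright DWI).  A fresh generator seeded
    from ``config.seed`` is used when ``rng`` is not supplied, so equal
    seeds give identical volumes.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    corr_len, contrast = cfg.texture_effect.params(outcome_class)
    shape = cfg.grid_shape
    spacing = np.asarray(cfg.voxel_spacing, dtype=float)

    lo, hi = cfg.lesion_axes_range
    axes_mm = rng.uniform(lo, hi, size=3)
    center = (np.asarray(shape) - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum(((g - c) * sp / a) ** 2 for g, c, a, sp in zip(grids, center, axes_mm, spacing))
    mask_arr = r2 <= 1.0
    if not mask_arr.any():
        raise ConfigurationError("lesion ellipsoid contains no voxels; enlarge lesion_axes_range")
    # keep the largest connected component (ellipsoids are connected anyway)
    lab, n_lab = ndimage.label(mask_arr)
    if n_lab > 1:
        mask_arr = lab == (np.bincount(lab.ravel())[1:].argmax() + 1)

    field = _smooth_unit_field(shape, corr_len, rng)
    noise_adc = rng.standard_normal(shape) * cfg.noise_sd
    noise_dwi = rng.standard_normal(shape) * cfg.noise_sd
    bg = cfg.background_adc_mean + rng.standard_normal(shape) * cfg.noise_sd

    adc = np.where(
        mask_arr, cfg.base_adc_mean + contrast * cfg.base_adc_sd * field + noise_adc, bg
    )
    dwi = np.where(
        mask_arr,
        cfg.base_dwi_mean - contrast * cfg.base_dwi_sd * field + noise_dwi,
        cfg.base_dwi_mean - 400.0 + rng.standard_normal(shape) * cfg.noise_sd,
    )

    spacing_t = tuple(float(s) for s in spacing)
    return (
        Volume(data=adc, spacing=spacing_t),
        Volume(data=dwi, spacing=spacing_t),
        VOIMask(data=mask_arr, spacing=spacing_t),
    )


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"cohort table missing columns: {sorted(missing)}")
    return df
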