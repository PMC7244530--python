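"""Synthetic data with known ground truth for every downstream stage.

Three generators:

* :func:`generate_spectral_noise_image` — images whose radially averaged
  power spectrum follows a prescribed power law ``f^beta``, built by
  random-phase Fourier filtering (white Gaussian noise with amplitudes
  scaled by ``f^(beta/2)``).  Natural scenes have beta roughly in
  [-3.5, -1.5]; the generator accepts any exponent.
* :func:`generate_sensitivity_curves` — smooth unimodal (Gaussian in
  wavelength) receptor sensitivity templates, peak-normalized to 1.
* :func:`generate_study_dataset` — a simulated study table from a Gaussian
  hierarchical model: fish slope = intercept + effect * habitat slope
  + species effect (multivariate normal with Brownian tree covariance)
  + site effect + sex effect + residual noise.

All generators are pure functions of their configurations, including
seeds: the same config always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .imaging import LuminanceImage, SensitivityCurve
from .inference import Phylogeny, phylo_covariance

__all__ = [
    "SpectralNoiseConfig",
    "StudySimConfig",
    "generate_spectral_noise_image",
    "generate_sensitivity_curves",
    "generate_training_spectra",
    "generate_study_dataset",
]


@dataclass(frozen=True)
class SpectralNoiseConfig:
    """Prescription for one power-law noise image.

    ``beta`` is the spectral exponent (power proportional to ``f^beta``);
    ``mean_level`` and ``contrast`` set the linear-intensity mean and the
    RMS fluctuation as a fraction of the mean.  The default contrast of
    0.2 keeps +/-3 sigma inside [0, 1] for mid-grey images, so clipping is
    rare and the realized spectrum stays close to the prescription.
    """

    side_px: int
    beta: float
    mean_level: float = 0.5
    contrast: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_px < 32 or self.side_px % 2:
            raise ConfigurationError(
                f"side_px must be even and >= 32, got {self.side_px}"
            )
        if self.contrast <= 0:
            raise ConfigurationError(f"contrast must be > 0, got {self.contrast}")
        if not 0 < self.mean_level < 1:
            raise ConfigurationError(
                f"mean_level must be in (0, 1), got {self.mean_level}"
            )
        spread = 3 * self.contrast * self.mean_level
        if self.mean_level - spread < 0 or self.mean_level + spread > 1:
            raise ConfigurationError(
                "mean_level +/- 3*contrast*mean_level must stay within [0, 1]; "
                f"got mean_level={self.mean_level}, contrast={self.contrast}"
            )


def generate_spectral_noise_image(cfg: SpectralNoiseConfig) -> LuminanceImage:
    """Seeded power-law noise image via random-phase Fourier filtering.

    A white Gaussian field is transformed, its Fourier amplitudes scaled
    by ``f^(beta/2)`` (DC set to zero), and transformed back; the result
    is standardized, scaled to the requested mean and contrast, and
    clipped to [0, 1].  The expected periodogram is then proportional to
    ``f^beta`` at every non-DC grid frequency.
    """
    n = cfg.side_px
    rng = np.random.default_rng(cfg.seed)
    white = rng.standard_normal((n, n))
    u = np.fft.fftfreq(n) * n
    f = np.hypot(u[:, None], u[None, :])
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (cfg.beta / 2.0)
    spectrum = np.fft.fft2(white) * amp
    fieldvals = np.fft.ifft2(spectrum).real
    sd = fieldvals.std()
    if sd == 0:
        raise DataError("degenerate noise field (zero variance)")
    z = (fieldvals - fieldvals.mean()) / sd
    img = cfg.mean_level * (1.0 + cfg.contrast * z)
    np.clip(img, 0.0, 1.0, out=img)
    return LuminanceImage(
        img, source_id=f"synth_beta{cfg.beta:+.3f}_seed{cfg.seed}"
    )


def generate_sensitivity_curves(
    peaks_nm,
    range_nm: tuple[float, float] = (400.0, 700.0),
    width_nm: float = 40.0,
    step_nm: float = 1.0,
) -> list[SensitivityCurve]:
    """Gaussian-in-wavelength sensitivity templates on a shared grid.

    One curve per peak, each peak-normalized to 1.  A Gaussian template is
    a generic smooth unimodal stand-in for receptor nomograms; only the
    shape of the mapping machinery downstream depends on it.
    """
    lo, hi = range_nm
    if width_nm <= 0:
        raise ConfigurationError(f"width_nm must be > 0, got {width_nm}")
    if lo >= hi:
        raise ConfigurationError(f"invalid wavelength range {range_nm}")
    grid = np.arange(lo, hi + 0.5 * step_nm, step_nm)
    curves = []
    for peak in peaks_nm:
        if not lo <= peak <= hi:
            raise ConfigurationError(
                f"peak {peak} nm lies outside the range {range_nm}"
            )
        resp = np.exp(-0.5 * ((grid - peak) / width_nm) ** 2)
        resp = resp / resp.max()
        curves.append(SensitivityCurve(grid.copy(), resp, label=f"peak{peak:g}nm"))
    return curves


def generate_training_spectra(
    n_spectra: int,
    wavelengths_nm,
    seed: int = 0,
    n_components: int = 4,
) -> np.ndarray:
    """Smooth random positive spectra for fitting the camera-to-cone map.

    Each spectrum is a random positive mixture of broad Gaussians plus a
    flat floor, emulating the smooth reflectance/radiance spectra used to
    train receptor mappings.  Returns an (n_spectra, n_wavelengths) array.
    """
    grid = np.asarray(wavelengths_nm, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = grid.min(), grid.max()
    spectra = np.empty((n_spectra, grid.size))
    for i in range(n_spectra):
        s = np.full(grid.size, 0.05 + 0.1 * rng.random())
        for _ in range(n_components):
            center = rng.uniform(lo, hi)
            width = rng.uniform(0.05, 0.3) * (hi - lo)
            s = s + rng.uniform(0.1, 1.0) * np.exp(-0.5 * ((grid - center) / width) ** 2)
        spectra[i] = s
    return spectra


@dataclass(frozen=True)
class StudySimConfig:
    """Ground-truth parameters for a simulated slope study.

    Per fish: ``slope = intercept_b0 + effect_b * habitat_slope(species)
    + u_species + u_site + sex_effect * I(female) + e`` with
    ``u_species ~ MVN(0, sigma_phylo^2 * C(tree))`` (C in correlation
    form), ``u_site ~ N(0, sigma_site^2)`` iid, ``e ~ N(0, sigma_resid^2)``
    iid.  Sexes alternate within site, so sites are balanced.
    """

    habitat_slopes: Mapping[str, float]
    species_habitat: Mapping[str, str]
    sites_per_species: int = 2
    fish_per_site: int = 10
    intercept_b0: float = 0.0
    effect_b: float = 1.0
    sigma_phylo: float = 0.0
    sigma_site: float = 0.0
    sigma_resid: float = 0.0
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_phylo", "sigma_site", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sites_per_species < 1 or self.fish_per_site < 1:
            raise ConfigurationError("sites_per_species and fish_per_site must be >= 1")
        missing = [
            sp for sp, hab in self.species_habitat.items()
            if hab not in self.habitat_slopes
        ]
        if missing:
            raise ConfigurationError(
                f"species mapped to undeclared habitat classes: {missing}"
            )


def generate_study_dataset(cfg: StudySimConfig, tree: Phylogeny) -> pd.DataFrame:
    """Simulate a study table with known hierarchical ground truth.

    Returns one row per fish with columns fish_id, species, sex, site,
    habitat_class, habitat_slope (the true class slope), and slope.
    Deterministic for a given seed.
    """
    species = sorted(cfg.species_habitat)
    absent = [s for s in species if s not in tree.taxa]
    if absent:
        raise DataError(f"species absent from tree: {absent}")
    rng = np.random.default_rng(cfg.seed)

    cov = phylo_covariance(tree, species, normalize=True)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(species)))
    u_species = cfg.sigma_phylo * (chol @ rng.standard_normal(len(species)))

    rows = []
    for i, sp in enumerate(species):
        hab = cfg.species_habitat[sp]
        hab_slope = cfg.habitat_slopes[hab]
        for j in range(cfg.sites_per_species):
            site = f"{sp}|s{j + 1}"
            u_site = cfg.sigma_site * rng.standard_normal()
            for k in range(cfg.fish_per_site):
                sex = "male" if k % 2 == 0 else "female"
                e = cfg.sigma_resid * rng.standard_normal()
                slope = (
                    cfg.intercept_b0
                    + cfg.effect_b * hab_slope
                    + u_species[i]
                    + u_site
                    + (cfg.sex_effect if sex == "female" else 0.0)
                    + e
                )
                rows.append(
                    {
                        "fish_id": f"{sp}|s{j + 1}|f{k + 1:02d}",
                        "species": sp,
                        "sex": sex,
                        "site": site,
                        "habitat_class": hab,
                        "habitat_slope": hab_slope,
                        "slope": slope,
                    }
                )
    return pd.DataFrame(rows)
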