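"""Linear-image handling: receiver color space, luminance, and patches.

Camera images are assumed linear (no gamma, no white balance).  A
dichromat receiver (two cone classes) sees each pixel through a fitted
quadratic map from the three camera catches to the two cone catches; the
achromatic (luminance) image is the pixel-wise sum of the two cone
channels, mimicking how vertebrate brains are thought to pool cone
signals.  Analysis operates on square patches sampled at random from each
luminance image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = [
    "LuminanceImage",
    "SensitivityCurve",
    "ColorMapModel",
    "LuminancePatch",
    "downsample_half",
    "resize_block_mean",
    "quantum_catches",
    "fit_quadratic_map",
    "fit_color_map",
    "apply_color_map",
    "to_luminance",
    "sample_patches",
    "read_image",
    "write_image_16bit",
    "read_curve",
    "write_curve",
]


@dataclass
class LuminanceImage:
    """2-D grid of non-negative linear luminance values."""

    pixels: np.ndarray
    scale: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DataError(f"luminance image must be 2-D, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise DataError("luminance values must be non-negative")


@dataclass
class SensitivityCurve:
    """Spectral sensitivity on an ascending wavelength grid, peak = 1."""

    wavelengths_nm: np.ndarray
    response: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.wavelengths_nm.shape != self.response.shape:
            raise DataError("wavelength and response grids differ in length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise DataError("wavelength grid must be strictly ascending")
        peak = self.response.max()
        if not np.isclose(peak, 1.0, atol=1e-9):
            raise DataError(f"curve {self.label!r} is not peak-normalized (max={peak})")

    def resample(self, grid_nm: np.ndarray) -> np.ndarray:
        return np.interp(grid_nm, self.wavelengths_nm, self.response, left=0.0, right=0.0)


# 10 monomials of total degree <= 2 in (R, G, B): the quadratic basis of
# the camera-to-cone map.
_BASIS_POWERS = [
    (0, 0, 0),
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (2, 0, 0),
    (0, 2, 0),
    (0, 0, 2),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
]


@dataclass
class ColorMapModel:
    """Quadratic map from 3 camera catches to cone catches (10 terms each)."""

    coefficients: np.ndarray  # (n_cones, 10)
    training_residual: float
    degree: int = 2

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.degree != 2:
            raise ConfigurationError("only degree-2 color maps are supported")
        if self.coefficients.ndim != 2 or self.coefficients.shape[1] != len(_BASIS_POWERS):
            raise ConfigurationError(
                f"coefficients must have {len(_BASIS_POWERS)} terms per cone channel"
            )


@dataclass
class LuminancePatch:
    """Square luminance patch plus provenance (source, offset, replicate)."""

    pixels: np.ndarray
    source_id: str = ""
    offset_rc: tuple[int, int] = (0, 0)
    replicate: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise DataError(f"patch must be square, got shape {self.pixels.shape}")


def _as_array(image) -> np.ndarray:
    return np.asarray(getattr(image, "pixels", image), dtype=float)


def downsample_half(image):
    """Halve an image by non-overlapping 2x2 block means.

    Works on 2-D luminance grids and (H, W, C) multichannel images; an odd
    trailing row/column is dropped.  Returns the same kind as the input
    (a :class:`LuminanceImage` in gives a :class:`LuminanceImage` out).
    """
    arr = _as_array(image)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError(f"image smaller than 2x2 cannot be halved, got {arr.shape[:2]}")
    h, w = (arr.shape[0] // 2) * 2, (arr.shape[1] // 2) * 2
    arr = arr[:h, :w]
    if arr.ndim == 2:
        out = arr.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    elif arr.ndim == 3:
        out = arr.reshape(h // 2, 2, w // 2, 2, arr.shape[2]).mean(axis=(1, 3))
    else:
        raise DataError(f"expected 2-D or 3-D image, got shape {arr.shape}")
    if isinstance(image, LuminanceImage):
        return LuminanceImage(out, scale=image.scale, source_id=image.source_id)
    return out


def resize_block_mean(image, out_hw: tuple[int, int]):
    """Resize by local averaging to a target (rows, cols) shape.

    Used for the habitat-image reduction step before patch sampling;
    delegates to scikit-image's local-mean resampler, which generalizes
    exact block averaging to non-integer factors.
    """
    from skimage.transform import resize_local_mean

    arr = _as_array(image)
    out_shape = tuple(out_hw) + arr.shape[2:]
    out = resize_local_mean(arr, out_shape, preserve_range=True)
    if isinstance(image, LuminanceImage):
        return LuminanceImage(out, scale=image.scale, source_id=image.source_id)
    return out


def quantum_catches(curves: list[SensitivityCurve], wavelengths_nm, spectra) -> np.ndarray:
    """Receptor catches: inner product of each spectrum with each curve.

    ``spectra`` is (n_spectra, n_wavelengths); returns (n_spectra, n_curves).
    """
    grid = np.asarray(wavelengths_nm, dtype=float)
    s = np.atleast_2d(np.asarray(spectra, dtype=float))
    if s.shape[1] != grid.size:
        raise DataError("spectra and wavelength grid differ in length")
    responses = np.column_stack([c.resample(grid) for c in curves])
    return np.trapezoid(s[:, :, None] * responses[None, :, :], grid, axis=1)


def _monomials(catches: np.ndarray) -> np.ndarray:
    r, g, b = catches[:, 0], catches[:, 1], catches[:, 2]
    return np.column_stack(
        [r**i * g**j * b**k for i, j, k in _BASIS_POWERS]
    )


def fit_quadratic_map(camera_catches, cone_catches) -> ColorMapModel:
    """Least squares of cone catches on the quadratic camera-catch basis.

    ``camera_catches`` is (n, 3), ``cone_catches`` is (n, n_cones); each
    cone channel is regressed on the 10-term degree-2 monomial expansion
    of the camera catches.  Requires at least 10 rows and a full-rank
    design.
    """
    cam = np.atleast_2d(np.asarray(camera_catches, dtype=float))
    cone = np.atleast_2d(np.asarray(cone_catches, dtype=float))
    if cam.ndim != 2 or cam.shape[1] != 3:
        raise DataError(f"camera catches must be (n, 3), got {cam.shape}")
    if cam.shape[0] < len(_BASIS_POWERS):
        raise ConfigurationError(
            f"rank-deficient design: need >= {len(_BASIS_POWERS)} training rows, "
            f"got {cam.shape[0]}"
        )
    design = _monomials(cam)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfigurationError(
            "rank-deficient design: training inputs do not span the quadratic "
            "basis of the camera catches"
        )
    coeffs, _, _, _ = np.linalg.lstsq(design, cone, rcond=None)
    resid = design @ coeffs - cone
    rms = float(np.sqrt(np.mean(resid**2)))
    return ColorMapModel(coefficients=coeffs.T, training_residual=rms)


def fit_color_map(
    camera_curves: list[SensitivityCurve],
    cone_curves: list[SensitivityCurve],
    wavelengths_nm,
    training_spectra,
) -> ColorMapModel:
    """Fit the camera-to-cone quadratic map from training spectra.

    Each training spectrum yields 3 camera catches and one catch per cone
    class; the map is then fitted by :func:`fit_quadratic_map`.
    """
    if len(camera_curves) != 3:
        raise ConfigurationError(f"need 3 camera curves, got {len(camera_curves)}")
    if len(cone_curves) < 1:
        raise ConfigurationError("need at least one cone curve")
    spectra = np.atleast_2d(np.asarray(training_spectra, dtype=float))
    cam = quantum_catches(camera_curves, wavelengths_nm, spectra)
    cone = quantum_catches(cone_curves, wavelengths_nm, spectra)
    return fit_quadratic_map(cam, cone)


def apply_color_map(model: ColorMapModel, image) -> np.ndarray:
    """Per-pixel polynomial evaluation; negative predictions clamp to 0."""
    arr = _as_array(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataError(f"expected a 3-channel image, got shape {arr.shape}")
    flat = arr.reshape(-1, 3)
    out = _monomials(flat) @ model.coefficients.T
    np.clip(out, 0.0, None, out=out)
    return out.reshape(arr.shape[0], arr.shape[1], model.coefficients.shape[0])


def to_luminance(cone_image, source_id: str = "") -> LuminanceImage:
    """Luminance = pixel-wise sum of the two cone channels."""
    arr = _as_array(cone_image)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise DataError(f"expected a 2-channel cone image, got shape {arr.shape}")
    return LuminanceImage(arr.sum(axis=2), source_id=source_id)


def sample_patches(
    image: LuminanceImage,
    box_px: int = 200,
    n: int = 2,
    seed: int = 0,
) -> list[LuminancePatch]:
    """Sample ``n`` square patches at uniform random valid offsets."""
    arr = _as_array(image)
    h, w = arr.shape
    if h < box_px or w < box_px:
        raise DataError(
            f"image {getattr(image, 'source_id', '')!r} is {h}x{w}; "
            f"need at least {box_px}x{box_px} for patch sampling"
        )
    rng = np.random.default_rng(seed)
    patches = []
    for rep in range(1, n + 1):
        r = int(rng.integers(0, h - box_px + 1))
        c = int(rng.integers(0, w - box_px + 1))
        patches.append(
            LuminancePatch(
                pixels=arr[r : r + box_px, c : c + box_px].copy(),
                source_id=getattr(image, "source_id", ""),
                offset_rc=(r, c),
                replicate=rep,
            )
        )
    return patches


# ---------------------------------------------------------------------------
# I/O


def read_image(path: str) -> np.ndarray:
    """Read an 8/16-bit TIFF or PNG as linear floats in [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_image_16bit(path: str, pixels) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF or PNG."""
    arr = np.asarray(getattr(pixels, "pixels", pixels), dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DataError("pixels must lie in [0, 1] for 16-bit output")
    coded = np.round(arr * 65535.0).astype(np.uint16)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, coded)
    elif ext == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, coded)
    else:
        raise ConfigurationError(f"unsupported image extension {ext!r}")


def read_curve(path: str, label: str = "") -> SensitivityCurve:
    """Read a two-column (wavelength, response) whitespace-delimited table."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise DataError(f"{path}: expected two columns (wavelength, response)")
    return SensitivityCurve(data[:, 0], data[:, 1], label=label or os.path.basename(path))


def write_curve(path: str, curve: SensitivityCurve) -> None:
    np.savetxt(path, np.column_stack([curve.wavelengths_nm, curve.response]))
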