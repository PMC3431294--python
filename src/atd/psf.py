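"""Point-spread-function construction and measurement.

A PSF can be built two ways:

* **empirically**, from an image of a field of sub-diffraction fluorescent
  beads deposited on an ultrathin section: candidate beads are detected,
  screened for detector saturation, registered by their brightest pixel and
  averaged (:func:`detect_bead_candidates`, :func:`average_psf`);
* **synthetically**, from the optical configuration: a Gaussian of given
  FWHM, an Airy (jinc-squared) diffraction pattern, the Airy pattern
  convolved with the finite bead diameter, or the confocal product of
  excitation and emission Airy patterns (:func:`synthetic_psf`).

Widths are quantified by the linearly interpolated full width at half
maximum of the central cross-section (:func:`psf_fwhm`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import j1

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "OpticalConfig",
    "PointSpreadFunction",
    "BeadFieldImage",
    "detect_bead_candidates",
    "average_psf",
    "synthetic_psf",
    "psf_fwhm",
]

#: sub-pixel sampling factor used to integrate analytic models over the
#: area of each camera pixel
SUPERSAMPLE = 5


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the imaging system.

    Parameters
    ----------
    wavelength_nm : float
        Emission wavelength of the imaged fluorophore, nm.
    numerical_aperture : float
        NA of the objective (1.4 for the oil-immersion plan-apochromat
        objectives typically used for array tomography).
    refractive_index : float
        Refractive index of the immersion medium (1.51 for oil).
    pixel_nm : float
        Lateral size of a camera pixel in sample space, nm.
    """

    wavelength_nm: float
    numerical_aperture: float
    refractive_index: float = 1.51
    pixel_nm: float = 100.0

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "numerical_aperture", "refractive_index", "pixel_nm"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.numerical_aperture > self.refractive_index:
            raise InvalidParameterError(
                "numerical_aperture cannot exceed the refractive index of the medium"
            )


@dataclass(frozen=True)
class PointSpreadFunction:
    """A small 2D blur kernel: non-negative, unit sum, peak at the center.

    ``kernel`` has odd side lengths so the center is a well-defined pixel.
    """

    kernel: np.ndarray
    pixel_nm: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if k.ndim != 2 or k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
            raise InvalidInputError("PSF kernel must be 2D with odd side lengths")
        if not self.pixel_nm > 0:
            raise InvalidParameterError("pixel_nm must be positive")
        if np.any(k < 0):
            raise InvalidInputError("PSF kernel must be non-negative")
        if abs(k.sum() - 1.0) > 1e-9:
            raise InvalidInputError("PSF kernel must sum to 1 (within 1e-9)")
        if k[self.center] != k.max():
            raise InvalidInputError("PSF global maximum must lie at the center pixel")

    @property
    def center(self) -> tuple[int, int]:
        return (self.kernel.shape[0] // 2, self.kernel.shape[1] // 2)

    @classmethod
    def from_array(cls, arr: np.ndarray, pixel_nm: float) -> "PointSpreadFunction":
        """Clip negatives and normalize ``arr`` into a valid PSF."""
        a = np.clip(np.asarray(arr, dtype=float), 0.0, None)
        total = a.sum()
        if total <= 0:
            raise InvalidInputError("cannot normalize an all-zero kernel into a PSF")
        return cls(a / total, pixel_nm)


@dataclass(frozen=True)
class BeadFieldImage:
    """A wide-field image of sub-diffraction beads used for PSF extraction."""

    pixels: np.ndarray
    pixel_nm: float
    saturation_level: float = 65535.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", p)
        if p.ndim != 2:
            raise InvalidInputError("bead field must be a 2D image")
        if np.any(p < 0) or np.any(p > self.saturation_level):
            raise InvalidInputError("bead field pixels must lie in [0, saturation_level]")
        if not self.pixel_nm > 0:
            raise InvalidParameterError("pixel_nm must be positive")


def detect_bead_candidates(
    img: BeadFieldImage, window_px: int, min_separation_px: int
) -> list[tuple[int, int]]:
    """Find isolated, unsaturated bead centers in a bead-field image.

    A candidate is a local intensity maximum above an automatic background
    level (median + 5·MAD of the whole image).  Candidates are rejected when
    their extraction window leaves the image, contains two or more saturated
    pixels (only a single saturated pixel per bead is tolerated), or when two
    candidates fall closer than ``min_separation_px`` (both are dropped, since
    overlapping beads would bias the average).

    Returns centers as ``(row, col)`` tuples in row-major order.
    """
    if window_px % 2 == 0 or window_px < 5:
        raise InvalidParameterError("window_px must be odd and >= 5")
    if min_separation_px < window_px:
        raise InvalidParameterError("min_separation_px must be >= window_px")
    p = img.pixels
    if p.shape[0] < window_px or p.shape[1] < window_px:
        raise InvalidInputError("image smaller than the extraction window")

    med = float(np.median(p))
    mad = float(np.median(np.abs(p - med)))
    level = med + 5.0 * mad

    r = window_px // 2
    h, w = p.shape
    candidates: list[tuple[int, int]] = []
    # Strictly greater than the row-major-earlier neighbours and >= the later
    # ones: picks exactly one pixel per plateau, in row-major order.
    earlier = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    later = [(0, 1), (1, -1), (1, 0), (1, 1)]
    above = np.argwhere(p > level)
    for y, x in above:
        if y < r or x < r or y >= h - r or x >= w - r:
            continue
        v = p[y, x]
        if any(p[y + dy, x + dx] >= v for dy, dx in earlier):
            continue
        if any(p[y + dy, x + dx] > v for dy, dx in later):
            continue
        win = p[y - r : y + r + 1, x - r : x + r + 1]
        if np.count_nonzero(win == img.saturation_level) >= 2:
            continue
        candidates.append((int(y), int(x)))

    # mutual-exclusion pass: drop BOTH members of any too-close pair
    keep = [True] * len(candidates)
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            dy = candidates[i][0] - candidates[j][0]
            dx = candidates[i][1] - candidates[j][1]
            if (dy * dy + dx * dx) ** 0.5 < min_separation_px:
                keep[i] = keep[j] = False
    return [c for c, k in zip(candidates, keep) if k]


def average_psf(
    img: BeadFieldImage, centers: list[tuple[int, int]], window_px: int
) -> PointSpreadFunction:
    """Register bead windows by their brightest pixel and average them.

    Each window is background-subtracted (median of its one-pixel border
    ring), re-extracted so its brightest pixel sits exactly at the window
    center (integer-pixel registration), then all windows are averaged,
    clipped at zero and normalized to unit sum.
    """
    if window_px % 2 == 0 or window_px < 3:
        raise InvalidParameterError("window_px must be odd and >= 3")
    if len(centers) == 0:
        raise InvalidInputError("average_psf requires at least one bead center")
    p = img.pixels
    r = window_px // 2
    h, w = p.shape

    def extract(cy: int, cx: int) -> np.ndarray:
        if cy < r or cx < r or cy >= h - r or cx >= w - r:
            raise InvalidInputError(f"bead window at ({cy}, {cx}) leaves the image")
        return p[cy - r : cy + r + 1, cx - r : cx + r + 1]

    acc = np.zeros((window_px, window_px))
    for cy, cx in centers:
        win = extract(cy, cx)
        # integer registration: recentre on the brightest pixel
        dy, dx = np.unravel_index(int(np.argmax(win)), win.shape)
        win = extract(cy + dy - r, cx + dx - r)
        border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        acc += win - np.median(border)
    acc /= len(centers)
    return PointSpreadFunction.from_array(acc, img.pixel_nm)


def _airy_intensity(r_nm: np.ndarray, wavelength_nm: float, na: float) -> np.ndarray:
    """Paraxial Airy intensity (2 J1(v)/v)^2 with v = 2*pi*NA*r/lambda.

    The first zero sits at v = 3.8317, i.e. r = 0.61*lambda/NA.
    """
    v = 2.0 * np.pi * na * r_nm / wavelength_nm
    out = np.ones_like(v)
    nz = v != 0
    out[nz] = (2.0 * j1(v[nz]) / v[nz]) ** 2
    return out


def _fine_grid(window_px: int, pixel_nm: float) -> np.ndarray:
    """Radii (nm) of a SUPERSAMPLE-times oversampled window grid."""
    n = window_px * SUPERSAMPLE
    step = pixel_nm / SUPERSAMPLE
    coords = (np.arange(n) - (n - 1) / 2.0) * step
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return np.hypot(yy, xx)


def _bin_down(fine: np.ndarray, window_px: int) -> np.ndarray:
    """Average SUPERSAMPLE x SUPERSAMPLE blocks back to camera pixels."""
    s = SUPERSAMPLE
    return fine.reshape(window_px, s, window_px, s).mean(axis=(1, 3))


def synthetic_psf(
    cfg: OpticalConfig,
    model: str,
    fwhm_nm: float | None = None,
    bead_diameter_nm: float | None = None,
    window_px: int = 15,
    emission_wavelength_nm: float | None = None,
) -> PointSpreadFunction:
    """Build a model PSF on the camera pixel grid.

    Models
    ------
    ``gaussian``
        Isotropic Gaussian of the given ``fwhm_nm``.
    ``airy``
        Diffraction-limited incoherent pattern for (wavelength, NA): the
        squared first-order jinc, whose first radial zero lies at
        0.61*lambda/NA.
    ``bead_convolved_airy``
        Airy pattern convolved with a uniform disc of ``bead_diameter_nm``,
        i.e. what a finite fluorescent bead actually images as.
    ``confocal_product``
        Pixel-wise product of the excitation and emission Airy patterns
        (``emission_wavelength_nm`` defaults to the excitation wavelength);
        the product is narrower than either factor.

    All models are integrated over the pixel area by 5x5 supersampling and
    normalized to unit sum.
    """
    if window_px % 2 == 0 or window_px < 3:
        raise InvalidParameterError("window_px must be odd and >= 3")
    r_nm = _fine_grid(window_px, cfg.pixel_nm)

    if model == "gaussian":
        if fwhm_nm is None:
            raise InvalidParameterError("gaussian model requires fwhm_nm")
        sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        # sampled at pixel centers, not area-integrated: the Gaussian model is
        # defined by its FWHM on the grid, and box integration would widen it
        coords = (np.arange(window_px) - window_px // 2) * cfg.pixel_nm
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        grid = np.exp(-0.5 * (np.hypot(yy, xx) / sigma) ** 2)
        return PointSpreadFunction.from_array(grid, cfg.pixel_nm)
    if model == "airy":
        fine = _airy_intensity(r_nm, cfg.wavelength_nm, cfg.numerical_aperture)
    elif model == "bead_convolved_airy":
        if bead_diameter_nm is None:
            raise InvalidParameterError("bead_convolved_airy model requires bead_diameter_nm")
        fine = _airy_intensity(r_nm, cfg.wavelength_nm, cfg.numerical_aperture)
        disc = (r_nm <= bead_diameter_nm / 2.0).astype(float)
        if disc.sum() == 0:  # bead smaller than a sub-sample: effectively a point
            disc[tuple(d // 2 for d in disc.shape)] = 1.0
        disc /= disc.sum()
        fine = fftconvolve(fine, disc, mode="same")
    elif model == "confocal_product":
        em = emission_wavelength_nm if emission_wavelength_nm is not None else cfg.wavelength_nm
        exc = _airy_intensity(r_nm, cfg.wavelength_nm, cfg.numerical_aperture)
        emi = _airy_intensity(r_nm, em, cfg.numerical_aperture)
        fine = exc * emi
    else:
        raise InvalidParameterError(f"unknown PSF model: {model!r}")

    return PointSpreadFunction.from_array(_bin_down(fine, window_px), cfg.pixel_nm)


def psf_fwhm(psf: PointSpreadFunction) -> float:
    """FWHM (nm) of the central horizontal cross-section.

    The half-maximum crossings on each side of the peak are located by
    linear interpolation between pixels.  If the profile never falls to half
    maximum inside the window the window edge is used, so a single-pixel
    delta kernel reports a width of one pixel.
    """
    row = psf.kernel[psf.center[0]].astype(float)
    cx = psf.center[1]
    peak = row[cx]
    if peak <= 0:
        raise InvalidInputError("PSF cross-section has no positive peak")
    half = peak / 2.0

    def crossing(direction: int) -> float:
        x = cx
        while 0 <= x + direction < row.size and row[x + direction] >= half:
            x += direction
        if not 0 <= x + direction < row.size:
            return abs(x - cx) + 0.5
        a, b = row[x], row[x + direction]
        return abs(x - cx) + (a - half) / (a - b)

    return (crossing(-1) + crossing(+1)) * psf.pixel_nm
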