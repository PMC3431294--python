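"""Modulation transfer functions and diffraction-limit arithmetic.

The MTF is the modulus of the optical transfer function (the Fourier
transform of the PSF), DC-normalized so modulation(0) = 1: it states how
much contrast the system delivers at each spatial frequency.  Two landmark
frequencies bound the analysis:

* the **diffraction cut-off** ``2 NA / lambda`` - the highest frequency an
  incoherent imaging system physically passes;
* the **pixel (Nyquist) limit** ``1 / (2 * pixel)`` - the highest frequency
  the sampling grid represents.

Deconvolution raises in-band modulation (quantified by :func:`mtf_gain`),
and with a non-negativity-constrained restorer such as Richardson-Lucy the
restored spectrum can extend past the cut-off into the band between the two
limits, which :func:`band_extension` measures.

All frequencies are expressed in cycles/um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .psf import OpticalConfig

__all__ = [
    "MTFCurve",
    "compute_mtf",
    "cutoff_frequency",
    "rayleigh_lateral_limit",
    "axial_limit",
    "mtf_gain",
    "band_extension",
]


def cutoff_frequency(cfg: OpticalConfig) -> float:
    """Incoherent diffraction cut-off 2*NA/lambda, in cycles/um."""
    return 2.0 * cfg.numerical_aperture / cfg.wavelength_nm * 1000.0


def rayleigh_lateral_limit(cfg: OpticalConfig) -> float:
    """Rayleigh two-point resolution 0.61*lambda/NA, in nm."""
    return 0.61 * cfg.wavelength_nm / cfg.numerical_aperture


def axial_limit(cfg: OpticalConfig) -> float:
    """Diffraction-limited axial resolution 1.4*n*lambda/NA^2, in nm."""
    return 1.4 * cfg.refractive_index * cfg.wavelength_nm / cfg.numerical_aperture**2


@dataclass(frozen=True)
class MTFCurve:
    """Rotationally averaged, DC-normalized modulation vs spatial frequency."""

    frequencies: np.ndarray  # cycles/um, ascending, starts at 0
    modulation: np.ndarray  # modulation(0) = 1
    pixel_limit: float  # Nyquist frequency of the pixel grid, cycles/um
    cutoff: float | None = None  # diffraction cut-off, cycles/um

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.modulation, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "modulation", m)
        if f.shape != m.shape or f.ndim != 1 or f.size == 0:
            raise InvalidInputError("frequencies and modulation must be matching 1D arrays")
        if f[0] != 0 or np.any(np.diff(f) <= 0):
            raise InvalidInputError("frequencies must start at 0 and increase strictly")
        if m[0] != 1.0:
            raise InvalidInputError("modulation must be DC-normalized (modulation(0) = 1)")
        if np.any(m < 0):
            raise InvalidInputError("modulation values must be non-negative")


def compute_mtf(
    grid: np.ndarray,
    pixel_nm: float,
    pad_to: int = 256,
    n_bins: int | None = None,
    cutoff: float | None = None,
) -> MTFCurve:
    """Rotationally averaged MTF of a PSF or restored point-source image.

    The grid is centered in a ``pad_to``-square zero-padded canvas, Fourier
    transformed, the magnitude normalized by its zero-frequency value, and
    averaged into radial bins one DFT sample wide (empty bins are dropped).
    ``pad_to`` must be a power of two >= 128 so the radial sampling is fine
    enough for stable binning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise InvalidInputError("expected a 2D grid")
    if np.any(grid < 0):
        raise InvalidInputError("grid must be non-negative")
    if grid.sum() <= 0:
        raise InvalidInputError("grid is all zero")
    if pad_to < 128 or (pad_to & (pad_to - 1)) != 0:
        raise InvalidParameterError("pad_to must be a power of two >= 128")
    if grid.shape[0] > pad_to or grid.shape[1] > pad_to:
        raise InvalidInputError("grid does not fit within pad_to")

    canvas = np.zeros((pad_to, pad_to))
    y0 = (pad_to - grid.shape[0]) // 2
    x0 = (pad_to - grid.shape[1]) // 2
    canvas[y0 : y0 + grid.shape[0], x0 : x0 + grid.shape[1]] = grid

    mag = np.abs(np.fft.fft2(canvas))
    mag /= mag[0, 0]  # DC normalization

    f1d = np.fft.fftfreq(pad_to, d=pixel_nm) * 1000.0  # cycles/um
    fy, fx = np.meshgrid(f1d, f1d, indexing="ij")
    radius = np.hypot(fy, fx)

    pixel_limit = 1000.0 / (2.0 * pixel_nm)
    dfreq = pixel_limit / (pad_to / 2)  # one DFT sample per bin
    idx = np.rint(radius / dfreq).astype(int)

    counts = np.bincount(idx.ravel())
    sums = np.bincount(idx.ravel(), weights=mag.ravel())
    present = counts > 0
    freqs = np.arange(counts.size)[present] * dfreq
    mods = sums[present] / counts[present]
    mods[0] = 1.0  # exact after normalization; enforce against roundoff

    if n_bins is not None:
        freqs, mods = freqs[:n_bins], mods[:n_bins]
    return MTFCurve(freqs, mods, pixel_limit=pixel_limit, cutoff=cutoff)


def mtf_gain(before: MTFCurve, after: MTFCurve) -> tuple[np.ndarray, float]:
    """Per-bin modulation ratio after/before, and its in-band maximum.

    The in-band maximum is taken over bins with 0 < f <= cutoff; the
    ``before`` curve is floored at 1e-12 so empty bands report finite gains.
    """
    if before.frequencies.shape != after.frequencies.shape or not np.allclose(
        before.frequencies, after.frequencies
    ):
        raise InvalidParameterError("MTF curves must share identical frequency bins")
    if before.cutoff is None or after.cutoff is None or before.cutoff != after.cutoff:
        raise InvalidParameterError("MTF curves must share one cut-off frequency")
    ratio = after.modulation / np.maximum(before.modulation, 1e-12)
    in_band = (before.frequencies > 0) & (before.frequencies <= before.cutoff)
    if not np.any(in_band):
        raise InvalidParameterError("no frequency bins below the cut-off")
    return ratio, float(ratio[in_band].max())


def band_extension(curve: MTFCurve, floor: float) -> tuple[float, float]:
    """How far past the cut-off a curve keeps contrast above ``floor``.

    Returns the highest frequency whose modulation is >= ``floor`` and the
    fraction of bins in the (cutoff, pixel_limit] band whose modulation
    exceeds ``floor`` (0.0 when the band is empty, e.g. when the pixel grid
    under-samples the diffraction limit).
    """
    if not 0.0 < floor < 1.0:
        raise InvalidParameterError("floor must lie strictly between 0 and 1")
    above = curve.modulation >= floor
    extension = float(curve.frequencies[above].max()) if np.any(above) else 0.0
    if curve.cutoff is None:
        raise InvalidParameterError("curve has no cut-off frequency set")
    grey = (curve.frequencies > curve.cutoff) & (curve.frequencies <= curve.pixel_limit)
    fraction = float(np.mean(curve.modulation[grey] > floor)) if np.any(grey) else 0.0
    return extension, fraction
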