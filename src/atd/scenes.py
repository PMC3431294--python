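"""Synthetic scenes with known ground truth.

Every other module is exercised on simulated imagery whose ground truth is
recorded in a manifest: fields of sub-diffraction beads (point sources at
integer pixels), pairs of parallel 1-px-wide filaments emulating adjacent
microtubules, and 3D volumes of Gaussian puncta emulating presynaptic
protein clusters.  The observed image is the ground truth blurred
section-wise by a chosen PSF, with optional calibrated Poisson noise; all
randomness flows from the single integer seed in the scene spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import fftconvolve

from .errors import InvalidParameterError
from .noise import add_poisson_noise
from .psf import PointSpreadFunction

__all__ = ["SceneSpec", "render_scene"]

_KINDS = ("bead_field", "filament_pair", "puncta_volume")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``shape`` is (y, x) for 2D kinds and (z, y, x) for ``puncta_volume``.
    Amplitudes are drawn uniformly from ``amplitude_range``; puncta are
    isotropic-in-plane Gaussian blobs with in-plane sigma drawn from
    ``sigma_range`` (pixels) and an axial sigma of one section.
    """

    kind: str
    shape: tuple[int, ...]
    pixel_nm: float = 100.0
    section_nm: float = 70.0
    n_objects: int = 10
    separation_px: int = 1  # filament_pair: blank columns between the two filaments
    min_separation_px: float = 6.0
    sigma_range: tuple[float, float] = (0.8, 1.5)
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    noise_percent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"kind must be one of {_KINDS}")
        if self.n_objects < 0:
            raise InvalidParameterError("n_objects must be non-negative")
        if self.noise_percent < 0:
            raise InvalidParameterError("noise_percent must be non-negative")
        want = 3 if self.kind == "puncta_volume" else 2
        if len(self.shape) != want:
            raise InvalidParameterError(f"{self.kind} expects a {want}D shape")


def _place_points(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n: int,
    margins: tuple[int, ...],
    min_sep: float,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample n integer positions >= min_sep apart, margins off edges."""
    lows = list(margins)
    highs = [s - m for s, m in zip(shape, margins)]
    if any(h <= lo for lo, h in zip(lows, highs)):
        raise InvalidParameterError("scene too small for the PSF margin")
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise InvalidParameterError(
                f"could not place {n} objects {min_sep} px apart after {max_tries} tries"
            )
        tries += 1
        cand = np.array([rng.integers(lo, hi) for lo, hi in zip(lows, highs)])
        if all(np.linalg.norm(cand - p) >= min_sep for p in placed):
            placed.append(cand)
    return np.array(placed).reshape(n, len(shape))


def render_scene(
    spec: SceneSpec, psf: PointSpreadFunction
) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Render ``(ground_truth, observed, manifest)`` for a scene spec.

    The observed image is the truth convolved 2D-section-wise with the PSF
    (sections are physically independent in array tomography) plus Poisson
    noise at ``spec.noise_percent``.  The manifest records every object's
    coordinates and parameters; identical specs render bitwise-identical
    outputs.
    """
    rng = np.random.default_rng(spec.seed)
    margin = max(psf.kernel.shape) // 2 + 2
    manifest: dict[str, Any] = {
        "kind": spec.kind,
        "shape": list(spec.shape),
        "pixel_nm": spec.pixel_nm,
        "section_nm": spec.section_nm,
        "noise_percent": spec.noise_percent,
        "seed": spec.seed,
        "objects": [],
    }

    truth = np.zeros(spec.shape)
    if spec.kind == "bead_field":
        positions = _place_points(
            rng, spec.shape, spec.n_objects, (margin, margin), spec.min_separation_px
        )
        amps = rng.uniform(*spec.amplitude_range, size=spec.n_objects)
        for (y, x), a in zip(positions, amps):
            truth[y, x] = a
            manifest["objects"].append({"y": int(y), "x": int(x), "amplitude": float(a)})
    elif spec.kind == "filament_pair":
        h, w = spec.shape
        mid = w // 2
        # separation_px counts the blank columns between the filaments
        x_left = mid - (spec.separation_px + 2) // 2
        x_right = x_left + spec.separation_px + 1
        if x_left < margin or x_right >= w - margin:
            raise InvalidParameterError("filament separation does not fit the scene")
        truth[margin : h - margin, x_left] = 1.0
        truth[margin : h - margin, x_right] = 1.0
        manifest["objects"] = [
            {"x": int(x_left), "orientation": "vertical"},
            {"x": int(x_right), "orientation": "vertical"},
        ]
    else:  # puncta_volume
        # the PSF blurs only laterally; z needs just a small blob margin
        positions = _place_points(
            rng, spec.shape, spec.n_objects, (2, margin, margin), spec.min_separation_px
        )
        amps = rng.uniform(*spec.amplitude_range, size=spec.n_objects)
        sigmas = rng.uniform(*spec.sigma_range, size=spec.n_objects)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in spec.shape), indexing="ij")
        for (z, y, x), a, s in zip(positions, amps, sigmas):
            blob = a * np.exp(
                -(((zz - z) ** 2) / 2.0 + ((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * s**2))
            )
            truth += blob
            manifest["objects"].append(
                {"z": int(z), "y": int(y), "x": int(x), "amplitude": float(a), "sigma_px": float(s)}
            )

    if truth.ndim == 2:
        observed = fftconvolve(truth, psf.kernel, mode="same")
    else:
        observed = np.stack([fftconvolve(s, psf.kernel, mode="same") for s in truth])
    observed = np.clip(observed, 0.0, None)
    observed = add_poisson_noise(observed, spec.noise_percent, spec.seed)
    return truth, observed, manifest
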