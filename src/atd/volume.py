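"""Aligned serial-section image volumes.

Array tomography stacks are ribbons of physically cut ultrathin sections
(70 nm by default), so the axial sampling is set by the microtome, not the
optics; sections are stored as an ordered (z, y, x) array with the lateral
pixel size and section thickness carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["ImageVolume"]


@dataclass(frozen=True)
class ImageVolume:
    """An aligned stack of equally shaped 2D sections."""

    data: np.ndarray  # (n_sections, height, width), non-negative
    pixel_nm: float = 100.0
    section_nm: float = 70.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 3 or d.shape[0] < 1:
            raise InvalidInputError("volume must be a (sections, y, x) array with >= 1 section")
        if np.any(d < 0):
            raise InvalidInputError("volume intensities must be non-negative")
        if not (self.pixel_nm > 0 and self.section_nm > 0):
            raise InvalidParameterError("pixel_nm and section_nm must be positive")

    @classmethod
    def from_sections(
        cls, sections: list[np.ndarray], pixel_nm: float = 100.0, section_nm: float = 70.0
    ) -> "ImageVolume":
        shapes = {np.asarray(s).shape for s in sections}
        if len(shapes) != 1:
            raise InvalidInputError("all sections must share one shape")
        return cls(np.stack([np.asarray(s, dtype=float) for s in sections]), pixel_nm, section_nm)

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def sections(self) -> list[np.ndarray]:
        return [self.data[i] for i in range(self.n_sections)]
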