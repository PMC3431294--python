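"""3D puncta segmentation and localization.

Protein puncta (e.g. Synapsin clusters) are segmented from aligned section
volumes by a fixed absolute threshold - a stated fraction (default 0.1) of
the detector dynamic range, i.e. 6553.5 counts for a 16-bit camera - and
grouped into 3D connected components under 26-neighborhood adjacency (face,
edge and corner neighbours, sections adjacent in z).  Each component is
summarized by its intensity-weighted center of mass, voxel count and
integrated intensity.

Puncta sets from two imaging modalities are compared by nearest-neighbour
center-of-mass distances (z rescaled by section/pixel anisotropy), and
whole image pairs by the Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InvalidInputError, InvalidParameterError
from .volume import ImageVolume

__all__ = [
    "SegmentationParams",
    "PunctaSet",
    "MatchResult",
    "absolute_threshold",
    "segment_puncta",
    "match_puncta",
    "pearson_correlation",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold settings; connectivity is fixed at 26-neighborhood."""

    threshold_fraction: float = 0.1
    dynamic_range_max: float = 65535.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise InvalidParameterError("threshold_fraction must lie strictly in (0, 1)")
        if not self.dynamic_range_max > 0:
            raise InvalidParameterError("dynamic_range_max must be positive")

    connectivity: int = field(default=26, init=False)


def absolute_threshold(params: SegmentationParams) -> float:
    """Background threshold in intensity counts: fraction x dynamic range."""
    return params.threshold_fraction * params.dynamic_range_max


@dataclass(frozen=True)
class PunctaSet:
    """Intensity-weighted 3D centroids of segmented components.

    Centroids are real-valued 0-based voxel coordinates ``(z, y, x)``;
    ``pixel_nm``/``section_nm`` carry the voxel geometry for matching.
    """

    centroids: np.ndarray  # (n, 3) in (z, y, x) voxel coordinates
    voxel_counts: np.ndarray  # (n,) integer
    integrated_intensities: np.ndarray  # (n,)
    pixel_nm: float = 100.0
    section_nm: float = 70.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "voxel_counts", np.asarray(self.voxel_counts, dtype=int))
        object.__setattr__(
            self, "integrated_intensities", np.asarray(self.integrated_intensities, dtype=float)
        )
        if len(self.voxel_counts) != len(c) or len(self.integrated_intensities) != len(c):
            raise InvalidInputError("per-punctum arrays must have matching lengths")
        if np.any(self.voxel_counts < 1):
            raise InvalidInputError("every punctum must contain at least one voxel")

    def __len__(self) -> int:
        return len(self.voxel_counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "z": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "x": self.centroids[:, 2],
                "voxel_count": self.voxel_counts,
                "integrated_intensity": self.integrated_intensities,
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, pixel_nm: float = 100.0, section_nm: float = 70.0
    ) -> "PunctaSet":
        return cls(
            df[["z", "y", "x"]].to_numpy(float),
            df["voxel_count"].to_numpy(int),
            df["integrated_intensity"].to_numpy(float),
            pixel_nm,
            section_nm,
        )


#: full 3x3x3 neighbourhood = 26-connectivity
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def segment_puncta(vol: ImageVolume, params: SegmentationParams | None = None) -> PunctaSet:
    """Threshold, label 26-connected 3D components, and localize them.

    Foreground voxels are those *strictly above* the absolute threshold
    (values at the threshold count as background).  Centroid weights are the
    original voxel intensities, so the reported positions are true centers
    of mass.  Components are ordered by the (z, y, x) of their first voxel
    in scan order; an empty foreground yields an empty set.
    """
    params = params or SegmentationParams()
    thr = absolute_threshold(params)
    mask = vol.data > thr
    labels, n = ndimage.label(mask, structure=_STRUCTURE_26)
    if n == 0:
        return PunctaSet(
            np.empty((0, 3)), np.empty(0, dtype=int), np.empty(0), vol.pixel_nm, vol.section_nm
        )
    weighted = np.where(mask, vol.data, 0.0)
    index = np.arange(1, n + 1)
    centroids = np.asarray(ndimage.center_of_mass(weighted, labels, index))
    counts = ndimage.sum_labels(mask, labels, index).astype(int)
    integrated = ndimage.sum_labels(weighted, labels, index)
    return PunctaSet(centroids, counts, integrated, vol.pixel_nm, vol.section_nm)


@dataclass(frozen=True)
class MatchResult:
    """Nearest-neighbour distances from set a into set b, in lateral pixels."""

    distances: np.ndarray
    hist_counts: np.ndarray
    bin_edges: np.ndarray


def match_puncta(a: PunctaSet, b: PunctaSet, bin_px: float = 0.5) -> MatchResult:
    """Distance from every punctum in ``a`` to its nearest neighbour in ``b``.

    Distances are 3D Euclidean in lateral-pixel units, with the z coordinate
    scaled by section_nm/pixel_nm to correct the axial anisotropy of
    section volumes.  A histogram with ``bin_px``-wide bins is returned
    alongside the raw distances.
    """
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("both puncta sets must be non-empty")
    if (a.pixel_nm, a.section_nm) != (b.pixel_nm, b.section_nm):
        raise InvalidParameterError("puncta sets must share one voxel geometry")
    if not bin_px > 0:
        raise InvalidParameterError("bin_px must be positive")
    zscale = a.section_nm / a.pixel_nm
    scale = np.array([zscale, 1.0, 1.0])
    tree = cKDTree(b.centroids * scale)
    distances, _ = tree.query(a.centroids * scale)
    top = max(float(distances.max()), bin_px)
    edges = np.arange(0.0, top + bin_px, bin_px)
    counts, edges = np.histogram(distances, bins=edges)
    return MatchResult(distances, counts, edges)


def pearson_correlation(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Product-moment correlation of two equally shaped images or volumes."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("images must share one shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvalidInputError("correlation is undefined for a constant image")
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
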