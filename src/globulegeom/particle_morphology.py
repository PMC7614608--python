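"""Iso-surface particle morphometry on 3-D density grids.

Mirrors the "measure blob" style of analysis applied to denoised tomograms:
connected voxel components above a density threshold are treated as
particles; each is summarised by its enclosed volume (voxel count × voxel
volume), the extents along its three principal axes, and sphericity
(shortest extent / longest extent).  A two-group Welch comparison is
provided for contrasting morphology between particle classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DensityGrid",
    "MorphologyRecord",
    "measure_blobs",
    "sphericity",
    "roundness2d",
    "diameter_summary",
    "compare_groups",
]


@dataclass
class DensityGrid:
    """3-D scalar voxel array with voxel size and origin in Å.

    ``values[i, j, k]`` is the density at position
    ``origin + voxel_size * (i, j, k)`` (voxel centers).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, float).reshape(3)
        )


@dataclass
class MorphologyRecord:
    """Per-blob measurements, lengths in Å, volume in Å³."""

    volume: float
    axes: tuple[float, float, float]    # principal-axis extents, descending
    sphericity: float
    centroid: np.ndarray
    n_voxels: int
    touches_boundary: bool = False
    blob_id: int = 0

    @property
    def diameter(self) -> float:
        """Longest principal-axis extent."""
        return self.axes[0]

    def as_dict(self) -> dict:
        return {
            "blob_id": self.blob_id,
            "volume_A3": self.volume,
            "axis1_A": self.axes[0],
            "axis2_A": self.axes[1],
            "axis3_A": self.axes[2],
            "sphericity": self.sphericity,
            "n_voxels": self.n_voxels,
            "flagged": self.touches_boundary,
        }


def records_to_frame(records: Sequence[MorphologyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def measure_blobs(
    grid: DensityGrid,
    threshold: float = 0.025,
    min_voxels: int = 50,
) -> list[MorphologyRecord]:
    """Measure every connected component of voxels above ``threshold``.

    Components use 26-connectivity and must contain at least ``min_voxels``
    voxels.  Axis extents are the span of voxel projections onto the
    component's principal axes (covariance eigenvectors): max−min of the
    voxel centers plus one voxel size, i.e. the extent of the enclosing
    voxel boxes, so a one-voxel-thick blob has extent ``voxel_size`` rather
    than zero.  A blob's "diameter" is its longest extent.  Components
    touching the grid
    boundary are flagged (their extents are truncated by the box) but still
    reported; an empty result is returned when nothing exceeds the
    threshold.
    """
    mask = grid.values > threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    records: list[MorphologyRecord] = []
    if n == 0:
        return records
    voxel_vol = grid.voxel_size ** 3
    shape = np.array(grid.values.shape)
    objects = ndimage.find_objects(labels)
    for blob_id, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == blob_id
        n_vox = int(sub.sum())
        if n_vox < min_voxels:
            continue
        idx = np.argwhere(sub) + np.array([s.start for s in sl])
        pts = idx * grid.voxel_size + grid.origin
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        # principal axes from the voxel-center covariance
        cov = centered.T @ centered / n_vox
        _, vecs = np.linalg.eigh(cov)
        proj = centered @ vecs
        extents = np.sort(proj.max(axis=0) - proj.min(axis=0))[::-1] + grid.voxel_size
        touches = bool((idx == 0).any() or (idx == shape - 1).any())
        sph = float(extents[2] / extents[0]) if extents[0] > 0 else 1.0
        records.append(
            MorphologyRecord(
                volume=n_vox * voxel_vol,
                axes=tuple(float(e) for e in extents),
                sphericity=sph,
                centroid=centroid,
                n_voxels=n_vox,
                touches_boundary=touches,
                blob_id=blob_id,
            )
        )
    return records


def sphericity(axes: Sequence[float]) -> float:
    """Shortest principal-axis extent divided by the longest (3-D)."""
    axes = np.asarray(axes, dtype=float)
    if axes.size != 3:
        raise ValueError("expected three axis extents")
    if (axes <= 0).any():
        raise ValueError("axis extents must be positive")
    return float(axes.min() / axes.max())


def roundness2d(axes2d: Sequence[float]) -> float:
    """Shortest in-plane extent divided by the longest (2-D roundness)."""
    axes2d = np.asarray(axes2d, dtype=float)
    if axes2d.size != 2:
        raise ValueError("expected two axis extents")
    if (axes2d <= 0).any():
        raise ValueError("axis extents must be positive")
    return float(axes2d.min() / axes2d.max())


def diameter_summary(
    measurements: Sequence[MorphologyRecord] | Sequence[float],
    include_flagged: bool = False,
) -> tuple[float, float, float, int]:
    """(median, min, max, n) of particle diameters in Å.

    Accepts MorphologyRecords (diameter = longest axis extent; boundary-
    flagged blobs excluded unless ``include_flagged``) or raw diameter
    values.  Median of an even-sized sample is the mean of the middle two.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements")
    if isinstance(measurements[0], MorphologyRecord):
        diam = [
            r.diameter for r in measurements
            if include_flagged or not r.touches_boundary
        ]
        if not diam:
            raise ValueError("all blobs flagged; pass include_flagged=True to use them")
    else:
        diam = [float(x) for x in measurements]
    arr = np.asarray(diam, float)
    return float(np.median(arr)), float(arr.min()), float(arr.max()), len(arr)


def compare_groups(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, int, int]:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns (statistic, p-value, n_a, n_b).  Degenerate input with zero
    variance in both groups and equal means yields (0, 1) by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, len(a), len(b)
        return float("inf"), 0.0, len(a), len(b)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), len(a), len(b)
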