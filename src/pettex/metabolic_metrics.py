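"""Semiquantitative PET metrics: SUVmax, metabolic tumor volume, ROI volume,
and maximal lesion diameter.

The metabolic tumor volume (MTV) uses the common fixed-fraction rule: the
volume of masked voxels whose intensity is *strictly greater* than
``fraction x SUVmax`` (default fraction 0.41). Ties at exactly the threshold
are excluded. The MTV is evaluated inside the supplied ROI mask; diameters
are measured between voxel centers.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from pettex.imaging_io import ImageVolume, RoiMask

__all__ = ["suv_max", "metabolic_tumor_volume", "roi_volume", "max_diameter"]


def _masked_values(volume: ImageVolume, mask: RoiMask) -> np.ndarray:
    mask.check_congruent(volume)
    vals = volume.values[mask.flags]
    if vals.size == 0:
        raise ValueError("mask is empty; no voxels to analyse")
    return vals


def suv_max(volume: ImageVolume, mask: RoiMask) -> float:
    """Maximum intensity over the masked voxels."""
    return float(_masked_values(volume, mask).max())


def metabolic_tumor_volume(volume: ImageVolume, mask: RoiMask, fraction: float = 0.41) -> float:
    """Volume (mm^3) of masked voxels with intensity > fraction * SUVmax."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"threshold fraction must lie in (0, 1); got {fraction}")
    vals = _masked_values(volume, mask)
    threshold = fraction * vals.max()
    return float(np.count_nonzero(vals > threshold)) * volume.voxel_volume_mm3


def roi_volume(mask: RoiMask) -> float:
    """Physical volume (mm^3) of the mask: voxel count x voxel volume."""
    n = mask.n_voxels
    if n == 0:
        raise ValueError("mask is empty")
    return float(n) * float(np.prod(mask.spacing_mm))


def max_diameter(mask: RoiMask) -> float:
    """Maximum Euclidean distance (mm) between centers of any two masked voxels.

    For a single-slice mask this is the in-plane maximal diameter. The
    computation prunes to the convex hull when the mask is large; the result
    is identical to the exhaustive all-pairs scan because the diameter of a
    point set is attained on its hull.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    coords = np.argwhere(mask.flags).astype(np.float64)
    coords *= np.asarray(mask.spacing_mm)
    if coords.shape[0] == 1:
        return 0.0
    # drop degenerate axes (e.g. single-slice masks) so the hull is full-rank
    spans = coords.max(axis=0) - coords.min(axis=0)
    pts = coords[:, spans > 0]
    if pts.shape[1] == 0:
        return 0.0
    if pts.shape[0] > 64 and pts.shape[1] >= 2:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # nearly-degenerate geometry: fall back to all pairs
    return float(pdist(pts).max())
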