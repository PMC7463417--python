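"""First-order histogram features and grey-level co-occurrence matrix (GLCM)
texture features for PET (3-D ROI) and CT (single-slice ROI).

Feature definitions
-------------------
First-order statistics are computed on the raw masked intensities:
mean, SD, minimum, maximum, cumulative percentiles (5/10/25/50/75/90),
skewness (third standardized moment, g1), kurtosis (excess, g2), and the
Shannon entropy of the n_bins histogram over the ROI's own min-max range
(base-2 logarithm, so entropy is in bits and bounded by log2(n_bins)).
Mode and max-frequency are computed on integer-quantized intensities:
max-frequency is the count of the most frequent integer level, mode the
level itself (ties broken toward the lowest level).

GLCMs are accumulated per axial slice at a fixed voxel offset; both voxels
of a pair must lie inside the mask. The four conventional in-plane
directions at distance 1 are labelled 10-13:

====== ============== =========
label  (row, col)      angle
====== ============== =========
10     (0, 1)          0 deg
11     (1, 1)          45 deg
12     (1, 0)          90 deg
13     (1, -1)         135 deg
====== ============== =========

From the normalized matrix P the scalar features are
energy = sum P^2, entropy = -sum P log2 P, inertia (contrast)
= sum (i-j)^2 P, and variance = sum (i-mu)^2 P with mu = sum i P(i, j),
where i, j are 0-based grey-level bin indices.

Grey levels are discretized into ``n_bins`` equal-width bins. The generic
default is the ROI's own min-max range (a common radiomics convention), but
the cohort analysis uses fixed per-modality ranges
(:data:`PET_ANALYSIS_DISC`, :data:`CT_ANALYSIS_DISC`): with a fixed range,
entropy and the GLCM respond to the *absolute* grey-level spread of the
tumor, so hotter and more heterogeneous lesions score higher first-order
entropy and lower GLCM energy — the sign pattern the response analysis
relies on. Under ROI-relative binning those statistics are scale-free and
blind to that effect. Bin count, range policy, offsets and symmetrization
are all configurable.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from pettex.imaging_io import ImageVolume, PatientRecord, RoiMask
from pettex.metabolic_metrics import max_diameter, metabolic_tumor_volume, roi_volume, suv_max

__all__ = [
    "DiscretizationSpec",
    "GlcmSpec",
    "GLCM_DIRECTION_OFFSETS",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "extract_patient_features",
    "extract_feature_table",
    "PET_FEATURES",
    "CT_FEATURES",
]

#: direction label -> (row, col) offset at distance 1
GLCM_DIRECTION_OFFSETS: dict[int, tuple[int, int]] = {
    10: (0, 1),
    11: (1, 1),
    12: (1, 0),
    13: (1, -1),
}


@dataclasses.dataclass(frozen=True)
class DiscretizationSpec:
    """Grey-level binning used for histogram entropy and the GLCM."""

    n_bins: int = 256
    range_policy: str = "roi-min-max"  # or "fixed"
    fixed_range: tuple[float, float] | None = None
    integer_quantize_for_mode: bool = True

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2; got {self.n_bins}")
        if self.range_policy not in ("roi-min-max", "fixed"):
            raise ValueError(f"unknown range policy {self.range_policy!r}")
        if self.range_policy == "fixed" and self.fixed_range is None:
            raise ValueError("fixed range policy requires fixed_range")

    def bounds(self, values: np.ndarray) -> tuple[float, float]:
        if self.range_policy == "fixed":
            return float(self.fixed_range[0]), float(self.fixed_range[1])
        return float(values.min()), float(values.max())


@dataclasses.dataclass(frozen=True)
class GlcmSpec:
    """Offset and symmetrization for one co-occurrence matrix."""

    direction_label: int = 10
    distance: int = 1
    symmetric: bool = True

    def __post_init__(self):
        if self.direction_label not in GLCM_DIRECTION_OFFSETS:
            raise ValueError(
                f"direction label must be one of {sorted(GLCM_DIRECTION_OFFSETS)}; "
                f"got {self.direction_label}"
            )
        if self.distance < 1:
            raise ValueError(f"distance must be a positive integer; got {self.distance}")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = GLCM_DIRECTION_OFFSETS[self.direction_label]
        return dr * self.distance, dc * self.distance


#: analysis-convention binning: 256 bins over a fixed grey-level range wide
#: enough for the hottest lesions (PET) or the attenuation window (CT)
PET_ANALYSIS_DISC = DiscretizationSpec(n_bins=256, range_policy="fixed", fixed_range=(0.0, 20480.0))
CT_ANALYSIS_DISC = DiscretizationSpec(n_bins=256, range_policy="fixed", fixed_range=(0.0, 256.0))


def _discretize(values: np.ndarray, disc: DiscretizationSpec) -> np.ndarray:
    """Map values to 0-based bin indices over the discretization range."""
    lo, hi = disc.bounds(values)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp)
    idx = np.floor((values - lo) / (hi - lo) * disc.n_bins).astype(np.intp)
    return np.clip(idx, 0, disc.n_bins - 1)


def first_order_features(
    masked_values: Iterable[float],
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, float]:
    """First-order histogram statistics of the masked intensities.

    Returns a dict with keys mean, sd, max_frequency, mode, minimum, maximum,
    p5, p10, p25, p50, p75, p90, skewness, kurtosis, entropy.
    """
    vals = np.asarray(list(masked_values) if not isinstance(masked_values, np.ndarray) else masked_values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("first-order features require at least one value")
    n = vals.size
    mean = float(vals.mean())
    if n == 1 or vals.min() == vals.max():
        sd = 0.0  # exact zero for a constant region (no summation noise)
    else:
        sd = float(vals.std(ddof=1))

    # mode / max-frequency on integer-quantized grey levels
    q = np.round(vals).astype(np.int64) if disc.integer_quantize_for_mode else vals
    levels, counts = np.unique(q, return_counts=True)
    top = int(counts.max())
    mode = float(levels[counts == top].min())  # ties -> lowest level

    # skewness g1 / excess kurtosis g2 (bias-uncorrected standardized moments)
    centered = vals - mean
    m2 = float(np.mean(centered**2))
    if m2 > 0:
        skew = float(np.mean(centered**3)) / m2**1.5
        kurt = float(np.mean(centered**4)) / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0

    # Shannon entropy of the n_bins histogram over the ROI range
    lo, hi = disc.bounds(vals)
    if hi > lo:
        hist, _ = np.histogram(vals, bins=disc.n_bins, range=(lo, hi))
        p = hist[hist > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0

    pcts = np.percentile(vals, [5, 10, 25, 50, 75, 90])
    return {
        "mean": mean,
        "sd": sd,
        "max_frequency": float(top),
        "mode": mode,
        "minimum": float(vals.min()),
        "maximum": float(vals.max()),
        "p5": float(pcts[0]),
        "p10": float(pcts[1]),
        "p25": float(pcts[2]),
        "p50": float(pcts[3]),
        "p75": float(pcts[4]),
        "p90": float(pcts[5]),
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
    }


def glcm_matrix(
    image: ImageVolume,
    mask: RoiMask,
    spec: GlcmSpec = GlcmSpec(),
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> np.ndarray:
    """Normalized grey-level co-occurrence matrix for one direction.

    Counts are accumulated per axial slice over every slice intersecting the
    mask; a pair contributes only when both voxels are inside the mask.
    Symmetric by default (each ordered pair counted in both orders), then
    normalized to sum 1.
    """
    mask.check_congruent(image)
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    vals = image.values[mask.flags]
    binned = np.zeros(image.values.shape, dtype=np.intp)
    binned[mask.flags] = _discretize(vals, disc)

    dr, dc = spec.offset
    k = disc.n_bins
    counts = np.zeros((k, k), dtype=np.float64)
    nz, ny, nx = image.values.shape
    total_pairs = 0
    for z in range(nz):
        m = mask.flags[z]
        if not m.any():
            continue
        b = binned[z]
        # source region such that (r+dr, c+dc) stays in bounds
        r0, r1 = max(0, -dr), ny - max(0, dr)
        c0, c1 = max(0, -dc), nx - max(0, dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not src.any():
            continue
        i = b[r0:r1, c0:c1][src]
        j = b[r0 + dr : r1 + dr, c0 + dc : c1 + dc][src]
        np.add.at(counts, (i, j), 1.0)
        total_pairs += i.size
    if total_pairs == 0:
        raise ValueError(
            f"no in-mask voxel pair exists for GLCM direction {spec.direction_label} "
            f"(offset {spec.offset})"
        )
    if spec.symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Scalar texture features of a normalized co-occurrence matrix.

    energy = sum P^2; entropy = -sum P log2 P (0 log 0 = 0);
    inertia = sum (i-j)^2 P; variance = sum (i-mu)^2 P, mu = sum i P.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(P.sum() - 1.0) > 1e-9 or (P < 0).any():
        raise ValueError("GLCM must be normalized to sum 1 with nonnegative entries")
    k = P.shape[0]
    i = np.arange(k, dtype=np.float64)[:, None]
    j = np.arange(k, dtype=np.float64)[None, :]
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    energy = float((P**2).sum())
    inertia = float(((i - j) ** 2 * P).sum())
    mu = float((i * P).sum())
    variance = float(((i - mu) ** 2 * P).sum())
    return {"entropy_glcm": entropy, "energy_glcm": energy, "inertia_glcm": inertia, "variance_glcm": variance}


# canonical column orders for the feature table -----------------------------

_PET_FIRST_ORDER = [
    "mean", "sd", "max_frequency", "mode", "minimum", "maximum",
    "p5", "p10", "p25", "p50", "p75", "p90", "skewness", "kurtosis", "entropy",
]
_CT_FIRST_ORDER = [
    "mean", "sd", "max_frequency", "mode", "maximum", "minimum",
    "skewness", "kurtosis", "entropy",
]
_GLCM_STATS = ["entropy_glcm", "energy_glcm", "inertia_glcm", "variance_glcm"]

PET_FEATURES = (
    _PET_FIRST_ORDER
    + ["volume_mm3", "max_diameter_mm"]
    + [f"{s}{d}" for s in _GLCM_STATS for d in GLCM_DIRECTION_OFFSETS]
)
CT_FEATURES = (
    [f"ct_{name}" for name in _CT_FIRST_ORDER]
    + ["ct_max_diameter_mm"]
    + [f"ct_{s}{d}" for s in _GLCM_STATS for d in GLCM_DIRECTION_OFFSETS]
)


def extract_patient_features(
    record: PatientRecord,
    disc: DiscretizationSpec | None = None,
    reader: int = 1,
    ct_disc: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """Full PET + CT feature vector for one patient and one reader.

    PET features use the 3-D mask (GLCMs accumulated per axial slice); CT
    features use the single-slice mask. ``disc``/``ct_disc`` default to the
    fixed-range analysis conventions :data:`PET_ANALYSIS_DISC` and
    :data:`CT_ANALYSIS_DISC`. Returns a name -> value mapping including
    suvmax and mtv_mm3. Deterministic given its inputs.
    """
    disc = PET_ANALYSIS_DISC if disc is None else disc
    ct_disc = CT_ANALYSIS_DISC if ct_disc is None else ct_disc
    if reader == 1:
        pet_mask, ct_mask = record.pet_mask, record.ct_mask
    elif reader == 2:
        pet_mask, ct_mask = record.pet_mask_reader2, record.ct_mask_reader2
    else:
        raise ValueError(f"reader must be 1 or 2; got {reader}")

    out: dict[str, float] = {}
    out["suvmax"] = suv_max(record.pet, pet_mask)
    out["mtv_mm3"] = metabolic_tumor_volume(record.pet, pet_mask)

    pet_vals = record.pet.values[pet_mask.flags]
    out.update(first_order_features(pet_vals, disc))
    out["volume_mm3"] = roi_volume(pet_mask)
    out["max_diameter_mm"] = max_diameter(pet_mask)
    for d in GLCM_DIRECTION_OFFSETS:
        P = glcm_matrix(record.pet, pet_mask, GlcmSpec(direction_label=d), disc)
        for stat, val in glcm_features(P).items():
            out[f"{stat}{d}"] = val

    ct_vals = record.ct_slice.values[ct_mask.flags]
    ct_fo = first_order_features(ct_vals, ct_disc)
    for name in _CT_FIRST_ORDER:
        out[f"ct_{name}"] = ct_fo[name]
    out["ct_max_diameter_mm"] = max_diameter(ct_mask)
    for d in GLCM_DIRECTION_OFFSETS:
        P = glcm_matrix(record.ct_slice, ct_mask, GlcmSpec(direction_label=d), ct_disc)
        for stat, val in glcm_features(P).items():
            out[f"ct_{stat}{d}"] = val
    return out


def extract_feature_table(
    records: Iterable[PatientRecord],
    disc: DiscretizationSpec | None = None,
    reader: int = 1,
    ct_disc: DiscretizationSpec | None = None,
) -> pd.DataFrame:
    """Feature table with one row per patient, indexed by patient id."""
    rows = {}
    for rec in records:
        rows[rec.id] = extract_patient_features(rec, disc, reader, ct_disc)
    order = ["suvmax", "mtv_mm3"] + PET_FEATURES + CT_FEATURES
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[order]
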