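"""Synthetic phantom cohorts with the statistical structure the analysis
assumes: a complete-response (CR) group and a non-CR group whose tumors are
larger, hotter, and more heterogeneous, plus a perturbed second-reader mask
set for interobserver agreement analysis.

Phantom model
-------------
Each patient's PET volume is a spherical tumor on a uniform background.
Intratumor heterogeneity is log-normal multiplicative noise: a standard
normal field is smoothed with a Gaussian kernel of width
``correlation_length_mm``, restandardized to unit variance, scaled by
``heterogeneity_sd`` (the SD of the log-intensity) and exponentiated. A
single knob therefore moves both the first-order entropy and the GLCM
features. With ``heterogeneity_sd = 0`` every tumor voxel equals
``base_intensity`` exactly.

The second reader's mask is a stochastic morphological perturbation of the
first reader's: boundary voxels are eroded and outer-boundary voxels dilated
independently, which yields ICC < 1 without a second human. The CT "image"
is the central PET slice rescaled to an attenuation-like range with
independent additive noise — a plausible 2-D texture source, not an
anatomical simulation.

Deauville scores are drawn consistently with the response label (CR from
{1, 2, 3} with weights 3:8:9, non-CR from {4, 5} with weights 3:7, matching
the reported score mix of the 30-patient cohort this emulates).

Group-level defaults mirror the reported cohort: 20 CR vs 10 non-CR
patients; non-CR multipliers of 1.6 on intensity (median grey level ~4000
vs ~7000), 1.75 on radius (~5.4x on volume, ~42 cm^3 vs ~226 cm^3) and 1.8
on the log-intensity SD (kept small enough that the hottest voxel stays
within ~2-3x the tumor median, as observed clinically), with log-normal
between-patient spread wide enough that the group distributions overlap
the way the reported interquartile ranges do.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from pettex.imaging_io import ImageVolume, PatientRecord, RoiMask

__all__ = ["PhantomSpec", "CohortConfig", "generate_phantom", "generate_cohort"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one spherical-tumor phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    tumor_radius_mm: float = 20.0
    base_intensity: float = 4000.0
    heterogeneity_sd: float = 0.35
    correlation_length_mm: float = 8.0
    background_intensity: float = 0.0

    def __post_init__(self):
        if any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"grid shape must be positive; got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel spacing must be positive; got {self.voxel_spacing_mm}")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.base_intensity <= 0:
            raise ValueError("base intensity must be positive")
        if self.heterogeneity_sd < 0 or self.correlation_length_mm < 0:
            raise ValueError("heterogeneity_sd and correlation_length_mm must be nonnegative")
        if not 0 <= self.background_intensity < self.base_intensity:
            raise ValueError("require 0 <= background_intensity < base_intensity")
        max_fit = min(
            (n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm)
        )
        if self.tumor_radius_mm > max_fit:
            raise ValueError(
                f"tumor radius {self.tumor_radius_mm} mm does not fit inside the grid "
                f"(max {max_fit:.1f} mm for shape {self.grid_shape} at spacing "
                f"{self.voxel_spacing_mm})"
            )


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[ImageVolume, RoiMask]:
    """Simulate one PET volume and its tumor mask; bit-reproducible per (spec, seed)."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing_mm)

    center = (np.array(shape) - 1) / 2.0
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    inside = dist2 <= spec.tumor_radius_mm**2

    values = np.full(shape, float(spec.background_intensity))
    if spec.heterogeneity_sd > 0:
        field = rng.standard_normal(shape)
        sigma_vox = [spec.correlation_length_mm / s for s in spacing]
        if any(sv > 0 for sv in sigma_vox):
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        sd = field.std()
        if sd > 0:
            field = field / sd
        values[inside] = spec.base_intensity * np.exp(spec.heterogeneity_sd * field[inside])
    else:
        values[inside] = spec.base_intensity
    return ImageVolume(values, spacing), RoiMask(inside, spacing)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort simulation settings.

    Effect multipliers apply to the non-CR group and must be >= 1 so that
    the non-CR group stochastically dominates the CR group in intensity,
    size, and heterogeneity. ``*_sigma`` are log-normal between-patient SDs
    on the log scale.
    """

    n_cr: int = 20
    n_noncr: int = 10
    seed: int = 0

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    tumor_radius_mm: float = 21.5
    base_intensity: float = 4000.0
    heterogeneity_sd: float = 0.18
    correlation_length_mm: float = 8.0
    background_intensity: float = 0.0

    intensity_multiplier: float = 1.6
    size_multiplier: float = 1.75
    heterogeneity_multiplier: float = 1.8
    radius_sigma: float = 0.40
    intensity_sigma: float = 0.60
    heterogeneity_sigma: float = 0.20

    # covariate model: per-group probabilities, CR first
    intestinal_rate: tuple[float, float] = (0.30, 0.70)
    stage_probs: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.45, 0.30, 0.25),  # CR: stage I, II, IV
        (0.10, 0.30, 0.60),
    )
    ipi_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.30, 0.30, 0.20, 0.10, 0.10, 0.0),
        (0.20, 0.20, 0.10, 0.30, 0.20, 0.0),
    )
    ki67_high_rate: tuple[float, float] = (0.55, 0.70)
    gcb_rate: tuple[float, float] = (0.45, 0.40)
    deauville_weights_cr: tuple[float, float, float] = (3.0, 8.0, 9.0)  # scores 1..3
    deauville_weights_noncr: tuple[float, float] = (3.0, 7.0)  # scores 4..5

    reader2_perturbation: float = 0.2

    ct_noise_sd: float = 3.0
    ct_window: tuple[float, float] = (20.0, 80.0)

    def __post_init__(self):
        if self.n_cr < 1 or self.n_noncr < 1:
            raise ValueError("both groups need at least one patient")
        for m in (self.intensity_multiplier, self.size_multiplier, self.heterogeneity_multiplier):
            if m < 1:
                raise ValueError("effect multipliers must be >= 1 (non-CR dominates)")
        probs = (
            list(self.intestinal_rate)
            + list(self.ki67_high_rate)
            + list(self.gcb_rate)
            + [self.reader2_perturbation]
            + [p for row in self.stage_probs for p in row]
            + [p for row in self.ipi_probs for p in row]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for row in self.stage_probs + self.ipi_probs:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"probability vector must sum to 1; got {row}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def tuplify(v):
            return tuple(tuplify(x) for x in v) if isinstance(v, (list, tuple)) else v

        return cls(**{k: tuplify(v) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        def listify(v):
            return [listify(x) for x in v] if isinstance(v, tuple) else v

        with open(path, "w") as fh:
            yaml.safe_dump({k: listify(v) for k, v in dataclasses.asdict(self).items()}, fh)


def _perturb_mask(flags: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Stochastically erode/dilate the mask boundary (second-reader model)."""
    if prob <= 0:
        return flags.copy()
    structure = ndimage.generate_binary_structure(flags.ndim, 1)
    eroded = ndimage.binary_erosion(flags, structure)
    dilated = ndimage.binary_dilation(flags, structure)
    inner_boundary = flags & ~eroded
    outer_boundary = dilated & ~flags
    out = flags.copy()
    drop = inner_boundary & (rng.random(flags.shape) < prob / 2)
    add = outer_boundary & (rng.random(flags.shape) < prob / 2)
    out[drop] = False
    out[add] = True
    if not out.any():  # degenerate tiny mask: keep reader 1's
        return flags.copy()
    return out


def _choice(rng, options, probs):
    return options[int(rng.choice(len(options), p=np.asarray(probs) / np.sum(probs)))]


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Simulate a full two-group cohort of :class:`PatientRecord` objects.

    Pure function of the config (including its seed): identical configs
    reproduce bit-identical cohorts.
    """
    master = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    groups = ["CR"] * config.n_cr + ["nonCR"] * config.n_noncr
    max_fit = min(
        (n - 1) / 2.0 * s for n, s in zip(config.grid_shape, config.voxel_spacing_mm)
    )
    for idx, group in enumerate(groups):
        rng = np.random.default_rng(master.integers(2**31))
        g = 1 if group == "nonCR" else 0

        radius = config.tumor_radius_mm * (config.size_multiplier**g)
        radius *= float(np.exp(rng.normal(0.0, config.radius_sigma)))
        radius = float(np.clip(radius, 2.0 * max(config.voxel_spacing_mm), 0.95 * max_fit))
        intensity = config.base_intensity * (config.intensity_multiplier**g)
        intensity *= float(np.exp(rng.normal(0.0, config.intensity_sigma)))
        hetero = config.heterogeneity_sd * (config.heterogeneity_multiplier**g)
        hetero *= float(np.exp(rng.normal(0.0, config.heterogeneity_sigma)))

        spec = PhantomSpec(
            grid_shape=config.grid_shape,
            voxel_spacing_mm=config.voxel_spacing_mm,
            tumor_radius_mm=radius,
            base_intensity=intensity,
            heterogeneity_sd=hetero,
            correlation_length_mm=config.correlation_length_mm,
            background_intensity=config.background_intensity,
        )
        pet, pet_mask = generate_phantom(spec, int(rng.integers(2**31)))
        pet_mask_r2 = RoiMask(
            _perturb_mask(pet_mask.flags, config.reader2_perturbation, rng),
            pet_mask.spacing_mm,
        )

        # CT: central PET slice windowed to an attenuation-like range + noise
        zc = pet.values.shape[0] // 2
        sl = pet.values[zc]
        lo, hi = float(sl.min()), float(sl.max())
        wlo, whi = config.ct_window
        scaled = wlo + (whi - wlo) * (sl - lo) / (hi - lo) if hi > lo else np.full_like(sl, wlo)
        ct_vals = scaled + rng.normal(0.0, config.ct_noise_sd, sl.shape)
        ct = ImageVolume(ct_vals[None, :, :], pet.spacing_mm)
        ct_flags = pet_mask.flags[zc][None, :, :]
        ct_mask = RoiMask(ct_flags, pet.spacing_mm)
        ct_mask_r2 = RoiMask(
            _perturb_mask(ct_flags[0], config.reader2_perturbation, rng)[None, :, :],
            pet.spacing_mm,
        )

        if group == "CR":
            deauville = _choice(rng, [1, 2, 3], config.deauville_weights_cr)
        else:
            deauville = _choice(rng, [4, 5], config.deauville_weights_noncr)

        stage = _choice(rng, ["I", "II", "IV"], config.stage_probs[g])
        ipi = _choice(rng, [0, 1, 2, 3, 4, 5], config.ipi_probs[g])
        ki67_high = rng.random() < config.ki67_high_rate[g]
        ki67 = float(rng.uniform(80, 95) if ki67_high else rng.uniform(50, 79))
        subtype = "GCB" if rng.random() < config.gcb_rate[g] else "nonGCB"
        intestinal = bool(rng.random() < config.intestinal_rate[g])

        rec = PatientRecord(
            id=f"P{idx + 1:03d}",
            pet=pet,
            pet_mask=pet_mask,
            pet_mask_reader2=pet_mask_r2,
            ct_slice=ct,
            ct_mask=ct_mask,
            ct_mask_reader2=ct_mask_r2,
            stage=stage,
            ipi=int(ipi),
            intestinal_involvement=intestinal,
            ki67_percent=round(ki67, 1),
            subtype=subtype,
            deauville=int(deauville),
            marrow_fdg_avid=False,
        )
        rec.classify()
        assert rec.response == group  # scores are drawn consistently with the label
        records.append(rec)
    return records
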