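"""Image volumes, tumor masks, patient records, and cohort I/O.

Conventions
-----------
* Arrays use 0-based indices with axis order ``(z, y, x)``; ``spacing_mm``
  follows the same order.
* A CT "slice" is stored as a 3-D volume with z-extent 1 so that 2-D and 3-D
  analyses share a single code path.
* Masks must be congruent with their image: identical shape and spacing.
  There is no implicit resampling — silent resampling corrupts texture
  statistics, so mismatches are rejected with :class:`GeometryMismatchError`.

Images and masks round-trip through NIfTI (``.nii``/``.nii.gz``); the cohort
manifest is a CSV with one row per patient carrying file paths and clinical
covariates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "MissingFileError",
    "GeometryMismatchError",
    "InvalidScoreError",
    "ImageVolume",
    "RoiMask",
    "PatientRecord",
    "classify_response",
    "save_cohort",
    "load_cohort",
]

STAGES = ("I", "II", "IV")
SUBTYPES = ("GCB", "nonGCB")


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class MissingFileError(CohortError):
    """A manifest references an image or mask file that does not exist."""


class GeometryMismatchError(CohortError):
    """Mask shape or spacing does not match the paired image."""


class InvalidScoreError(CohortError):
    """A Deauville score outside the 1-5 scale (or other domain violation)."""


@dataclasses.dataclass(frozen=True)
class ImageVolume:
    """A gridded intensity image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray
        3-D array of finite grey-level intensities, axis order ``(z, y, x)``.
    spacing_mm : tuple of float
        Voxel edge lengths in mm per axis, same order.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise CohortError(f"image must be 3-D (z, y, x); got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise CohortError("image contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise CohortError(f"spacing must be three positive lengths; got {self.spacing_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def __eq__(self, other):
        if not isinstance(other, ImageVolume):
            return NotImplemented
        return self.spacing_mm == other.spacing_mm and np.array_equal(self.values, other.values)


@dataclasses.dataclass(frozen=True)
class RoiMask:
    """A binary region of interest congruent with an :class:`ImageVolume`."""

    flags: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        flags = np.asarray(self.flags).astype(bool)
        if flags.ndim != 3:
            raise CohortError(f"mask must be 3-D (z, y, x); got ndim={flags.ndim}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise CohortError(f"spacing must be three positive lengths; got {self.spacing_mm}")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())

    def check_congruent(self, image: ImageVolume, context: str = "") -> None:
        """Raise :class:`GeometryMismatchError` unless mask and image align."""
        where = f" ({context})" if context else ""
        if self.flags.shape != image.values.shape:
            raise GeometryMismatchError(
                f"mask shape {self.flags.shape} does not match image shape "
                f"{image.values.shape}{where}"
            )
        if not np.allclose(self.spacing_mm, image.spacing_mm):
            raise GeometryMismatchError(
                f"mask spacing {self.spacing_mm} does not match image spacing "
                f"{image.spacing_mm}{where}"
            )

    def __eq__(self, other):
        if not isinstance(other, RoiMask):
            return NotImplemented
        return self.spacing_mm == other.spacing_mm and np.array_equal(self.flags, other.flags)


def classify_response(deauville: int, marrow_fdg_avid: bool = False) -> str:
    """Classify the interim PET response from the Deauville 5-point score.

    Complete response (``"CR"``) requires a Deauville score of 1-3 and no
    FDG-avid marrow disease; everything else is ``"nonCR"``.
    """
    deauville = int(deauville)
    if not 1 <= deauville <= 5:
        raise InvalidScoreError(f"Deauville score must be in 1..5; got {deauville}")
    return "CR" if deauville <= 3 and not marrow_fdg_avid else "nonCR"


@dataclasses.dataclass
class PatientRecord:
    """One patient: PET volume, CT slice, two readers' masks, covariates."""

    id: str
    pet: ImageVolume
    pet_mask: RoiMask
    pet_mask_reader2: RoiMask
    ct_slice: ImageVolume
    ct_mask: RoiMask
    ct_mask_reader2: RoiMask
    stage: str
    ipi: int
    intestinal_involvement: bool
    ki67_percent: float
    subtype: str
    deauville: int
    marrow_fdg_avid: bool = False
    response: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        pid = self.id
        if not 1 <= int(self.deauville) <= 5:
            raise InvalidScoreError(f"patient {pid}: Deauville score must be in 1..5; got {self.deauville}")
        if self.stage not in STAGES:
            raise InvalidScoreError(f"patient {pid}: stage must be one of {STAGES}; got {self.stage!r}")
        if not 0 <= int(self.ipi) <= 5:
            raise InvalidScoreError(f"patient {pid}: IPI must be in 0..5; got {self.ipi}")
        if not 0 <= float(self.ki67_percent) <= 100:
            raise InvalidScoreError(f"patient {pid}: Ki67 must be in [0, 100]; got {self.ki67_percent}")
        if self.subtype not in SUBTYPES:
            raise InvalidScoreError(f"patient {pid}: subtype must be one of {SUBTYPES}; got {self.subtype!r}")
        if self.response is not None and self.response not in ("CR", "nonCR"):
            raise InvalidScoreError(f"patient {pid}: response must be CR/nonCR; got {self.response!r}")
        self.pet_mask.check_congruent(self.pet, f"patient {pid}, PET mask reader 1")
        self.pet_mask_reader2.check_congruent(self.pet, f"patient {pid}, PET mask reader 2")
        if self.ct_slice.values.shape[0] != 1:
            raise GeometryMismatchError(f"patient {pid}: CT slice must have z-extent 1")
        self.ct_mask.check_congruent(self.ct_slice, f"patient {pid}, CT mask reader 1")
        self.ct_mask_reader2.check_congruent(self.ct_slice, f"patient {pid}, CT mask reader 2")

    def classify(self) -> str:
        """Assign ``response`` from the Deauville score and marrow status."""
        self.response = classify_response(self.deauville, self.marrow_fdg_avid)
        return self.response

    def covariates(self) -> dict:
        return {
            "id": self.id,
            "stage": self.stage,
            "ipi": int(self.ipi),
            "intestinal_involvement": bool(self.intestinal_involvement),
            "ki67_percent": float(self.ki67_percent),
            "subtype": self.subtype,
            "deauville": int(self.deauville),
            "marrow_fdg_avid": bool(self.marrow_fdg_avid),
            "response": self.response,
        }

    def __eq__(self, other):
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return (
            self.covariates() == other.covariates()
            and self.pet == other.pet
            and self.pet_mask == other.pet_mask
            and self.pet_mask_reader2 == other.pet_mask_reader2
            and self.ct_slice == other.ct_slice
            and self.ct_mask == other.ct_mask
            and self.ct_mask_reader2 == other.ct_mask_reader2
        )


# ---------------------------------------------------------------------------
# NIfTI + manifest round trip
# ---------------------------------------------------------------------------

_IMAGE_COLUMNS = ("pet", "pet_mask", "pet_mask_reader2", "ct_slice", "ct_mask", "ct_mask_reader2")


def _save_nifti(path: Path, values: np.ndarray, spacing_zyx: Sequence[float]) -> None:
    # nibabel expects (x, y, z); we store (z, y, x)
    data = np.ascontiguousarray(np.transpose(values, (2, 1, 0)))
    sz, sy, sx = spacing_zyx
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not Path(path).exists():
        raise MissingFileError(f"file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    sx, sy, sz = (float(z) for z in img.header.get_zooms()[:3])
    return np.transpose(data, (2, 1, 0)), (sz, sy, sx)


def save_cohort(records: Sequence[PatientRecord], outdir: str | Path) -> Path:
    """Write a cohort to ``outdir`` as NIfTI images plus a CSV manifest.

    Returns the manifest path. Layout: ``<outdir>/<id>_<kind>.nii.gz`` per
    image/mask and ``<outdir>/manifest.csv`` with paths and covariates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row = rec.covariates()
        for kind in _IMAGE_COLUMNS:
            obj = getattr(rec, kind)
            path = outdir / f"{rec.id}_{kind}.nii.gz"
            if isinstance(obj, ImageVolume):
                _save_nifti(path, obj.values, obj.spacing_mm)
            else:
                _save_nifti(path, obj.flags.astype(np.uint8), obj.spacing_mm)
            row[kind] = path.name
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[PatientRecord]:
    """Load and fully validate a cohort from a CSV manifest.

    Every geometry or domain violation raises a named error carrying the
    patient id; nothing is silently resampled or coerced.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingFileError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    records = []
    for _, row in df.iterrows():
        images = {}
        for kind in _IMAGE_COLUMNS:
            values, spacing = _load_nifti(base / str(row[kind]))
            if kind in ("pet", "ct_slice"):
                images[kind] = ImageVolume(values.astype(np.float64), spacing)
            else:
                images[kind] = RoiMask(values > 0, spacing)
        response = row.get("response")
        if isinstance(response, float) and np.isnan(response):
            response = None
        rec = PatientRecord(
            id=str(row["id"]),
            stage=str(row["stage"]),
            ipi=int(row["ipi"]),
            intestinal_involvement=bool(row["intestinal_involvement"]),
            ki67_percent=float(row["ki67_percent"]),
            subtype=str(row["subtype"]),
            deauville=int(row["deauville"]),
            marrow_fdg_avid=bool(row.get("marrow_fdg_avid", False)),
            response=response,
            **images,
        )
        records.append(rec)
    return records


def export_metadata(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Dump validated per-patient covariates as JSON (no image data)."""
    with open(path, "w") as fh:
        json.dump([r.covariates() for r in records], fh, indent=2)
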