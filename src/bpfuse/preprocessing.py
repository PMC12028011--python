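"""Geometric and intensity preprocessing plus clinical-variable scaling.

The imaging chain is: resample to a common voxel spacing, extract a fixed
central crop, then per-image min-max normalization to [0, 1]. Clinical
variables (age, PSA, PSA density) are scaled to [-1, 1] with bounds fitted
on the training cohort only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from bpfuse.data_model import BpMriCase, ClinicalRecord, SequenceKind, SequenceVolume

__all__ = [
    "PreprocessConfig",
    "ClinicalScalingBounds",
    "resample",
    "resample_mask",
    "central_crop",
    "crop_array",
    "minmax_normalize",
    "prostate_volume",
    "psa_density",
    "fit_clinical_bounds",
    "scale_clinical",
    "preprocess_case",
]

MM3_PER_ML = 1000.0  # explicit mm^3 -> mL constant; avoid silent unit bugs

CropCenterPolicy = Literal["IMAGE_CENTER", "MASK_CENTROID"]


@dataclass
class ClinicalScalingBounds:
    """Per-variable (min, max) learned on the training cohort."""

    age: tuple[float, float]
    psa: tuple[float, float]
    psa_density: tuple[float, float]


@dataclass
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)
    crop_shape: tuple[int, int, int] = (32, 224, 224)
    crop_center_policy: CropCenterPolicy = "IMAGE_CENTER"
    clinical_bounds: Optional[ClinicalScalingBounds] = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError(f"target_spacing must be positive, got {self.target_spacing}")
        if any(s <= 0 for s in self.crop_shape):
            raise ValueError(f"crop_shape must be positive, got {self.crop_shape}")


# ---------------------------------------------------------------------------
# Geometric ops
# ---------------------------------------------------------------------------

def _zoom_factors(spacing, target_spacing):
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be strictly positive, got {target_spacing}")
    return tuple(s / t for s, t in zip(spacing, target_spacing))


def resample(
    volume: SequenceVolume,
    target_spacing: tuple[float, float, float] = (3.0, 0.5, 0.5),
    order: int = 1,
) -> SequenceVolume:
    """Resample intensities to ``target_spacing`` with linear interpolation.

    Output shape is ``round(shape * spacing / target_spacing)`` per axis.
    """
    factors = _zoom_factors(volume.spacing, target_spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return volume.with_voxels(volume.voxels.copy(), spacing=tuple(target_spacing))
    out = ndimage.zoom(
        volume.voxels.astype(np.float32), factors, order=order, mode="nearest",
        grid_mode=True, prefilter=False,
    )
    return volume.with_voxels(out, spacing=tuple(target_spacing))


def resample_mask(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float],
) -> np.ndarray:
    """Nearest-neighbour resampling for binary masks."""
    factors = _zoom_factors(spacing, target_spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return mask.copy()
    out = ndimage.zoom(mask.astype(np.uint8), factors, order=0, mode="nearest",
                       grid_mode=True, prefilter=False)
    return out.astype(np.uint8)


def _crop_bounds(size: int, target: int, center: float) -> tuple[int, int, int, int]:
    """Start/stop in source plus left-pad for one axis; clamps to the image."""
    start = int(round(center - target / 2.0))
    start = max(0, min(start, size - target))
    if size >= target:
        return start, start + target, 0, 0
    # undersized axis: take everything, pad symmetrically
    pad_total = target - size
    pad_lo = pad_total // 2
    return 0, size, pad_lo, pad_total - pad_lo


def crop_array(
    voxels: np.ndarray,
    shape: tuple[int, int, int],
    center: Optional[Sequence[float]] = None,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Crop (and zero-pad when undersized) a 3D array to ``shape`` around ``center``."""
    if center is None:
        center = [s / 2.0 for s in voxels.shape]
    slices, pads = [], []
    for size, target, c in zip(voxels.shape, shape, center):
        a, b, lo, hi = _crop_bounds(size, target, c)
        slices.append(slice(a, b))
        pads.append((lo, hi))
    out = voxels[tuple(slices)]
    if any(lo or hi for lo, hi in pads):
        out = np.pad(out, pads, mode="constant", constant_values=pad_value)
    assert out.shape == tuple(shape)
    return out


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    if mask.sum() == 0:
        raise ValueError("cannot compute centroid of an empty mask")
    return np.asarray(ndimage.center_of_mass(mask), dtype=float)


def central_crop(
    volume: SequenceVolume,
    shape: tuple[int, int, int] = (32, 224, 224),
    policy: CropCenterPolicy = "IMAGE_CENTER",
    mask: Optional[np.ndarray] = None,
) -> SequenceVolume:
    """Extract a fixed-shape crop centred on the image centre or mask centroid.

    Undersized axes are symmetrically zero-padded, so the output shape is
    always exactly ``shape``.
    """
    if policy == "MASK_CENTROID":
        if mask is None:
            raise ValueError("MASK_CENTROID policy requires a mask")
        center = mask_centroid(mask) + 0.5  # voxel index -> continuous coord
    else:
        center = None
    return volume.with_voxels(crop_array(volume.voxels, shape, center))


# ---------------------------------------------------------------------------
# Intensity + clinical
# ---------------------------------------------------------------------------

def minmax_normalize(volume: SequenceVolume) -> SequenceVolume:
    """Per-image min-max normalization to [0, 1].

    A constant image has zero range; it is mapped to all zeros with a warning.
    """
    v = volume.voxels.astype(np.float32)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn(
            f"constant intensities in {volume.kind} of case {volume.case_id!r}; "
            "normalized output is all zeros",
            stacklevel=2,
        )
        return volume.with_voxels(np.zeros_like(v))
    return volume.with_voxels((v - lo) / (hi - lo))


def prostate_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Gland volume in mL: ``N_voxels * dz*dy*dx / 1000``."""
    mask = np.asarray(mask)
    n_voxels = int(np.count_nonzero(mask))
    if n_voxels == 0:
        raise ValueError("empty gland mask: volume would be zero and PSA density undefined")
    return n_voxels * float(np.prod(spacing)) / MM3_PER_ML


def psa_density(psa: float, gland_volume_ml: float) -> float:
    """PSA density in ng/mL per mL of gland."""
    if gland_volume_ml <= 0:
        raise ValueError(f"gland volume must be positive, got {gland_volume_ml}")
    return psa / gland_volume_ml


def _scale_one(x: float, lo: float, hi: float, name: str) -> float:
    if hi == lo:
        warnings.warn(f"degenerate bounds for {name} (min == max); mapping to 0", stacklevel=3)
        return 0.0
    return float(np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0))


def fit_clinical_bounds(records: Iterable[ClinicalRecord]) -> ClinicalScalingBounds:
    """Fit per-variable (min, max) on the training cohort.

    Records with missing PSA density are skipped for that variable.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot fit clinical bounds on an empty cohort")
    ages = [r.age for r in records]
    psas = [r.psa for r in records]
    psads = [r.psa_density for r in records if r.psa_density is not None]
    if not psads:
        psads = [0.0, 1.0]
    return ClinicalScalingBounds(
        age=(min(ages), max(ages)),
        psa=(min(psas), max(psas)),
        psa_density=(min(psads), max(psads)),
    )


def scale_clinical(record: ClinicalRecord, bounds: ClinicalScalingBounds) -> ClinicalRecord:
    """Scale age/PSA/PSAD to [-1, 1]; out-of-bounds values are clipped."""
    psad = record.psa_density if record.psa_density is not None else 0.0
    return replace(
        record,
        age_norm=_scale_one(record.age, *bounds.age, "age"),
        psa_norm=_scale_one(record.psa, *bounds.psa, "psa"),
        psad_norm=_scale_one(psad, *bounds.psa_density, "psa_density"),
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_case(case: BpMriCase, config: PreprocessConfig) -> BpMriCase:
    """Resample, crop and normalize all three sequences of one case.

    Computes PSA density from the gland mask when available, and fills the
    normalized clinical fields when ``config.clinical_bounds`` is set.
    Normalization is applied after cropping.
    """
    mask_rs = None
    if case.gland_mask is not None:
        t2_spacing = case.volumes[SequenceKind.T2W].spacing
        mask_rs = resample_mask(case.gland_mask, t2_spacing, config.target_spacing)

    centroid_mask = mask_rs if config.crop_center_policy == "MASK_CENTROID" else None
    new_volumes = {}
    for kind, vol in case.volumes.items():
        v = resample(vol, config.target_spacing)
        v = central_crop(v, config.crop_shape, config.crop_center_policy, centroid_mask)
        new_volumes[kind] = minmax_normalize(v)

    clinical = case.clinical
    if case.gland_mask is not None and clinical.psa_density is None:
        t2 = case.volumes[SequenceKind.T2W]
        gv = prostate_volume(case.gland_mask, t2.spacing)
        clinical = replace(clinical, psa_density=psa_density(clinical.psa, gv))
    if config.clinical_bounds is not None:
        clinical = scale_clinical(clinical, config.clinical_bounds)

    cropped_mask = None
    if mask_rs is not None:
        center = (
            mask_centroid(mask_rs) + 0.5
            if config.crop_center_policy == "MASK_CENTROID"
            else None
        )
        cropped_mask = crop_array(mask_rs.astype(np.uint8), config.crop_shape, center)

    return BpMriCase(
        case_id=case.case_id,
        volumes=new_volumes,
        clinical=clinical,
        label=case.label,
        gland_mask=cropped_mask,
        cohort=case.cohort,
    )
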