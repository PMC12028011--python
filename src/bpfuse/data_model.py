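"""Case-level container types, cohort splits, and volume/tabular IO.

Axis convention used throughout the package: volume arrays are indexed
``(slice, row, col)`` with voxel spacing ``(dz, dy, dx)`` in millimetres.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SequenceKind",
    "Cohort",
    "SequenceVolume",
    "ClinicalRecord",
    "BpMriCase",
    "CohortSplit",
    "load_volume",
    "save_volume",
    "load_case",
    "load_cohort",
    "stratified_split",
    "read_clinical_table",
    "write_split_manifest",
    "read_split_manifest",
]


class SequenceKind(str, enum.Enum):
    """The three bi-parametric MRI sequences."""

    T2W = "T2W"
    DWI_HIGH_B = "DWI_HIGH_B"
    ADC = "ADC"


class Cohort(str, enum.Enum):
    TRAIN = "TRAIN"
    VAL = "VAL"
    TEST_RETRO = "TEST_RETRO"
    TEST_PROSP = "TEST_PROSP"


@dataclass
class SequenceVolume:
    """A single 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Scalar intensities; must be finite.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm, all strictly positive.
    kind : SequenceKind
    case_id : str
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    kind: SequenceKind
    case_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"volume for case {self.case_id!r} must be rank 3, "
                f"got rank {self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"non-finite voxels in {self.kind} of case {self.case_id!r}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.kind = SequenceKind(self.kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_voxels(self, voxels: np.ndarray, spacing=None) -> "SequenceVolume":
        return replace(self, voxels=voxels, spacing=spacing or self.spacing)


@dataclass
class ClinicalRecord:
    """Per-patient clinical variables and their normalized versions.

    ``age_norm``/``psa_norm``/``psad_norm`` are filled by
    :func:`bpfuse.preprocessing.scale_clinical` and must lie in [-1, 1].
    """

    age: float
    psa: float
    psa_density: Optional[float] = None
    age_norm: Optional[float] = None
    psa_norm: Optional[float] = None
    psad_norm: Optional[float] = None
    site: str = ""
    field_strength: Optional[float] = None
    manufacturer: str = ""

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.psa < 0:
            raise ValueError(f"psa must be >= 0, got {self.psa}")
        for name in ("age_norm", "psa_norm", "psad_norm"):
            v = getattr(self, name)
            if v is not None and not -1.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [-1, 1]")

    def normalized_vector(self) -> np.ndarray:
        """The (age, PSA, PSAD) scalars fed to the classifier, in [-1, 1]."""
        vals = (self.age_norm, self.psa_norm, self.psad_norm)
        if any(v is None for v in vals):
            raise ValueError("clinical record has not been scaled; call scale_clinical first")
        return np.asarray(vals, dtype=np.float64)


@dataclass
class BpMriCase:
    """One patient: three aligned sequence volumes, optional gland mask,
    clinical record, binary biopsy-proven label and cohort assignment."""

    case_id: str
    volumes: dict[SequenceKind, SequenceVolume]
    clinical: ClinicalRecord
    label: int
    gland_mask: Optional[np.ndarray] = None
    cohort: Optional[Cohort] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        missing = [k for k in SequenceKind if k not in self.volumes]
        if missing:
            raise ValueError(
                f"case {self.case_id!r} is missing sequence kind(s): "
                + ", ".join(k.value for k in missing)
            )
        t2_shape = self.volumes[SequenceKind.T2W].shape
        if self.gland_mask is not None:
            self.gland_mask = np.asarray(self.gland_mask)
            if self.gland_mask.shape != t2_shape:
                raise ValueError(
                    f"gland mask shape {self.gland_mask.shape} does not match "
                    f"T2W shape {t2_shape} for case {self.case_id!r}"
                )
            uniq = np.unique(self.gland_mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("gland mask must be binary (values in {0, 1})")

    @property
    def t2w(self) -> SequenceVolume:
        return self.volumes[SequenceKind.T2W]


@dataclass
class CohortSplit:
    """Bookkeeping for a stratified train/val/test split."""

    fractions: tuple[float, float, float]
    members: dict[Cohort, list[str]]
    counts: dict[Cohort, tuple[int, int]] = field(default_factory=dict)  # (neg, pos)

    def cohort_of(self, case_id: str) -> Cohort:
        for cohort, ids in self.members.items():
            if case_id in ids:
                return cohort
        raise KeyError(case_id)

    @property
    def sizes(self) -> dict[Cohort, int]:
        return {c: len(ids) for c, ids in self.members.items()}


# ---------------------------------------------------------------------------
# Volume IO
# ---------------------------------------------------------------------------

def save_volume(volume: SequenceVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1.

    The on-disk array is stored (x, y, z) = (col, row, slice) with an affine
    of ``diag(dx, dy, dz)``, so headers round-trip through other NIfTI tools.
    """
    data = np.ascontiguousarray(np.transpose(volume.voxels, (2, 1, 0)))
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_volume(
    path: str | os.PathLike,
    kind: SequenceKind,
    case_id: str = "",
) -> SequenceVolume:
    """Load a NIfTI (.nii/.nii.gz) or DICOM-series directory as a SequenceVolume."""
    path = Path(path)
    if path.is_dir():
        voxels, spacing = _load_dicom_series(path)
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) for our writer
        voxels = np.transpose(data, (2, 1, 0))
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return SequenceVolume(voxels=voxels, spacing=spacing, kind=kind, case_id=case_id)


def _load_dicom_series(series_dir: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Assemble a DICOM series in slice-position order. Requires pydicom."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM series requires the optional 'pydicom' package; "
            "install it or convert the series to NIfTI"
        ) from exc
    files = sorted(p for p in series_dir.iterdir() if p.is_file())
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    voxels = np.stack([s.pixel_array.astype(np.float32) for s in slices], axis=0)
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        dz = abs(
            float(slices[1].ImagePositionPatient[2]) - float(slices[0].ImagePositionPatient[2])
        )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return voxels, (dz, dy, dx)


def load_case(
    volume_paths: Mapping[SequenceKind | str, str | os.PathLike],
    clinical_row: Mapping,
    mask_path: Optional[str | os.PathLike] = None,
) -> BpMriCase:
    """Assemble a validated :class:`BpMriCase` from files plus one tabular row.

    Parameters
    ----------
    volume_paths : mapping of SequenceKind -> path
        One NIfTI file (or DICOM directory) per sequence kind; all three
        kinds must be present.
    clinical_row : mapping
        Must contain ``case_id``, ``age``, ``psa`` and ``label``; optional
        ``site``, ``field_strength``, ``manufacturer``, ``cohort``.
    mask_path : path, optional
        Binary whole-gland mask aligned to the T2W volume.
    """
    paths = {SequenceKind(k): Path(v) for k, v in volume_paths.items()}
    missing = [k.value for k in SequenceKind if k not in paths]
    if missing:
        raise ValueError("missing sequence kind(s): " + ", ".join(missing))
    case_id = str(clinical_row["case_id"])
    volumes = {k: load_volume(p, k, case_id=case_id) for k, p in paths.items()}

    mask = None
    if mask_path is not None:
        mask_vol = load_volume(mask_path, SequenceKind.T2W, case_id=case_id)
        mask = (mask_vol.voxels > 0.5).astype(np.uint8)

    fs = clinical_row.get("field_strength")
    clinical = ClinicalRecord(
        age=float(clinical_row["age"]),
        psa=float(clinical_row["psa"]),
        psa_density=(
            float(clinical_row["psa_density"])
            if clinical_row.get("psa_density") is not None
            and not pd.isna(clinical_row.get("psa_density"))
            else None
        ),
        site=str(clinical_row.get("site", "") or ""),
        field_strength=float(fs) if fs is not None and not pd.isna(fs) else None,
        manufacturer=str(clinical_row.get("manufacturer", "") or ""),
    )
    cohort = clinical_row.get("cohort")
    return BpMriCase(
        case_id=case_id,
        volumes=volumes,
        clinical=clinical,
        label=int(clinical_row["label"]),
        gland_mask=mask,
        cohort=Cohort(cohort) if cohort else None,
    )


def read_clinical_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the clinical CSV (``case_id,age,psa,label[,site,field_strength,manufacturer]``)."""
    df = pd.read_csv(path, dtype={"case_id": str})
    required = {"case_id", "age", "psa", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    return df


def load_cohort(
    data_dir: str | os.PathLike,
    clinical_csv: Optional[str | os.PathLike] = None,
) -> list[BpMriCase]:
    """Load every case of an emitted cohort directory (see ``phantom.emit``)."""
    data_dir = Path(data_dir)
    clinical_csv = Path(clinical_csv) if clinical_csv else data_dir / "clinical.csv"
    table = read_clinical_table(clinical_csv)
    suffix = {
        SequenceKind.T2W: "t2w",
        SequenceKind.DWI_HIGH_B: "dwi",
        SequenceKind.ADC: "adc",
    }
    cases = []
    for _, row in table.iterrows():
        cid = row["case_id"]
        vol_paths = {k: data_dir / f"{cid}_{s}.nii" for k, s in suffix.items()}
        mask_path = data_dir / f"{cid}_mask.nii"
        cases.append(
            load_case(vol_paths, row.to_dict(), mask_path if mask_path.exists() else None)
        )
    return cases


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer cohort sizes summing exactly to n (largest-remainder rounding)."""
    raw = [n * f for f in fractions]
    counts = [math.floor(r) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def stratified_split(
    cases: Sequence[BpMriCase] | Sequence[tuple[str, int]],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    ratio_tolerance: float = 0.02,
) -> CohortSplit:
    """Deterministic class-stratified split into TRAIN/VAL/TEST_RETRO.

    Cases may be :class:`BpMriCase` objects or ``(case_id, label)`` pairs.
    Within each class, ids are shuffled with ``seed`` and allocated to
    cohorts by largest-remainder rounding, so cohort sizes sum exactly to N
    and each cohort's positive fraction stays within ``ratio_tolerance``
    (2 percentage points by default) of the global one whenever the counts
    make that arithmetically possible.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    pairs = [
        (c.case_id, c.label) if isinstance(c, BpMriCase) else (str(c[0]), int(c[1]))
        for c in cases
    ]
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for cid, label in pairs:
        by_class.setdefault(label, []).append(cid)
    for label in (0, 1):
        if not by_class[label]:
            raise ValueError(f"no cases with label {label}; cannot stratify")

    rng = np.random.default_rng(seed)
    cohorts = (Cohort.TRAIN, Cohort.VAL, Cohort.TEST_RETRO)
    members: dict[Cohort, list[str]] = {c: [] for c in cohorts}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        counts = _largest_remainder_counts(len(ids), fractions)
        start = 0
        for cohort, cnt in zip(cohorts, counts):
            members[cohort].extend(ids[start : start + cnt])
            start += cnt

    label_of = dict(pairs)
    counts_per: dict[Cohort, tuple[int, int]] = {}
    global_pos = sum(label_of[cid] for cid in label_of) / len(label_of)
    for cohort in cohorts:
        ids = members[cohort]
        pos = sum(label_of[cid] for cid in ids)
        counts_per[cohort] = (len(ids) - pos, pos)
        if ids:
            frac = pos / len(ids)
            # +1 case of slack: tiny cohorts cannot hit the ratio exactly
            slack = max(ratio_tolerance, 1.0 / len(ids))
            if abs(frac - global_pos) > slack + 1e-9:
                raise RuntimeError(
                    f"{cohort.value} positive fraction {frac:.3f} deviates from "
                    f"global {global_pos:.3f} by more than {slack:.3f}"
                )
    return CohortSplit(fractions=tuple(fractions), members=members, counts=counts_per)


def write_split_manifest(split: CohortSplit, path: str | os.PathLike) -> None:
    rows = [
        {"case_id": cid, "cohort": cohort.value}
        for cohort, ids in split.members.items()
        for cid in ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_split_manifest(path: str | os.PathLike) -> dict[str, Cohort]:
    df = pd.read_csv(path, dtype={"case_id": str})
    return {row.case_id: Cohort(row.cohort) for row in df.itertuples()}
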