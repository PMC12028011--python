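"""Synthetic bi-parametric MRI phantom cohorts.

Each case contains three aligned volumes sharing one gland ellipsoid. A
positive case carries a lesion with the canonical contrast signature:
darker than gland tissue on T2W, brighter on high-b DWI, darker on the ADC
map. Distractor nodules mimic that signature in exactly one modality, so a
classifier restricted to a single sequence is systematically misled while
the three sequences jointly separate the classes. Clinical variables are
correlated with the label through a PSA shift.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from bpfuse.data_model import (
    BpMriCase,
    ClinicalRecord,
    SequenceKind,
    SequenceVolume,
    save_volume,
    stratified_split,
    write_split_manifest,
)
from bpfuse.preprocessing import prostate_volume, psa_density

__all__ = ["PhantomConfig", "generate_cohort", "generate_case", "emit"]

SITES = ("site_a", "site_b", "site_c")
MANUFACTURERS = ("vendor_x", "vendor_y", "vendor_z")
FIELD_STRENGTHS = (1.5, 3.0)


@dataclass
class PhantomConfig:
    """Generative model of the phantom cohort.

    Lesion contrast effects are multiplicative factors relative to gland
    tissue and must carry the canonical signs: ``t2w_effect < 1`` (darker),
    ``dwi_effect > 1`` (brighter), ``adc_effect < 1`` (darker).
    """

    n_cases: int = 100
    prevalence: float = 0.5
    volume_shape: tuple[int, int, int] = (16, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    gland_semiaxes_mm: tuple[float, float, float] = (14.0, 20.0, 20.0)
    gland_jitter: float = 0.15
    lesion_radius_mm: tuple[float, float] = (4.0, 7.0)
    t2w_effect: float = 0.55
    dwi_effect: float = 1.9
    adc_effect: float = 0.5
    distractor_rate: float = 0.3  # per mimic type, per case
    noise_sigma: float = 0.04  # relative to each sequence's dynamic range
    psa_label_shift: float = 4.0  # ng/mL added for positive cases
    site_offset_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not self.t2w_effect < 1.0:
            raise ValueError("t2w_effect must be < 1 (lesions are T2W-hypointense)")
        if not self.dwi_effect > 1.0:
            raise ValueError("dwi_effect must be > 1 (lesions are DWI-hyperintense)")
        if not self.adc_effect < 1.0:
            raise ValueError("adc_effect must be < 1 (lesions have low ADC)")
        extents = [s * n / 2 for s, n in zip(self.spacing, self.volume_shape)]
        if any(a >= e for a, e in zip(self.gland_semiaxes_mm, extents)):
            raise ValueError(
                f"gland semi-axes {self.gland_semiaxes_mm} mm do not fit inside the "
                f"half-extents {extents} mm of the volume"
            )
        if self.lesion_radius_mm[1] >= min(self.gland_semiaxes_mm):
            raise ValueError("lesion larger than gland: impossible geometry")


# per-sequence arbitrary pre-normalization intensity scales (gland, background)
_BASE_INTENSITY = {
    SequenceKind.T2W: (520.0, 260.0),
    SequenceKind.DWI_HIGH_B: (90.0, 45.0),
    SequenceKind.ADC: (1600.0, 2100.0),
}


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return r2 <= 1.0


def generate_case(
    config: PhantomConfig,
    case_id: str,
    label: int,
    rng: np.random.Generator,
) -> BpMriCase:
    """Generate one case; deterministic given the generator state."""
    shape, spacing = config.volume_shape, config.spacing
    center_mm = np.array([s * n / 2 for s, n in zip(spacing, shape)])
    jit = rng.uniform(1 - config.gland_jitter, 1 + config.gland_jitter, size=3)
    semiaxes = np.asarray(config.gland_semiaxes_mm) * jit
    gland = _ellipsoid_mask(shape, spacing, center_mm, semiaxes)

    effects = {
        SequenceKind.T2W: config.t2w_effect,
        SequenceKind.DWI_HIGH_B: config.dwi_effect,
        SequenceKind.ADC: config.adc_effect,
    }

    def nodule(radius_range) -> np.ndarray:
        r = rng.uniform(*radius_range)
        # place the nodule center well inside the gland
        frac = rng.uniform(-0.5, 0.5, size=3)
        c = center_mm + frac * (semiaxes - r)
        return _ellipsoid_mask(shape, spacing, c, (r, r, r)) & gland

    lesion = nodule(config.lesion_radius_mm) if label == 1 else None
    # one potential mimic per modality, each visible in that modality only
    mimics = {
        kind: nodule(config.lesion_radius_mm)
        if rng.random() < config.distractor_rate
        else None
        for kind in SequenceKind
    }

    site_i = int(rng.integers(len(SITES)))
    site_factor = float(np.exp(rng.normal(0.0, config.site_offset_sigma)))
    field_strength = float(FIELD_STRENGTHS[int(rng.integers(len(FIELD_STRENGTHS)))])
    manufacturer = MANUFACTURERS[int(rng.integers(len(MANUFACTURERS)))]

    volumes = {}
    for kind in SequenceKind:
        gland_int, bg_int = _BASE_INTENSITY[kind]
        vox = np.full(shape, bg_int, dtype=np.float64)
        vox[gland] = gland_int
        if lesion is not None:
            vox[lesion] = gland_int * effects[kind]
        if mimics[kind] is not None:
            vox[mimics[kind]] = gland_int * effects[kind]
        vox *= site_factor
        scale = abs(gland_int - bg_int) if gland_int != bg_int else gland_int
        vox += rng.normal(0.0, config.noise_sigma * scale, size=shape)
        volumes[kind] = SequenceVolume(
            voxels=vox.astype(np.float32), spacing=spacing, kind=kind, case_id=case_id
        )

    gland_ml = prostate_volume(gland, spacing)
    age = float(np.clip(rng.normal(65.0, 8.0), 45.0, 88.0))
    psa = (
        1.0
        + 0.06 * gland_ml
        + 0.04 * (age - 50.0)
        + config.psa_label_shift * label
        + float(rng.lognormal(0.0, 0.35))
    )
    clinical = ClinicalRecord(
        age=age,
        psa=psa,
        psa_density=psa_density(psa, gland_ml),
        site=SITES[site_i],
        field_strength=field_strength,
        manufacturer=manufacturer,
    )
    return BpMriCase(
        case_id=case_id,
        volumes=volumes,
        clinical=clinical,
        label=label,
        gland_mask=gland.astype(np.uint8),
    )


def generate_cohort(config: PhantomConfig) -> tuple[list[BpMriCase], pd.DataFrame]:
    """Generate ``config.n_cases`` cases plus a ground-truth table.

    Labels are assigned to hit the configured prevalence exactly (rounded),
    in a shuffled order; everything is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.n_cases * config.prevalence))
    labels = np.array([1] * n_pos + [0] * (config.n_cases - n_pos))
    rng.shuffle(labels)
    cases = [
        generate_case(config, f"case_{i:04d}", int(labels[i]), rng)
        for i in range(config.n_cases)
    ]
    truth = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "label": [c.label for c in cases],
            "age": [c.clinical.age for c in cases],
            "psa": [c.clinical.psa for c in cases],
            "psa_density": [c.clinical.psa_density for c in cases],
            "site": [c.clinical.site for c in cases],
            "field_strength": [c.clinical.field_strength for c in cases],
            "manufacturer": [c.clinical.manufacturer for c in cases],
        }
    )
    return cases, truth


def emit(
    cases: list[BpMriCase],
    out_dir: str | os.PathLike,
    split_seed: Optional[int] = None,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> Path:
    """Write a cohort as NIfTI volumes + masks + clinical CSV (+ manifest).

    Layout: ``{case_id}_{t2w,dwi,adc,mask}.nii`` plus ``clinical.csv`` and,
    when ``split_seed`` is given, ``split.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = {
        SequenceKind.T2W: "t2w",
        SequenceKind.DWI_HIGH_B: "dwi",
        SequenceKind.ADC: "adc",
    }
    rows = []
    for case in cases:
        for kind, vol in case.volumes.items():
            save_volume(vol, out_dir / f"{case.case_id}_{suffix[kind]}.nii")
        if case.gland_mask is not None:
            mask_vol = SequenceVolume(
                voxels=case.gland_mask.astype(np.float32),
                spacing=case.volumes[SequenceKind.T2W].spacing,
                kind=SequenceKind.T2W,
                case_id=case.case_id,
            )
            save_volume(mask_vol, out_dir / f"{case.case_id}_mask.nii")
        c = case.clinical
        rows.append(
            {
                "case_id": case.case_id,
                "age": c.age,
                "psa": c.psa,
                "psa_density": c.psa_density,
                "label": case.label,
                "site": c.site,
                "field_strength": c.field_strength,
                "manufacturer": c.manufacturer,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "clinical.csv", index=False)
    if split_seed is not None:
        split = stratified_split(cases, fractions, seed=split_seed)
        write_split_manifest(split, out_dir / "split.csv")
    return out_dir
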