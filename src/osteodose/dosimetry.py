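"""Dose maps by kernel convolution and lesion/patient dose summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .grids import VoxelGrid
from .kernel import DoseKernel

__all__ = [
    "Lesion",
    "PatientDoseSummary",
    "compute_dose_map",
    "summarize_lesions",
    "summarize_patient",
]


def compute_dose_map(cumulated_map: VoxelGrid, kernel: DoseKernel) -> VoxelGrid:
    """Absorbed dose map (Gy) = cumulated activity (MBq·h) ⊛ voxel S-kernel.

    Linear (zero-padded) convolution via the frequency domain — no
    wrap-around — cropped back to the input shape.
    """
    if abs(cumulated_map.voxel_size_mm - kernel.voxel_size_mm) > 1e-3 * kernel.voxel_size_mm:
        raise ValueError(
            f"voxel size mismatch: map {cumulated_map.voxel_size_mm} mm vs "
            f"kernel {kernel.voxel_size_mm} mm"
        )
    dose = fftconvolve(cumulated_map.data, kernel.values, mode="same")
    return VoxelGrid(np.clip(dose, 0.0, None), cumulated_map.voxel_size_mm, unit="Gy")


@dataclass
class Lesion:
    """One segmented metastatic lesion with its dose statistics."""

    label: int
    volume_ml: float
    mean_dose_gy: float
    max_dose_gy: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("lesion volume must be > 0")
        if not 0 <= self.mean_dose_gy <= self.max_dose_gy:
            raise ValueError("need 0 <= mean dose <= max dose")


def summarize_lesions(
    dose_map: VoxelGrid, masks: list[np.ndarray], keep_masks: bool = False
) -> list[Lesion]:
    """Per-lesion volume and mean/max dose over the mask voxels."""
    if masks:
        overlap = np.sum([m.astype(int) for m in masks], axis=0)
        if overlap.max() > 1:
            raise ValueError("lesion masks overlap")
    lesions = []
    for i, mask in enumerate(masks):
        vals = dose_map.data[mask]
        lesions.append(
            Lesion(
                label=i + 1,
                volume_ml=float(mask.sum() * dose_map.voxel_volume_ml),
                mean_dose_gy=float(vals.mean()),
                max_dose_gy=float(vals.max()),
                mask=mask if keep_masks else None,
            )
        )
    return lesions


@dataclass
class PatientDoseSummary:
    """Patient-level dosimetry summary.

    PMAD (patient mean absorbed dose) is the *unweighted* mean of the
    individual lesion mean doses; disease volume is the sum of lesion
    volumes.  PMAD is NaN (flagged) when no lesions were identified.
    """

    lesions: list[Lesion]
    patient_mean_absorbed_dose_gy: float
    disease_volume_ml: float
    whole_body_dose_gy: float
    administered_mbq: float
    pmad_defined: bool = True
    patient_id: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "patient_id": self.patient_id,
            "administered_MBq": self.administered_mbq,
            "whole_body_dose_Gy": self.whole_body_dose_gy,
            "patient_mean_absorbed_dose_Gy": (
                self.patient_mean_absorbed_dose_gy if self.pmad_defined else None
            ),
            "disease_volume_ml": self.disease_volume_ml,
            "n_lesions": len(self.lesions),
            "lesions": [
                {
                    "label": l.label,
                    "volume_ml": l.volume_ml,
                    "mean_dose_Gy": l.mean_dose_gy,
                    "max_dose_Gy": l.max_dose_gy,
                }
                for l in self.lesions
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize_patient(
    lesions: list[Lesion],
    whole_body_dose_gy: float,
    administered_mbq: float,
    patient_id: str = "",
) -> PatientDoseSummary:
    """Combine lesion summaries into the patient-level record."""
    if lesions:
        pmad = float(np.mean([l.mean_dose_gy for l in lesions]))
        defined = True
    else:
        pmad = float("nan")
        defined = False
    return PatientDoseSummary(
        lesions=lesions,
        patient_mean_absorbed_dose_gy=pmad,
        disease_volume_ml=float(np.sum([l.volume_ml for l in lesions])) if lesions else 0.0,
        whole_body_dose_gy=whole_body_dose_gy,
        administered_mbq=administered_mbq,
        pmad_defined=defined,
        patient_id=patient_id,
    )


def cohort_dose_table(summaries: list[PatientDoseSummary]) -> pd.DataFrame:
    """Cohort-level CSV-ready table, one row per patient."""
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in summaries],
            "PMAD_Gy": [s.patient_mean_absorbed_dose_gy for s in summaries],
            "WBD_Gy": [s.whole_body_dose_gy for s in summaries],
            "disease_volume_ml": [s.disease_volume_ml for s in summaries],
            "n_lesions": [len(s.lesions) for s in summaries],
            "administered_MBq": [s.administered_mbq for s in summaries],
        }
    )
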