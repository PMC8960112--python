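"""Cohort I/O: NIfTI volumes plus a JSON manifest.

Disk layout written by :func:`save_cohort` (and by the phantom simulator)::

    <dir>/manifest.json            entity tree, clinical scalars, labels
    <dir>/<case>_img.nii           4D image, axes (x=col, y=row, z=slice, t=phase)
    <dir>/<case>_<session>.nii     one mask file per session

NIfTI axis order on disk is the nibabel-native ``(i, j, k, t)``; in memory
everything is ``(phase, slice, row, col)`` (see :mod:`cardioloop.datamodel`).
Uncompressed ``.nii`` is written so that reruns with identical inputs produce
byte-identical artifacts; ``.nii.gz`` is accepted on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .datamodel import (
    Case,
    CohortError,
    ImageVolume,
    LabelMask,
    Patient,
    Session,
    Study,
    iter_cases,
)

log = logging.getLogger(__name__)

MISSING = "NA"  # CSV missing-value token used across the package


def _to_disk_order(voxels: np.ndarray) -> np.ndarray:
    # (phase, slice, row, col) -> (col, row, slice, phase)
    return np.ascontiguousarray(np.transpose(voxels, (3, 2, 1, 0)))


def _from_disk_order(data: np.ndarray) -> np.ndarray:
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise CohortError(f"NIfTI data must be 3D or 4D, got shape {data.shape}")
    return np.transpose(data, (3, 2, 1, 0))


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    slice_mm, row_mm, col_mm = spacing
    return np.diag([col_mm, row_mm, slice_mm, 1.0])


def write_nifti(path: Path, voxels: np.ndarray, spacing: tuple[float, float, float]) -> None:
    if voxels.ndim == 3:  # static volume: single-phase axis
        voxels = voxels[None]
    img = nib.Nifti1Image(_to_disk_order(voxels), _affine(spacing))
    img.header.set_zooms((spacing[2], spacing[1], spacing[0], 1.0)[: voxels.ndim])
    nib.save(img, str(path))


def read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return _from_disk_order(np.asarray(img.dataobj)), spacing


def save_cohort(cohort: list[Patient], out_dir: str | Path) -> Path:
    """Write images, per-session masks and the manifest; return manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "cardioloop-cohort-v1", "patients": []}
    for patient in cohort:
        p_entry: dict = {"patient_id": patient.patient_id, "studies": []}
        for study in patient.studies:
            s_entry: dict = {"study_id": study.study_id, "cases": []}
            for case in study.cases:
                img = case.image
                img_file = f"{case.case_id}_img.nii"
                write_nifti(out / img_file, img.voxels.astype(np.float32), img.spacing)
                sessions = []
                for session in case.sessions:
                    mask_file = f"{case.case_id}_{session.session_id}.nii"
                    write_nifti(out / mask_file, session.mask.labels.astype(np.int16),
                                session.mask.spacing)
                    sessions.append({
                        "session_id": session.session_id,
                        "origin": session.origin,
                        "mask": mask_file,
                        "corrected_contours": [
                            [int(p), int(s), st, bool(v)]
                            for (p, s, st), v in sorted(session.per_contour_corrected.items())
                        ],
                    })
                s_entry["cases"].append({
                    "case_id": case.case_id,
                    "image": img_file,
                    "modality": img.modality,
                    "spacing_mm": list(img.spacing),
                    "clinical": case.clinical,
                    "class_label": case.class_label,
                    "annotations": case.annotations,
                    "sessions": sessions,
                })
            p_entry["studies"].append(s_entry)
        manifest["patients"].append(p_entry)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def load_cohort(manifest_path: str | Path, fail_fast: bool = True) -> list[Patient]:
    """Load a cohort from a manifest; validates shapes and label values.

    With ``fail_fast=False`` broken cases are skipped with a logged error
    instead of aborting the whole import.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    spec = json.loads(manifest_path.read_text())
    if spec.get("format") != "cardioloop-cohort-v1":
        raise CohortError(f"unrecognized manifest format in {manifest_path}")
    cohort: list[Patient] = []
    for p_entry in spec["patients"]:
        patient = Patient(patient_id=p_entry["patient_id"])
        for s_entry in p_entry["studies"]:
            study = Study(study_id=s_entry["study_id"])
            for c_entry in s_entry["cases"]:
                try:
                    study.cases.append(_load_case(base, c_entry))
                    log.info("loaded case %s", c_entry["case_id"])
                except (CohortError, FileNotFoundError) as exc:
                    log.error("case %s failed to load: %s", c_entry["case_id"], exc)
                    if fail_fast:
                        raise
            patient.studies.append(study)
        cohort.append(patient)
    return cohort


def _load_case(base: Path, entry: dict) -> Case:
    img_path = base / entry["image"]
    if not img_path.exists():
        raise FileNotFoundError(f"image file missing: {img_path}")
    voxels, spacing = read_nifti(img_path)
    image = ImageVolume(voxels=voxels, spacing=spacing, modality=entry.get("modality", "cine"))
    case = Case(
        case_id=entry["case_id"],
        images=[image],
        clinical=dict(entry.get("clinical") or {}),
        class_label=entry.get("class_label"),
        annotations=dict(entry.get("annotations") or {}),
    )
    for s_entry in entry.get("sessions", []):
        mask_path = base / s_entry["mask"]
        if not mask_path.exists():
            raise FileNotFoundError(f"mask file missing: {mask_path}")
        labels, mspacing = read_nifti(mask_path)
        mask = LabelMask(labels=np.rint(labels).astype(np.int16), spacing=mspacing)
        if mask.labels.shape != image.voxels.shape:
            raise CohortError(
                f"mask shape {mask.labels.shape} does not match image shape "
                f"{image.voxels.shape} for case {entry['case_id']}"
            )
        flags = {
            (int(p), int(s), st): bool(v)
            for p, s, st, v in s_entry.get("corrected_contours", [])
        }
        case.sessions.append(Session(
            session_id=s_entry["session_id"],
            case_id=case.case_id,
            mask=mask,
            origin=s_entry["origin"],
            per_contour_corrected=flags,
        ))
    return case


def cohort_summary(cohort: list[Patient]) -> dict:
    cases = list(iter_cases(cohort))
    return {
        "n_patients": len(cohort),
        "n_cases": len(cases),
        "n_sessions": sum(len(c.sessions) for c in cases),
        "class_counts": _class_counts(cases),
    }


def _class_counts(cases: list[Case]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for case in cases:
        key = case.class_label or MISSING
        counts[key] = counts.get(key, 0) + 1
    return counts
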