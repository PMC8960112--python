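"""Hierarchical cohort data model with segmentation-session provenance.

The entity tree mirrors the DICOM patient/study hierarchy: a :class:`Patient`
owns :class:`Study` objects, each study owns :class:`Case` objects, and every
case carries one or more image volumes plus any number of segmentation
:class:`Session` objects.  Sessions are append-only: a correction never
mutates an existing segmentation but adds a new session tagged with its
origin (``automatic``, ``manual`` or ``corrected``), so any derived feature
row can always be traced back to the exact mask that produced it.

Array convention
----------------
Voxel grids are indexed ``(phase, slice, row, col)``; static 3D data has a
phase axis of length 1.  ``spacing`` is ``(slice_mm, row_mm, col_mm)``.
Slice 0 is the most basal slice by file order; physical coordinates are
``index * spacing`` (0-based, no anatomical re-sorting).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

#: Fixed label convention (ACDC): other conventions are remapped on import.
LABELS: dict[int, str] = {
    0: "background",
    1: "rv_bloodpool",
    2: "lv_myocardium",
    3: "lv_bloodpool",
}
LABEL_IDS: dict[str, int] = {name: value for value, name in LABELS.items()}
#: Segmentable structures (everything except background).
STRUCTURES: tuple[str, ...] = ("rv_bloodpool", "lv_myocardium", "lv_bloodpool")

ORIGINS = ("automatic", "manual", "corrected")

class CohortError(ValueError):
    """Raised on invariant violations in the cohort entity tree."""


def _as_4d(array: np.ndarray) -> np.ndarray:
    arr = np.asarray(array)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise CohortError(f"expected a 3D or 4D grid, got shape {arr.shape}")
    return arr


@dataclass
class ImageVolume:
    """A 3D(+t) grayscale volume with physical spacing.

    ``voxels`` is ``(phase, slice, row, col)``; ``spacing`` is
    ``(slice_mm, row_mm, col_mm)`` and must be strictly positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "cine"

    def __post_init__(self) -> None:
        self.voxels = _as_4d(self.voxels)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise CohortError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.modality not in ("cine", "lge", "other"):
            raise CohortError(f"unknown modality tag {self.modality!r}")

    @property
    def phase_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Integer segmentation grid using the fixed ACDC label convention."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = _as_4d(self.labels).astype(np.int16, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise CohortError(f"spacing must be strictly positive, got {self.spacing}")
        unknown = set(np.unique(self.labels)) - set(LABELS)
        if unknown:
            raise CohortError(
                f"mask contains undeclared label value(s) {sorted(int(u) for u in unknown)}; "
                f"allowed: {sorted(LABELS)}"
            )

    @property
    def phase_count(self) -> int:
        return self.labels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def structure(self, name: str, phase: int | None = None) -> np.ndarray:
        """Boolean grid of one structure, full 4D or a single phase."""
        if name not in LABEL_IDS:
            raise CohortError(f"unknown structure {name!r}; allowed: {STRUCTURES}")
        grid = self.labels if phase is None else self.labels[phase]
        return grid == LABEL_IDS[name]

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.spacing)


@dataclass
class Session:
    """One segmentation result plus its provenance.

    ``per_contour_corrected`` maps ``(phase, slice, structure)`` triples to a
    boolean recording whether that individual contour was manually corrected.
    """

    session_id: str
    case_id: str
    mask: LabelMask
    origin: str
    per_contour_corrected: dict[tuple[int, int, str], bool] = field(default_factory=dict)
    certainty: np.ndarray | None = None
    landmarks: list | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise CohortError(f"origin must be one of {ORIGINS}, got {self.origin!r}")
        if self.origin == "corrected" and not any(self.per_contour_corrected.values()):
            raise CohortError("origin='corrected' requires at least one corrected contour flag")


@dataclass
class Case:
    case_id: str
    images: list[ImageVolume] = field(default_factory=list)
    clinical: dict[str, float] = field(default_factory=dict)
    class_label: str | None = None
    annotations: dict = field(default_factory=dict)
    sessions: list[Session] = field(default_factory=list)

    @property
    def image(self) -> ImageVolume:
        if not self.images:
            raise CohortError(f"case {self.case_id} has no images")
        return self.images[0]

    def latest_session(self) -> Session:
        if not self.sessions:
            raise CohortError(f"case {self.case_id} has no sessions")
        return self.sessions[-1]

    def session(self, session_id: str) -> Session:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise CohortError(f"case {self.case_id} has no session {session_id!r}")


@dataclass
class Study:
    study_id: str
    cases: list[Case] = field(default_factory=list)


@dataclass
class Patient:
    patient_id: str
    studies: list[Study] = field(default_factory=list)


def iter_cases(cohort: list[Patient]):
    """Yield every case of a cohort in deterministic (file) order."""
    for patient in cohort:
        for study in patient.studies:
            yield from study.cases


def find_case(cohort: list[Patient], case_id: str) -> Case:
    for case in iter_cases(cohort):
        if case.case_id == case_id:
            return case
    raise CohortError(f"unknown case id {case_id!r}")


def session_fingerprint(mask: LabelMask, origin: str, salt: str = "") -> str:
    """Content-addressed session id: hash of mask voxels, origin and a salt.

    The salt (the case id plus the session's position in the case) keeps ids
    collision-free even when an identical mask is re-added, e.g. as a no-op
    correction, while staying deterministic across reruns.
    """
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mask.labels).tobytes())
    h.update(origin.encode())
    h.update(salt.encode())
    return h.hexdigest()[:16]


def add_session(
    case: Case,
    mask: LabelMask,
    origin: str,
    per_contour_corrected: dict | None = None,
    certainty: np.ndarray | None = None,
) -> Session:
    """Append a new segmentation session to ``case`` (append-only).

    Rejects masks whose grid does not match any image of the case and masks
    containing undeclared label values (the latter is enforced by
    :class:`LabelMask` itself).
    """
    shapes = [img.voxels.shape for img in case.images]
    if case.images and mask.labels.shape not in shapes:
        raise CohortError(
            f"mask shape {mask.labels.shape} matches no image of case "
            f"{case.case_id} (image shapes: {shapes})"
        )
    salt = f"{case.case_id}:{len(case.sessions)}"
    session = Session(
        session_id=session_fingerprint(mask, origin, salt),
        case_id=case.case_id,
        mask=mask,
        origin=origin,
        per_contour_corrected=dict(per_contour_corrected or {}),
        certainty=certainty,
    )
    case.sessions.append(session)
    return session


def feature_row_id(case_id: str, session_id: str) -> str:
    """Row identifier emitted by the features module (case::session)."""
    return f"{case_id}::{session_id}"


def resolve_provenance(row_id: str, cohort: list[Patient]) -> tuple[str, str, str]:
    """Trace a feature-table row id back to ``(case_id, session_id, origin)``."""
    if "::" not in row_id:
        raise CohortError(f"malformed feature row id {row_id!r}")
    case_id, session_id = row_id.split("::", 1)
    case = find_case(cohort, case_id)
    session = case.session(session_id)
    return case.case_id, session.session_id, session.origin
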