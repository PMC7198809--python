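"""Cohort container and on-disk layout.

A cohort is a set of subjects with one registered scalar volume each, a
two-group label (healthy control vs patient) and, for patients, a clinical
severity score (ALSFRS-R-like; higher = milder disease). On disk a cohort is
a directory of per-subject NIfTI-1 files plus a ``participants.tsv`` table.

Label conventions
-----------------
Internally controls are +1 and patients are -1, so that a positive SVM
decision value reads directly as "control". The TSV ``group`` column uses
the clinical convention 1 = control, 2 = patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import CohortError, GeometryError
from .volumes import ScalarVolume

HC = 1
PATIENT = -1

#: TSV group codes (clinical convention)
GROUP_CODE = {HC: 1, PATIENT: 2}
LABEL_FROM_CODE = {1: HC, 2: PATIENT}

TSV_NAME = "participants.tsv"
TSV_COLUMNS = ("subject_id", "group", "clinical_score")


@dataclass(frozen=True)
class CohortDataset:
    """Aligned volumes, group labels and optional clinical scores.

    ``labels`` are +1 (control) / -1 (patient); ``clinical_scores`` holds a
    finite score for every patient and NaN for controls.
    """

    subject_ids: tuple[str, ...]
    volumes: tuple[ScalarVolume, ...]
    labels: np.ndarray
    clinical_scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "volumes", tuple(self.volumes))
        labels = np.asarray(self.labels, dtype=np.int64)
        scores = np.asarray(self.clinical_scores, dtype=np.float64)
        n = len(self.subject_ids)
        if not (len(self.volumes) == len(labels) == len(scores) == n):
            raise CohortError("subject_ids, volumes, labels and clinical_scores must align")
        if n == 0:
            raise CohortError("empty cohort")
        if len(set(self.subject_ids)) != n:
            raise CohortError("subject ids must be unique")
        if not np.isin(labels, (HC, PATIENT)).all():
            raise CohortError("labels must be +1 (control) or -1 (patient)")
        if not ((labels == HC).any() and (labels == PATIENT).any()):
            raise CohortError("cohort must contain both groups")
        first = self.volumes[0]
        for vol in self.volumes[1:]:
            if not first.same_grid(vol):
                raise GeometryError("cohort volumes are not on an identical grid")
        if np.isnan(scores[labels == PATIENT]).any():
            raise CohortError("every patient needs a clinical score")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "clinical_scores", scores)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_patients(self) -> int:
        return int((self.labels == PATIENT).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == HC).sum())

    def patient_scores(self) -> np.ndarray:
        return self.clinical_scores[self.labels == PATIENT]


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag((*voxel_size, 1.0))


def write_volume(volume: ScalarVolume, path: Path | str) -> None:
    """Write one volume as NIfTI-1, recording the grid in the affine."""
    affine = volume.affine if volume.affine is not None else _default_affine(volume.voxel_size)
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def read_volume(path: Path | str) -> ScalarVolume:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(values, voxel_size=voxel_size, affine=np.asarray(img.affine))


def write_cohort(dataset: CohortDataset, directory: Path | str) -> list[Path]:
    """Write one ``<subject_id>.nii.gz`` per subject plus ``participants.tsv``.

    Control rows carry an empty ``clinical_score`` field. Returns the list of
    written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, vol in zip(dataset.subject_ids, dataset.volumes):
        path = directory / f"{sid}.nii.gz"
        write_volume(vol, path)
        paths.append(path)
    table = pd.DataFrame(
        {
            "subject_id": dataset.subject_ids,
            "group": [GROUP_CODE[int(lab)] for lab in dataset.labels],
            "clinical_score": dataset.clinical_scores,
        }
    )
    tsv_path = directory / TSV_NAME
    table.to_csv(tsv_path, sep="\t", index=False, na_rep="")
    paths.append(tsv_path)
    return paths


def read_cohort(directory: Path | str) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort` (or laid out the same way)."""
    directory = Path(directory)
    tsv_path = directory / TSV_NAME
    if not tsv_path.exists():
        raise CohortError(f"missing {TSV_NAME} in {directory}")
    table = pd.read_csv(tsv_path, sep="\t", dtype={"subject_id": str})
    missing = set(TSV_COLUMNS) - set(table.columns)
    if missing:
        raise CohortError(f"{TSV_NAME} lacks columns: {sorted(missing)}")
    volumes = []
    for sid in table["subject_id"]:
        path = directory / f"{sid}.nii.gz"
        if not path.exists():
            path = directory / f"{sid}.nii"
        if not path.exists():
            raise CohortError(f"no volume found for subject {sid}")
        volumes.append(read_volume(path))
    labels = np.array([LABEL_FROM_CODE[int(code)] for code in table["group"]], dtype=np.int64)
    scores = table["clinical_score"].to_numpy(dtype=np.float64)
    return CohortDataset(
        subject_ids=tuple(table["subject_id"]),
        volumes=tuple(volumes),
        labels=labels,
        clinical_scores=scores,
    )
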