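"""File formats: NIfTI volumes, frame-timing sidecars, cohort manifests,
feature tables, and class-basis files.

Conventions:

* dynamic images are 4D NIfTI with the frame axis last, plus a CSV timing
  sidecar with columns ``start_s, duration_s`` (one row per frame);
* masks and atlases are 3D NIfTI (uint8 / int16);
* feature tables are TSV with ``subject_id`` and ``group`` first;
* the kinetic class basis is a CSV with one column per class and one row
  per frame, header = class names.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicPETImage, FrameSchedule
from .synthetic import KineticClassBasis, SyntheticSubject

__all__ = [
    "write_schedule", "read_schedule",
    "write_volume", "read_volume",
    "write_dynamic_image", "read_dynamic_image",
    "write_subject", "write_cohort", "read_cohort_manifest",
    "write_feature_table", "read_feature_table",
    "write_class_basis", "read_class_basis",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_schedule(schedule: FrameSchedule, path) -> Path:
    path = Path(path)
    pd.DataFrame({"start_s": schedule.start,
                  "duration_s": schedule.duration}).to_csv(path, index=False)
    return path


def read_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path)
    return FrameSchedule(df["start_s"].to_numpy(float),
                         df["duration_s"].to_numpy(float))


def write_volume(data: np.ndarray, path, voxel_size=(2.0, 2.0, 2.0),
                 dtype=None) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))
    return path


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_dynamic_image(img: DynamicPETImage, image_path, schedule_path) -> None:
    write_volume(img.data.astype(np.float32), image_path, img.voxel_size)
    write_schedule(img.schedule, schedule_path)


def read_dynamic_image(image_path, schedule_path,
                       voxel_size=(2.0, 2.0, 2.0)) -> DynamicPETImage:
    return DynamicPETImage(read_volume(image_path), read_schedule(schedule_path),
                           voxel_size)


def write_subject(subject: SyntheticSubject, out_dir) -> dict:
    """Write one subject's volumes and sidecars; return the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    vox = subject.dynamic_image.voxel_size
    paths = {
        "dynamic": out_dir / f"{sid}_dynamic.nii.gz",
        "schedule": out_dir / f"{sid}_frames.csv",
        "mask": out_dir / f"{sid}_mask.nii.gz",
        "atlas": out_dir / f"{sid}_atlas.nii.gz",
        "true_dvr": out_dir / f"{sid}_true_dvr.nii.gz",
    }
    write_dynamic_image(subject.dynamic_image, paths["dynamic"], paths["schedule"])
    write_volume(subject.brain_mask.astype(np.uint8), paths["mask"], vox)
    write_volume(subject.atlas.astype(np.int16), paths["atlas"], vox)
    write_volume(subject.true_dvr.astype(np.float32), paths["true_dvr"], vox)
    return {k: str(v) for k, v in paths.items()}


def write_cohort(subjects, out_dir) -> Path:
    """Write every subject plus a TSV manifest; return the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for sub in subjects:
        paths = write_subject(sub, out_dir)
        rows.append({"subject_id": sub.subject_id, "group": sub.label, **paths})
    manifest = out_dir / "cohort_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_class_basis(basis: KineticClassBasis, path) -> Path:
    path = Path(path)
    pd.DataFrame(basis.class_tacs.T, columns=list(basis.class_names)
                 ).to_csv(path, index=False)
    return path


def read_class_basis(path, schedule: FrameSchedule) -> KineticClassBasis:
    df = pd.read_csv(path)
    return KineticClassBasis(tuple(df.columns), df.to_numpy(float).T, schedule)
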