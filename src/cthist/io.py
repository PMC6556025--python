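"""Reading and writing volumes, masks, feature tables and clinical tables.

Volumes and masks travel as NIfTI-1 (``.nii``/``.nii.gz``) or NRRD
(``.nrrd``), both handled by SimpleITK.  Feature tables and clinical records
are plain UTF-8 CSV with a header row.  Degenerate feature values (NaN, e.g.
skewness of a constant ROI) are serialized as empty cells and reported via a
warning rather than dropping the subject.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import (
    ClinicalRecord,
    DimensionalityError,
    FormatError,
    GeometryError,
    ImageVolume,
    RoiMask,
    ValidationError,
)

log = logging.getLogger(__name__)

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _read_sitk(path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK wraps unreadable files in RuntimeError
        raise FormatError(f"could not read {path} as an image: {exc}") from exc


def _image_to_arrays(img: sitk.Image):
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3 or img.GetDimension() != 3:
        raise DimensionalityError(
            f"expected a 3-D volume, file holds a {arr.ndim}-D payload"
        )
    spacing = tuple(reversed(img.GetSpacing()))  # file order (x,y,z) -> (z,y,x)
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def read_volume(path) -> ImageVolume:
    """Read a 3-D HU volume with its header spacing.

    HU values are returned unchanged; spacing/origin come from the file
    header, reordered to the package's ``(z, y, x)`` axis convention.
    """
    arr, spacing, origin = _image_to_arrays(_read_sitk(path))
    return ImageVolume(arr, spacing, origin)


def write_volume(volume: ImageVolume, path) -> None:
    img = sitk.GetImageFromArray(np.asarray(volume.data))
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    sitk.WriteImage(img, str(path))


def read_mask(path, reference: ImageVolume | None = None) -> RoiMask:
    """Read a binary ROI mask; any nonzero label collapses to foreground.

    If ``reference`` is given the mask grid must match its shape exactly.
    An empty mask is legal here (it only becomes an error at feature
    extraction time) but triggers a warning.
    """
    arr, spacing, origin = _image_to_arrays(_read_sitk(path))
    mask = RoiMask(arr, spacing, origin)
    if reference is not None:
        mask.check_aligned(reference)
    if mask.foreground_count() == 0:
        warnings.warn(f"mask {path} has no foreground voxels", stacklevel=2)
    return mask


def write_mask(mask: RoiMask, path) -> None:
    img = sitk.GetImageFromArray(mask.data.astype(np.uint8))
    img.SetSpacing(tuple(reversed(mask.spacing)))
    img.SetOrigin(tuple(reversed(mask.origin)))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# feature / clinical tables


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a subjects x features table to CSV.

    The table must carry ``subject_id`` and ``group`` columns and at least
    one feature column; duplicate subject ids are rejected.  NaN values are
    written as empty cells (and logged), never dropped.
    """
    if table.empty:
        raise ValidationError("refusing to write an empty feature table")
    for col in ("subject_id", "group"):
        if col not in table.columns:
            raise ValidationError(f"feature table must have a {col!r} column")
    dup = table["subject_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate subject_id values: {sorted(table.loc[dup, 'subject_id'])}"
        )
    n_nan = int(table.isna().sum().sum())
    if n_nan:
        rows = table.index[table.isna().any(axis=1)]
        log.warning(
            "feature table contains %d NaN value(s) (subjects %s); "
            "serialized as empty cells",
            n_nan,
            list(table.loc[rows, "subject_id"]),
        )
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"feature table {path} lacks a {col!r} column")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_clinical_table(records: list[ClinicalRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group.value,
            "age": r.age,
            "sex": r.sex,
            "smoking": r.smoking,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    return [
        ClinicalRecord(
            subject_id=str(r.subject_id),
            group=r.group,
            age=float(r.age),
            sex=str(r.sex),
            smoking=str(r.smoking),
        )
        for r in df.itertuples()
    ]
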