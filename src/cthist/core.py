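"""Core in-memory containers and error types.

Axis convention
---------------
All 3-D arrays are indexed ``(z, y, x)`` — slowest axis first, matching the
array layout SimpleITK hands back.  ``spacing`` and ``origin`` triples are
stored in the *same order as the array axes*, i.e. ``spacing[0]`` is the
physical step (mm) along array axis 0.  The origin is carried through I/O for
provenance but no feature computation depends on it; every feature depends on
intensities and spacing only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class CthistError(Exception):
    """Base class for package errors."""


class FormatError(CthistError):
    """File exists but is not a readable volume/mask format."""


class DimensionalityError(CthistError):
    """Payload is not a 3-D scalar volume."""


class GeometryError(CthistError):
    """Mask and volume grids do not align."""


class ValidationError(CthistError):
    """Input violates a documented precondition."""


class ExtractionError(CthistError):
    """Feature extraction is impossible (e.g. empty ROI)."""


def _as_triple(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValidationError(f"expected a length-3 triple, got {v!r}")
    return t


@dataclass
class ImageVolume:
    """A 3-D scalar grid of Hounsfield units with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU intensities.
    spacing : triple of float
        Voxel edge lengths in mm, per array axis, all strictly positive.
    origin : triple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume must be 3-D, got {self.data.ndim}-D payload"
            )
        if min(self.data.shape) < 1:
            raise ValidationError("every volume dimension must be >= 1")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive: {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")


@dataclass
class RoiMask:
    """Binary lesion mask aligned voxel-for-voxel with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError(f"mask must be 3-D, got {arr.ndim}-D payload")
        # any nonzero label collapses to foreground
        self.data = (arr != 0)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive: {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.data.shape != volume.data.shape:
            raise GeometryError(
                f"mask shape {self.data.shape} does not match volume shape "
                f"{volume.data.shape}"
            )


class Group(str, Enum):
    """EGFR mutation status of the lesion."""

    EGFR_POS = "EGFR_POS"
    EGFR_NEG = "EGFR_NEG"


@dataclass
class ClinicalRecord:
    """Per-subject clinical covariates (Table-1 style)."""

    subject_id: str
    group: Group
    age: float
    sex: str  # "M" | "F"
    smoking: str  # "ever" | "never"

    def __post_init__(self):
        self.group = Group(self.group)
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.smoking not in ("ever", "never"):
            raise ValidationError(f"smoking must be 'ever'/'never', got {self.smoking!r}")
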