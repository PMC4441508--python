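"""Canonical in-memory CT volume container and coordinate conventions.

Conventions used by every module in this package:

* ``voxels`` is a 3D array indexed ``[i, j, k]`` with axis 2 the craniocaudal
  axis: slice index ``k`` increases from cranial to caudal.
* World coordinates are in millimetres. Slice ``k`` spans the half-open
  interval ``[k*dz, (k+1)*dz)`` relative to the origin, so the centre of
  voxel ``(i, j, k)`` is at ``origin + (index + 0.5) * spacing``.
* Intensities are in Hounsfield Units with any rescale already applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIAL_AXIS = 2


@dataclass
class CTVolume:
    """A 3D CT scalar field in Hounsfield Units on a regular anisotropic grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axial_axis_index: int = AXIAL_AXIS

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        if self.axial_axis_index != AXIAL_AXIS:
            raise ValueError("volumes must be in canonical orientation (axial axis = 2)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_mm(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel centres for fractional indices."""
        index = np.asarray(index, dtype=float)
        return (index + 0.5) * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a world point (inverse of :meth:`index_to_mm`)."""
        point_mm = np.asarray(point_mm, dtype=float)
        return (point_mm - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5

    def slice_positions_mm(self) -> np.ndarray:
        """Craniocaudal world coordinate of every axial slice centre."""
        k = np.arange(self.shape[2])
        return (k + 0.5) * self.spacing[2] + self.origin[2]


@dataclass
class SeedPoint:
    """A segmentation seed in voxel coordinates, labelled by chamber ('RV'/'LV')."""

    position: tuple[float, float, float]
    chamber: str

    def __post_init__(self) -> None:
        if self.chamber not in ("RV", "LV"):
            raise ValueError(f"chamber must be 'RV' or 'LV', got {self.chamber!r}")
        self.position = tuple(float(p) for p in self.position)


@dataclass
class SeptumPlane:
    """Interventricular septum model: a plane in mm space, normal oriented RV -> LV."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    score: float
    scale_mm: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("septum normal must be a nonzero vector")
        self.normal = tuple(n / norm)
        self.point = tuple(float(p) for p in self.point)
        if self.score < 0:
            raise ValueError("planarity score must be >= 0")

    def signed_distance_mm(self, points_mm) -> np.ndarray:
        """Signed distance of points to the plane; positive on the LV side."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.point)) @ np.asarray(self.normal)

    def inplane_direction(self) -> np.ndarray:
        """Unit in-plane (axial) projection of the normal: the caliper direction."""
        n = np.asarray(self.normal)
        u = np.array([n[0], n[1], 0.0])
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            raise ValueError("septum normal is purely craniocaudal; "
                             "axial measurement direction is undefined")
        return u / norm


@dataclass
class ChamberMask:
    """Binary segmentation of one chamber on the volume grid."""

    mask: np.ndarray
    chamber: str
    converged: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.chamber not in ("RV", "LV"):
            raise ValueError(f"chamber must be 'RV' or 'LV', got {self.chamber!r}")


@dataclass
class Caliper:
    """A diameter measurement segment within one axial slice."""

    slice_index: int
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]
    length_mm: float
    chamber: str

    def __post_init__(self) -> None:
        p0, p1 = (np.asarray(e, dtype=float) for e in self.endpoints)
        if abs(p0[2] - p1[2]) > 1e-6:
            raise ValueError("caliper endpoints must lie in the same axial slice")
        d = float(np.linalg.norm(p1 - p0))
        if abs(d - self.length_mm) > 1e-6:
            raise ValueError("length_mm inconsistent with endpoint distance")


FLAG_LOW_RV_CONTRAST = "low_rv_contrast"
FLAG_DETECTION_FAILED_RV = "detection_failed_rv"
FLAG_DETECTION_FAILED_LV = "detection_failed_lv"
FLAG_SEPTUM_LOW_CONFIDENCE = "septum_low_confidence"
FLAG_CALIPER_SUSPECT = "caliper_out_of_ventricle_suspect"
FLAG_SEGMENTATION_NOT_CONVERGED = "segmentation_not_converged"

ALL_FLAGS = (
    FLAG_LOW_RV_CONTRAST,
    FLAG_DETECTION_FAILED_RV,
    FLAG_DETECTION_FAILED_LV,
    FLAG_SEPTUM_LOW_CONFIDENCE,
    FLAG_CALIPER_SUSPECT,
    FLAG_SEGMENTATION_NOT_CONVERGED,
)


@dataclass
class CaseReport:
    """Reviewable output of one case: calipers, ratio and quality flags."""

    rv_caliper: Caliper | None = None
    lv_caliper: Caliper | None = None
    ratio: float | None = None
    flags: set = field(default_factory=set)
    timings_s: dict = field(default_factory=dict)
    septum: SeptumPlane | None = None

    def __post_init__(self) -> None:
        both = self.rv_caliper is not None and self.lv_caliper is not None
        if (self.ratio is not None) != both:
            raise ValueError("ratio must be present exactly when both calipers are")
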