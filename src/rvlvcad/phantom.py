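"""Synthetic cardiac-CTPA phantoms with analytically known geometry.

The generator emulates the features of a contrast-enhanced chest CT that the
measurement pipeline depends on: two bright, roughly ellipsoidal ventricular
blood pools separated by a darker myocardial/septal slab, atrial bulges
attached cranially to each ventricle with the same blood-pool attenuation
(so there is no intensity edge at the atrioventricular valve), surrounding
soft tissue and lung, anisotropic voxel spacing, a small point-spread blur
and additive Gaussian noise. The septum may be rotated arbitrarily in-plane.

Ground truth (chamber masks, septum plane, per-chamber maximal axial diameter
perpendicular to the septum, and their ratio) is computed in closed form from
the noiseless geometry, never from the rendered voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage

from .core import CTVolume


class GeometryError(ValueError):
    """Raised when a phantom specification places the chambers impossibly."""


@dataclass
class PhantomSpec:
    """Declarative description of one phantom.

    Lengths are in mm, intensities in HU. ``septum_normal_angle`` is the
    in-plane rotation (degrees) of the septum normal about the craniocaudal
    axis; the normal is oriented RV -> LV. ``atrium_scale`` scales the atrial
    bulges (0 disables them). Default attenuations: ventricular pools 350/320
    HU (RV/LV), septum/myocardium 60 HU, soft tissue 40 HU, lung -800 HU.
    """

    rv_semi_axes: tuple[float, float, float] = (18.0, 15.0, 23.0)
    lv_semi_axes: tuple[float, float, float] = (16.0, 14.0, 22.0)
    chamber_separation: float = 4.0
    septum_normal_angle: float = 20.0
    septum_hu: float = 60.0
    rv_pool_hu: float = 350.0
    lv_pool_hu: float = 320.0
    background_hu: float = 40.0
    lung_hu: float = -800.0
    atrium_scale: float = 0.8
    noise_sigma: float = 5.0
    spacing: tuple[float, float, float] = (0.7, 0.7, 1.0)
    volume_shape: tuple[int, int, int] = (176, 176, 72)
    rng_seed: int = 0
    blur_sigma_voxels: float = 1.0

    def __post_init__(self) -> None:
        self.rv_semi_axes = tuple(float(v) for v in self.rv_semi_axes)
        self.lv_semi_axes = tuple(float(v) for v in self.lv_semi_axes)
        self.spacing = tuple(float(v) for v in self.spacing)
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        self.validate()

    def validate(self) -> None:
        if any(a <= 0 for a in self.rv_semi_axes + self.lv_semi_axes):
            raise ValueError("all semi-axes must be > 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.atrium_scale < 0:
            raise ValueError("atrium_scale must be >= 0")
        if self.chamber_separation <= 0:
            raise GeometryError(
                "chamber_separation must be > 0: ellipsoids would overlap "
                f"(separation {self.chamber_separation} mm)")

    @property
    def is_degraded(self) -> bool:
        """True for deliberate failure phantoms (pools not brighter than septum,
        or pool attenuation below the clinical contrast floor)."""
        return (self.rv_pool_hu <= self.septum_hu or self.lv_pool_hu <= self.septum_hu
                or self.rv_pool_hu < 150.0)

    # -- plain-text config round trip -------------------------------------
    def to_config(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(float(x)) if isinstance(x, float) else str(x)
                             for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "PhantomSpec":
        kwargs = {}
        tuple_fields = {"rv_semi_axes", "lv_semi_axes", "spacing", "volume_shape"}
        int_fields = {"rng_seed"}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in tuple_fields:
                parts = [float(p) for p in value.split(",")]
                kwargs[key] = tuple(int(p) if key == "volume_shape" else p
                                    for p in parts)
            elif key in int_fields:
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class PhantomTruth:
    """Analytic ground truth for a phantom: everything the pipeline estimates."""

    septum_point: np.ndarray
    septum_normal: np.ndarray
    rv_center: np.ndarray
    lv_center: np.ndarray
    rv_axial_diameter_mm: float
    lv_axial_diameter_mm: float
    true_ratio: float
    rv_mask: np.ndarray
    lv_mask: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)


def _septum_frame(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """In-plane septum normal (RV -> LV) and in-plane perpendicular."""
    th = math.radians(angle_deg)
    n = np.array([math.cos(th), math.sin(th), 0.0])
    t = np.array([-math.sin(th), math.cos(th), 0.0])
    return n, t


def _ellipsoid_quadratic(points_delta, n, t, semi_axes):
    """Quadratic form value of points (relative to centre) for an ellipsoid
    with principal axes (n, t, z) and the given semi-axes; <= 1 is inside."""
    dx, dy, dz = points_delta
    a, b, c = semi_axes
    un = dx * n[0] + dy * n[1]
    ut = dx * t[0] + dy * t[1]
    return (un / a) ** 2 + (ut / b) ** 2 + (dz / c) ** 2


def ground_truth_axial_diameter(semi_axes, center, septum_normal,
                                slice_positions) -> float:
    """Maximal axial chord of an ellipsoidal chamber perpendicular to the septum.

    The chamber is an ellipsoid whose principal axes are the in-plane septum
    normal, the in-plane perpendicular, and the craniocaudal axis. For each
    axial slice through the ellipsoid the cross-section is an ellipse; its
    maximal chord along the in-plane septum normal follows in closed form
    from the ellipse quadratic (chord = 2*sqrt(k / u' A u) with k the Schur
    complement of the slice offset). Returns the maximum over the slices.
    """
    center = np.asarray(center, dtype=float)
    nrm = np.asarray(septum_normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    u2 = nrm[:2]
    u2_norm = np.linalg.norm(u2)
    if u2_norm < 1e-9:
        raise ValueError("septum normal is parallel to the craniocaudal axis; "
                         "the axial measurement direction is undefined")
    u2 = u2 / u2_norm
    n3 = np.array([u2[0], u2[1], 0.0])
    t3 = np.array([-u2[1], u2[0], 0.0])
    z3 = np.array([0.0, 0.0, 1.0])
    R = np.column_stack([n3, t3, z3])
    a, b, c = (float(s) for s in semi_axes)
    A = R @ np.diag([1.0 / a**2, 1.0 / b**2, 1.0 / c**2]) @ R.T
    A2 = A[:2, :2]
    bvec = A[:2, 2]
    q33 = A[2, 2]
    schur = q33 - bvec @ np.linalg.solve(A2, bvec)
    denom = u2 @ A2 @ u2
    best = 0.0
    for z0 in np.atleast_1d(slice_positions):
        d = float(z0) - center[2]
        k = 1.0 - d * d * schur
        if k <= 0:
            continue
        best = max(best, 2.0 * math.sqrt(k / denom))
    if best == 0.0:
        raise ValueError("no axial slice intersects the chamber")
    return best


def _chamber_geometry(spec: PhantomSpec):
    """Centres and frames of both chambers and their atria, in mm."""
    n, t = _septum_frame(spec.septum_normal_angle)
    shape = np.asarray(spec.volume_shape)
    spacing = np.asarray(spec.spacing)
    mid = shape * spacing / 2.0
    sep = spec.chamber_separation
    rv_c = mid - n * (sep / 2.0 + spec.rv_semi_axes[0])
    lv_c = mid + n * (sep / 2.0 + spec.lv_semi_axes[0])
    atria = []
    if spec.atrium_scale > 0:
        for cham_c, semi, away in ((rv_c, spec.rv_semi_axes, -n),
                                   (lv_c, spec.lv_semi_axes, +n)):
            a, b, c = semi
            at_c = cham_c + away * (0.4 * a) + np.array([0, 0, -0.7 * c])
            at_semi = (0.85 * a * spec.atrium_scale,
                       0.85 * b * spec.atrium_scale,
                       0.5 * c * spec.atrium_scale)
            atria.append((at_c, at_semi))
    return n, t, mid, rv_c, lv_c, atria


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom volume and its analytic ground truth.

    The volume is painted region-by-region (lung, mediastinal soft tissue,
    myocardium, atrial pools, ventricular pools), blurred by a Gaussian
    point-spread kernel of ``blur_sigma_voxels`` and corrupted by zero-mean
    Gaussian noise seeded by ``rng_seed``. Identical specs give bit-identical
    volumes. The ground truth is computed from the noiseless geometry.
    """
    spec.validate()
    n, t, mid, rv_c, lv_c, atria = _chamber_geometry(spec)
    spacing = np.asarray(spec.spacing)
    nx, ny, nz = spec.volume_shape

    xs = (np.arange(nx) + 0.5) * spacing[0]
    ys = (np.arange(ny) + 0.5) * spacing[1]
    zs = (np.arange(nz) + 0.5) * spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    wall = max(4.0, spec.chamber_separation)

    def quad(center, semi):
        return _ellipsoid_quadratic((X - center[0], Y - center[1], Z - center[2]),
                                    n, t, semi)

    def expanded(semi):
        return tuple(s + wall for s in semi)

    vol = np.full(spec.volume_shape, spec.lung_hu, dtype=np.float64)

    # mediastinal soft tissue: in-plane ellipse around the whole heart, all z
    reach_n = spec.chamber_separation / 2 + 2 * max(spec.rv_semi_axes[0],
                                                    spec.lv_semi_axes[0]) + wall + 12
    reach_t = max(spec.rv_semi_axes[1], spec.lv_semi_axes[1]) + wall + 12
    dn = (X - mid[0]) * n[0] + (Y - mid[1]) * n[1]
    dt = (X - mid[0]) * t[0] + (Y - mid[1]) * t[1]
    vol[(dn / reach_n) ** 2 + (dt / reach_t) ** 2 <= 1.0] = spec.background_hu

    # myocardium: chamber (and atrial) ellipsoids expanded by the wall thickness
    myo = quad(rv_c, expanded(spec.rv_semi_axes)) <= 1.0
    myo |= quad(lv_c, expanded(spec.lv_semi_axes)) <= 1.0
    for at_c, at_semi in atria:
        myo |= (quad(at_c, expanded(at_semi)) <= 1.0) & (Z <= at_c[2])
    vol[myo] = spec.septum_hu

    # atrial pools (cranial half-ellipsoids, continuous with the ventricle pools)
    for (at_c, at_semi), hu in zip(atria, (spec.rv_pool_hu, spec.lv_pool_hu)):
        vol[(quad(at_c, at_semi) <= 1.0) & (Z <= at_c[2])] = hu

    # ventricular pools
    rv_mask = quad(rv_c, spec.rv_semi_axes) <= 1.0
    lv_mask = quad(lv_c, spec.lv_semi_axes) <= 1.0
    if np.any(rv_mask & lv_mask):
        raise GeometryError("RV and LV ellipsoids overlap after placement")
    vol[rv_mask] = spec.rv_pool_hu
    vol[lv_mask] = spec.lv_pool_hu

    if spec.blur_sigma_voxels > 0:
        vol = ndimage.gaussian_filter(vol, sigma=spec.blur_sigma_voxels)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    volume = CTVolume(vol.astype(np.float32), spec.spacing)

    rv_d = ground_truth_axial_diameter(spec.rv_semi_axes, rv_c, n, zs)
    lv_d = ground_truth_axial_diameter(spec.lv_semi_axes, lv_c, n, zs)
    truth = PhantomTruth(
        septum_point=mid.copy(),
        septum_normal=n.copy(),
        rv_center=rv_c,
        lv_center=lv_c,
        rv_axial_diameter_mm=rv_d,
        lv_axial_diameter_mm=lv_d,
        true_ratio=rv_d / lv_d,
        rv_mask=rv_mask,
        lv_mask=lv_mask,
        spec=spec,
    )
    return volume, truth


def truth_slice_box(mask: np.ndarray, slice_index: int):
    """Axis-aligned bounding box (x0, y0, x1, y1, inclusive voxel coords) of a
    chamber mask within one axial slice, or None if the slice is empty."""
    sl = mask[:, :, slice_index]
    if not sl.any():
        return None
    xs, ys = np.nonzero(sl)
    return (int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))


# ---------------------------------------------------------------------------
# Named phantom suites
# ---------------------------------------------------------------------------

def acceptance_suite_specs() -> list[PhantomSpec]:
    """The frozen 40-phantom validation suite.

    20 noiseless phantoms plus 10 at 10 HU and 10 at 20 HU noise, spanning
    RV/LV ratios 0.7-1.8, septum angles 0-45 degrees and both small and
    enlarged atria. Seeds are fixed; the suite is identical on every call.
    """
    specs = []
    angles = [0.0, 15.0, 30.0, 45.0]
    lv = (14.0, 12.0, 22.0)

    def make(i, ratio, noise):
        rv_a = ratio * lv[0]
        rv = (rv_a, 0.85 * rv_a, 22.0 + 2.0 * (i % 3 - 1))
        return PhantomSpec(
            rv_semi_axes=rv, lv_semi_axes=lv,
            septum_normal_angle=angles[i % 4],
            atrium_scale=0.7 if i % 2 == 0 else 1.0,
            noise_sigma=noise,
            rng_seed=100 + i,
        )

    i = 0
    for ratio in np.linspace(0.7, 1.8, 20):
        specs.append(make(i, float(ratio), 0.0))
        i += 1
    for ratio in np.linspace(0.7, 1.8, 10):
        specs.append(make(i, float(ratio), 10.0))
        i += 1
    for ratio in np.linspace(0.75, 1.75, 10):
        specs.append(make(i, float(ratio), 20.0))
        i += 1
    return specs


def training_suite_specs() -> list[PhantomSpec]:
    """Phantoms used to train the slice detector (disjoint seeds from the
    acceptance suite; heart size, ratio, rotation and noise all vary so the
    detector generalizes across subjects)."""
    specs = []
    lv_sizes = [12.0, 14.0, 16.0]
    # contrast-bolus timing varies the RV enhancement heavily in practice;
    # the detector must find the chamber across that range (the 150 HU
    # quality gate is applied downstream, not by the detector)
    rv_pools = [350.0, 240.0, 120.0]
    for i, ratio in enumerate([0.8, 1.0, 1.15, 1.3, 1.5, 1.7]):
        for j, angle in enumerate([0.0, 22.5, 45.0]):
            la = lv_sizes[(i + j) % 3]
            rv_a = ratio * la
            specs.append(PhantomSpec(
                rv_semi_axes=(rv_a, 0.85 * rv_a, 23.0),
                lv_semi_axes=(la, 0.85 * la, 22.0),
                septum_normal_angle=angle,
                atrium_scale=0.7 if (i + j) % 2 == 0 else 1.0,
                noise_sigma=[0.0, 10.0, 18.0][j],
                rv_pool_hu=rv_pools[i % 3],
                rng_seed=1000 + 10 * i + j,
            ))
    return specs


def failure_phantom_spec(kind: str) -> PhantomSpec:
    """Deliberately degraded phantoms reproducing the pipeline's failure modes.

    ``low_rv_contrast``: RV pool at 100 HU, below the 150 HU mean-attenuation
    floor. ``no_septum_contrast``: septum at the pool attenuation, so no
    plate-like structure exists between the chambers.
    """
    if kind == "low_rv_contrast":
        return PhantomSpec(rv_pool_hu=100.0, noise_sigma=5.0, rng_seed=77)
    if kind == "no_septum_contrast":
        return PhantomSpec(septum_hu=335.0, noise_sigma=5.0, rng_seed=78)
    raise ValueError(f"unknown failure phantom kind {kind!r}")
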