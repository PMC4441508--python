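"""Caliper positioning and RV/LV ratio estimation from chamber masks.

Per axial slice, the chamber diameter is the longest chord of the
segmentation along the in-plane direction perpendicular to the estimated
septum (i.e. along the in-plane projection of the septum normal), measured
with sub-voxel precision by scanning interpolated mask profiles at
quarter-voxel offsets.

Because the blood pool is continuous across the atrioventricular valve, the
segmentation can include part of the atrium. Atrial slices are recognized
from the shape of the segmentation: a 10th-order polynomial is fitted to the
radial contour profile of each slice and its derivative roots are analyzed
for a significant concave notch (the ventricle/atrium junction), and the
craniocaudal trend of caliper lengths (which is exactly quadratic in length
squared for an ellipsoidal chamber) flags slices that depart from it. Only
calipers between the valve cutoff and the apex (the most caudal non-empty
slice) compete; the chamber diameter is the maximum of those calipers and
the ratio is the division of the two maxima, which may come from different
slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (FLAG_DETECTION_FAILED_LV, FLAG_DETECTION_FAILED_RV,
                   Caliper, SeptumPlane)

POLY_DEGREE = 10
SCAN_STEP_VOXELS = 0.25


# ---------------------------------------------------------------------------
# Per-slice chord measurement
# ---------------------------------------------------------------------------

def _longest_run(row: np.ndarray, threshold: float = 0.5):
    """(start, stop) sample indices of the longest run >= threshold, or None."""
    above = row >= threshold
    if not above.any():
        return None
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, stops = edges[::2], edges[1::2]
    i = int(np.argmax(stops - starts))
    return int(starts[i]), int(stops[i])


def _refine_crossing(vals, idx_in, idx_out, threshold=0.5):
    """Sub-sample position of the 0.5 crossing between two sample indices."""
    v_in, v_out = vals[idx_in], vals[idx_out]
    if v_in == v_out:
        return float(idx_in)
    t = (threshold - v_out) / (v_in - v_out)
    return idx_out + t * (idx_in - idx_out)


def slice_caliper(mask_slice: np.ndarray, septum: SeptumPlane, spacing,
                  slice_z: float, chamber: str,
                  origin_xy=(0.0, 0.0)) -> Caliper | None:
    """Longest chord of a slice mask along the in-plane septum normal.

    Scan lines are laid perpendicular to the measurement direction at
    quarter-voxel offsets; the mask is bilinearly interpolated along each
    line and the chord endpoints refined to the 0.5 iso-level. Returns None
    for an empty slice. Raises if the septum normal is purely craniocaudal.
    """
    u3 = septum.inplane_direction()
    u = u3[:2]
    t = np.array([-u[1], u[0]])
    mask = np.asarray(mask_slice, dtype=np.float32)
    if not (mask > 0.5).any():
        return None
    dx, dy = float(spacing[0]), float(spacing[1])
    xs, ys = np.nonzero(mask > 0.5)
    pts_mm = np.stack([(xs + 0.5) * dx, (ys + 0.5) * dy], axis=1)
    center = pts_mm.mean(axis=0)
    radius = float(np.linalg.norm(pts_mm - center, axis=1).max()) + 2.0

    step = SCAN_STEP_VOXELS * min(dx, dy)
    s = np.arange(-radius, radius + step, step)   # along measurement direction
    w = np.arange(-radius, radius + step, step)   # scan-line offsets
    S, W = np.meshgrid(s, w, indexing="xy")
    px = center[0] + S * u[0] + W * t[0]
    py = center[1] + S * u[1] + W * t[1]
    coords = np.stack([px / dx - 0.5, py / dy - 0.5])
    vals = ndimage.map_coordinates(mask, coords, order=1, mode="constant")

    best_len, best = -1.0, None
    for row_idx in range(vals.shape[0]):
        run = _longest_run(vals[row_idx])
        if run is None:
            continue
        start, stop = run
        if stop - start > best_len:
            best_len = stop - start
            best = (row_idx, start, stop)
    if best is None:
        return None
    row_idx, start, stop = best
    row = vals[row_idx]
    left = _refine_crossing(row, start, start - 1) if start > 0 else float(start)
    right = (_refine_crossing(row, stop - 1, stop) if stop < len(s)
             else float(stop - 1))
    w_off = w[row_idx]

    def endpoint(si):
        sv = np.interp(si, np.arange(len(s)), s)
        p = center + sv * u + w_off * t
        return (p[0] + origin_xy[0], p[1] + origin_xy[1], float(slice_z))

    p0, p1 = endpoint(left), endpoint(right)
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    k = int(round(slice_z))  # caller overwrites below when it knows the index
    return Caliper(slice_index=k, endpoints=(p0, p1), length_mm=length,
                   chamber=chamber)


# ---------------------------------------------------------------------------
# Contour profile and its 10th-order polynomial
# ---------------------------------------------------------------------------

@dataclass
class ContourProfile:
    """Radial contour profile of one slice and its polynomial fit.

    The degree-10 polynomial is fitted by least squares over the normalized
    angle ``x = theta / pi - 1`` in [-1, 1) (plain Vandermonde would be badly
    conditioned over [0, 2*pi)); ``coeffs`` are in increasing-power order of
    ``x``.
    """

    slice_index: int
    angles: np.ndarray
    radii_mm: np.ndarray
    coeffs: np.ndarray
    residual_rms_mm: float
    centroid_mm: tuple[float, float]

    @property
    def mean_radius_mm(self) -> float:
        return float(self.radii_mm.mean())

    def evaluate(self, angles) -> np.ndarray:
        x = np.asarray(angles) / np.pi - 1.0
        return np.polynomial.polynomial.polyval(x, self.coeffs)


def fit_contour_profile(mask_slice: np.ndarray, centroid_vox, spacing,
                        slice_index: int = 0, n_angles: int = 96,
                        degree: int = POLY_DEGREE) -> ContourProfile:
    """Sample the radial contour about the centroid and fit the polynomial.

    The radius at each angle is the *largest* crossing of the interpolated
    mask (so non-star-shaped slices take the outermost boundary), refined to
    the 0.5 iso-level. Raises when fewer than 10 angles hit the mask.
    """
    mask = np.asarray(mask_slice, dtype=np.float32)
    dx, dy = float(spacing[0]), float(spacing[1])
    cx, cy = float(centroid_vox[0]), float(centroid_vox[1])
    c_mm = np.array([(cx + 0.5) * dx, (cy + 0.5) * dy])

    xs, ys = np.nonzero(mask > 0.5)
    if xs.size == 0:
        raise ValueError("empty slice mask")
    pts_mm = np.stack([(xs + 0.5) * dx, (ys + 0.5) * dy], axis=1)
    r_max = float(np.linalg.norm(pts_mm - c_mm, axis=1).max()) + 2.0

    step = SCAN_STEP_VOXELS * min(dx, dy)
    rs = np.arange(0.0, r_max + step, step)
    thetas = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    px = c_mm[0] + np.outer(np.cos(thetas), rs)
    py = c_mm[1] + np.outer(np.sin(thetas), rs)
    coords = np.stack([px / dx - 0.5, py / dy - 0.5])
    vals = ndimage.map_coordinates(mask, coords, order=1, mode="constant")

    radii = np.full(n_angles, np.nan)
    for i in range(n_angles):
        above = np.flatnonzero(vals[i] >= 0.5)
        if above.size == 0:
            continue
        j = above[-1]
        if j + 1 < len(rs):
            frac = _refine_crossing(vals[i], j, j + 1)
            radii[i] = np.interp(frac, np.arange(len(rs)), rs)
        else:
            radii[i] = rs[j]
    valid = ~np.isnan(radii)
    if valid.sum() < 10:
        raise ValueError("fewer than 10 boundary samples on the contour")
    th = thetas[valid]
    r = radii[valid]
    x = th / np.pi - 1.0
    V = np.vander(x, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(V, r, rcond=None)
    resid = V @ coeffs - r
    rms = float(np.sqrt(np.mean(resid**2)))
    return ContourProfile(slice_index=slice_index, angles=th, radii_mm=r,
                          coeffs=coeffs, residual_rms_mm=rms,
                          centroid_mm=(float(c_mm[0]), float(c_mm[1])))


# ---------------------------------------------------------------------------
# Valve cutoff
# ---------------------------------------------------------------------------

@dataclass
class ValveCutoff:
    """Most cranial non-atrial slice and the slices excluded as atrial."""

    slice_index: int
    atrial_slices: set = field(default_factory=set)


def _has_notch(profile: ContourProfile, notch_fraction: float) -> bool:
    """True when the fitted profile has a concave notch deeper than
    ``notch_fraction`` of the mean radius (derivative-root analysis)."""
    P = np.polynomial.polynomial
    lo = (profile.angles.min() / np.pi) - 1.0
    hi = (profile.angles.max() / np.pi) - 1.0
    d1 = P.polyder(profile.coeffs)
    d2 = P.polyder(d1)
    roots = P.polyroots(d1)
    roots = np.real(roots[np.abs(roots.imag) < 1e-8])
    roots = roots[(roots > lo) & (roots < hi)]
    if roots.size == 0:
        return False
    minima = roots[P.polyval(roots, d2) > 0]
    if minima.size == 0:
        return False
    maxima = np.sort(np.concatenate(
        [roots[P.polyval(roots, d2) < 0], [lo, hi]]))
    mean_r = profile.mean_radius_mm
    for m in minima:
        v_min = P.polyval(m, profile.coeffs)
        left = maxima[maxima < m]
        right = maxima[maxima > m]
        if left.size == 0 or right.size == 0:
            continue
        v_sides = min(P.polyval(left[-1], profile.coeffs),
                      P.polyval(right[0], profile.coeffs))
        if v_sides - v_min > notch_fraction * mean_r:
            return True
    return False


def find_valve_cutoff(profiles: list[ContourProfile],
                      caliper_lengths: dict,
                      notch_fraction: float = 0.25,
                      trend_tolerance: float = 0.18,
                      trend_min_dev_mm: float = 2.5) -> ValveCutoff:
    """Locate the atrioventricular valve along the slice stack.

    Slices are atrial when their contour profile shows a significant concave
    notch on the cranial side, or when their caliper length departs from the
    smooth craniocaudal trend (quadratic in length squared, fitted to the
    caudal 60% of slices) by more than ``trend_tolerance`` relatively. The
    cutoff is the most cranial slice of the contiguous non-atrial range; with
    no valve evidence the full range is retained.
    """
    slices = sorted(caliper_lengths)
    if len(slices) < 5:
        return ValveCutoff(slice_index=slices[0] if slices else 0)
    marked: set[int] = set()

    prof_by_slice = {p.slice_index: p for p in profiles}
    n = len(slices)
    cranial_half = set(slices[:n // 2])
    for k in cranial_half:
        p = prof_by_slice.get(k)
        if p is not None and _has_notch(p, notch_fraction):
            marked.add(k)

    # craniocaudal trend: L^2 is quadratic in slice index for an ellipsoid
    caudal = slices[int(np.ceil(0.4 * n)):]
    if len(caudal) >= 4:
        ks = np.array(caudal, dtype=float)
        L2 = np.array([caliper_lengths[k] ** 2 for k in caudal])
        coef = np.polyfit(ks, L2, 2)
        for k in slices:
            pred = float(np.polyval(coef, k))
            if pred <= 0:
                marked.add(k)
                continue
            trend_l = np.sqrt(pred)
            dev = abs(caliper_lengths[k] - trend_l)
            if dev / trend_l > trend_tolerance and dev > trend_min_dev_mm:
                marked.add(k)

    cutoff = slices[0]
    for k in slices:
        if k not in marked:
            cutoff = k
            break
    else:
        cutoff = slices[0]
        marked = set()
    return ValveCutoff(slice_index=cutoff, atrial_slices=marked)


# ---------------------------------------------------------------------------
# Maximum selection and the ratio
# ---------------------------------------------------------------------------

@dataclass
class RVLVResult:
    """Selected per-chamber maximal calipers and their ratio."""

    rv: Caliper | None
    lv: Caliper | None
    ratio: float | None
    valve_slice_rv: int | None
    valve_slice_lv: int | None
    flags: set = field(default_factory=set)


def _admissible(calipers: list[Caliper], valve: ValveCutoff | int | None):
    if valve is None:
        return list(calipers)
    if isinstance(valve, int):
        valve = ValveCutoff(slice_index=valve)
    return [c for c in calipers
            if c.slice_index >= valve.slice_index
            and c.slice_index not in valve.atrial_slices]


def select_max_and_ratio(rv_calipers: list[Caliper], lv_calipers: list[Caliper],
                         rv_valve: ValveCutoff | int | None = None,
                         lv_valve: ValveCutoff | int | None = None) -> RVLVResult:
    """Pick the maximal admissible caliper per chamber and divide.

    Only calipers between the valve cutoff and the apex compete; the RV and
    LV maxima may come from different craniocaudal levels. A chamber without
    an admissible caliper yields a flagged result without a ratio.
    """
    flags: set[str] = set()
    best = {}
    for chamber, cals, valve, flag in (
            ("RV", rv_calipers, rv_valve, FLAG_DETECTION_FAILED_RV),
            ("LV", lv_calipers, lv_valve, FLAG_DETECTION_FAILED_LV)):
        adm = _admissible(cals, valve)
        if not adm:
            flags.add(flag)
            best[chamber] = None
        else:
            best[chamber] = max(adm, key=lambda c: (c.length_mm, -c.slice_index))
    ratio = None
    if best["RV"] is not None and best["LV"] is not None:
        ratio = best["RV"].length_mm / best["LV"].length_mm

    def _vs(v):
        if v is None:
            return None
        return v.slice_index if isinstance(v, ValveCutoff) else int(v)

    return RVLVResult(rv=best["RV"], lv=best["LV"], ratio=ratio,
                      valve_slice_rv=_vs(rv_valve), valve_slice_lv=_vs(lv_valve),
                      flags=flags)


# ---------------------------------------------------------------------------
# Volume-level convenience used by the pipeline
# ---------------------------------------------------------------------------

def chamber_calipers(volume, mask: np.ndarray, septum: SeptumPlane,
                     chamber: str):
    """Per-slice calipers and contour profiles for one chamber mask."""
    calipers: list[Caliper] = []
    profiles: list[ContourProfile] = []
    spacing = volume.spacing
    zs = volume.slice_positions_mm()
    for k in range(volume.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        cal = slice_caliper(sl, septum, spacing[:2], float(zs[k]), chamber,
                            origin_xy=volume.origin[:2])
        if cal is None:
            continue
        cal.slice_index = k
        calipers.append(cal)
        xs, ys = np.nonzero(sl)
        try:
            profiles.append(fit_contour_profile(
                sl, (xs.mean(), ys.mean()), spacing[:2], slice_index=k))
        except ValueError:
            pass
    return calipers, profiles


def caliper_table(calipers: list[Caliper]) -> str:
    """Per-slice caliper table as tab-separated text for review."""
    lines = ["slice\tchamber\tlength_mm\tx0\ty0\tx1\ty1"]
    for c in calipers:
        (x0, y0, _), (x1, y1, _) = c.endpoints
        lines.append(f"{c.slice_index}\t{c.chamber}\t{c.length_mm:.3f}"
                     f"\t{x0:.2f}\t{y0:.2f}\t{x1:.2f}\t{y1:.2f}")
    return "\n".join(lines) + "\n"
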