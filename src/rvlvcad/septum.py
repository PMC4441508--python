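"""Interventricular septum estimation from second-order image derivatives.

The septum appears in contrast-enhanced CT as a dark slab (myocardium,
~40-80 HU) between the two bright ventricular blood pools (150-500 HU).
Along the slab normal the intensity profile has a minimum, so the Hessian of
the Gaussian-smoothed image has one strongly positive eigenvalue whose
eigenvector is the slab normal, while the in-slab eigenvalues stay near
zero. The plate score used here is

    S = max(lambda1, 0) * exp(-(lambda2^2 + lambda3^2) / (2 (c lambda1)^2))
                        * exp(-k (|grad I| / (lambda1 sigma))^2)

with |lambda1| >= |lambda2| >= |lambda3|. The last factor suppresses the
response on the dark flank of strong intensity *edges* (which also have a
large positive second derivative): at a slab mid-plane the smoothed gradient
vanishes, while on a blurred step the gradient and curvature maxima coincide
with |grad I| ~= lambda1 * sigma. Without it, the myocardium/soft-tissue
boundary can masquerade as a septum when the true slab has no contrast.

The septum plane is the arg-max of S over a search region between the
per-slice RV and LV seed pairs; the eigenvector at the arg-max is the plane
normal, re-oriented to point RV->LV. The score is linear in the image under
positive affine intensity maps, so the arg-max location is
contrast-invariant.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import CTVolume, SeedPoint, SeptumPlane

DEFAULT_SCALE_MM = 3.0
DEFAULT_CONFIDENCE_FLOOR = 2.0  # HU / mm^2
DEFAULT_DILATION_MM = 5.0


def _hessian_components(img: np.ndarray, spacing, scale_mm: float):
    """Spacing-aware Hessian of the Gaussian-smoothed image, in HU/mm^2."""
    sigma_vox = np.asarray([scale_mm / s for s in spacing])
    comps = {}
    for (a, b) in ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)):
        order = [0, 0, 0]
        order[a] += 1
        order[b] += 1
        comps[(a, b)] = (ndimage.gaussian_filter(img, sigma=sigma_vox,
                                                 order=tuple(order))
                         / (spacing[a] * spacing[b]))
    return comps


def _gradient_magnitude(img: np.ndarray, spacing, scale_mm: float):
    """|grad| of the Gaussian-smoothed image, in HU/mm."""
    sigma_vox = np.asarray([scale_mm / s for s in spacing])
    total = np.zeros_like(img)
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 1
        d = ndimage.gaussian_filter(img, sigma=sigma_vox,
                                    order=tuple(order)) / spacing[ax]
        total += d * d
    return np.sqrt(total)


def _plate_eig(comps, where=None):
    """Eigenvalues (sorted by |.| descending) and leading eigenvector of the
    Hessian at the selected voxels."""
    keys = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    if where is None:
        flat = [comps[k].ravel() for k in keys]
    else:
        flat = [comps[k][where] for k in keys]
    n = flat[0].size
    H = np.empty((n, 3, 3))
    H[:, 0, 0], H[:, 0, 1], H[:, 0, 2] = flat[0], flat[1], flat[2]
    H[:, 1, 1], H[:, 1, 2], H[:, 2, 2] = flat[3], flat[4], flat[5]
    H[:, 1, 0], H[:, 2, 0], H[:, 2, 1] = flat[1], flat[2], flat[4]
    vals, vecs = np.linalg.eigh(H)
    order = np.argsort(-np.abs(vals), axis=1, kind="stable")
    rows = np.arange(n)[:, None]
    vals_sorted = vals[rows, order]
    lead_vec = vecs[rows.ravel(), :, order[:, 0]]
    return vals_sorted, lead_vec


EDGE_SUPPRESSION = 3.0


def _plate_score(vals_sorted: np.ndarray, c: float, gradmag=None,
                 scale_mm: float = DEFAULT_SCALE_MM) -> np.ndarray:
    l1 = vals_sorted[:, 0]
    l2 = vals_sorted[:, 1]
    l3 = vals_sorted[:, 2]
    pos = np.maximum(l1, 0.0)
    denom = 2.0 * (c * np.where(l1 != 0, l1, 1.0)) ** 2
    score = pos * np.exp(-(l2**2 + l3**2) / denom)
    if gradmag is not None:
        r = gradmag / (np.abs(np.where(l1 != 0, l1, 1.0)) * scale_mm)
        score = score * np.exp(-EDGE_SUPPRESSION * r * r)
    return np.where(l1 > 0, score, 0.0)


def plate_score_field(volume: CTVolume, scale_mm: float = DEFAULT_SCALE_MM,
                      c: float = 0.5):
    """Per-voxel plate score and plate-normal orientation of a volume.

    Returns ``(score, orientation)``: score is a float array on the volume
    grid (HU/mm^2), orientation an array of unit plate normals with shape
    ``volume.shape + (3,)``.
    """
    if scale_mm < min(volume.spacing):
        raise ValueError(f"analysis scale {scale_mm} mm is smaller than one "
                         f"voxel (min spacing {min(volume.spacing)} mm)")
    img = np.asarray(volume.voxels, dtype=np.float64)
    comps = _hessian_components(img, volume.spacing, scale_mm)
    gradmag = _gradient_magnitude(img, volume.spacing, scale_mm)
    vals, vecs = _plate_eig(comps)
    score = _plate_score(vals, c, gradmag.ravel(), scale_mm
                         ).reshape(volume.shape)
    orientation = vecs.reshape(volume.shape + (3,))
    return score, orientation


def _pair_seeds_by_slice(rv_seeds, lv_seeds):
    rv_by_slice = {int(round(s.position[2])): s for s in rv_seeds}
    lv_by_slice = {int(round(s.position[2])): s for s in lv_seeds}
    common = sorted(set(rv_by_slice) & set(lv_by_slice))
    if common:
        return [(rv_by_slice[k], lv_by_slice[k]) for k in common]
    # fall back: pair every RV seed with the nearest-slice LV seed
    pairs = []
    for k, rv in sorted(rv_by_slice.items()):
        nearest = min(lv_by_slice, key=lambda kk: abs(kk - k))
        pairs.append((rv, lv_by_slice[nearest]))
    return pairs


def estimate_septum(volume: CTVolume, rv_seeds: list[SeedPoint],
                    lv_seeds: list[SeedPoint],
                    scale_mm: float = DEFAULT_SCALE_MM, c: float = 0.5,
                    dilation_mm: float = DEFAULT_DILATION_MM,
                    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
                    ) -> SeptumPlane:
    """Fit the septum plane by maximizing the plate score between the seeds.

    The search region is the union of the line segments joining each
    per-slice RV-LV seed pair, dilated by ``dilation_mm``. The arg-max voxel
    of the plate score inside the region gives the plane point and its
    Hessian eigenvector the normal (re-oriented RV->LV). A maximal score
    below ``confidence_floor`` marks the plane low-confidence.
    """
    if not rv_seeds or not lv_seeds:
        raise ValueError("septum estimation requires seeds for both chambers")
    spacing = np.asarray(volume.spacing)
    pairs = _pair_seeds_by_slice(rv_seeds, lv_seeds)

    marked = np.zeros(volume.shape, dtype=bool)
    any_segment = False
    for rv, lv in pairs:
        p0 = np.asarray(rv.position, dtype=float)
        p1 = np.asarray(lv.position, dtype=float)
        seg_mm = np.linalg.norm((p1 - p0) * spacing)
        if seg_mm < 1e-6:
            continue
        any_segment = True
        n_steps = max(int(np.ceil(seg_mm / (0.5 * spacing.min()))), 2)
        for t in np.linspace(0.0, 1.0, n_steps):
            q = np.round(p0 + t * (p1 - p0)).astype(int)
            marked[tuple(np.clip(q, 0, np.asarray(volume.shape) - 1))] = True
    if not any_segment:
        raise ValueError("empty septum search region: RV and LV seeds coincide")

    # crop with margin for the dilation and the Gaussian support
    margin_mm = dilation_mm + 4.0 * scale_mm
    idx = np.nonzero(marked)
    lo = [max(int(idx[d].min() - np.ceil(margin_mm / spacing[d])), 0)
          for d in range(3)]
    hi = [min(int(idx[d].max() + np.ceil(margin_mm / spacing[d])) + 1,
              volume.shape[d]) for d in range(3)]
    crop = tuple(slice(l, h) for l, h in zip(lo, hi))

    region = ndimage.distance_transform_edt(
        ~marked[crop], sampling=spacing) <= dilation_mm

    img = np.asarray(volume.voxels, dtype=np.float64)[crop]
    comps = _hessian_components(img, volume.spacing, scale_mm)
    gradmag = _gradient_magnitude(img, volume.spacing, scale_mm)
    where = np.nonzero(region)
    vals, vecs = _plate_eig(comps, where)
    scores = _plate_score(vals, c, gradmag[where], scale_mm)

    best = int(np.argmax(scores))
    best_score = float(scores[best])
    vox = np.array([where[0][best] + lo[0], where[1][best] + lo[1],
                    where[2][best] + lo[2]], dtype=float)
    point = volume.index_to_mm(vox)
    normal = vecs[best]

    rv_mm = np.mean([volume.index_to_mm(s.position) for s in rv_seeds], axis=0)
    lv_mm = np.mean([volume.index_to_mm(s.position) for s in lv_seeds], axis=0)
    if float(normal @ (lv_mm - rv_mm)) < 0:
        normal = -normal

    return SeptumPlane(point=tuple(point), normal=tuple(normal),
                       score=best_score, scale_mm=scale_mm,
                       low_confidence=best_score < confidence_floor)
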