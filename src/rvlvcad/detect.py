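"""Per-slice ventricle detection and cross-slice clustering.

The original clinical system used a detector trained on annotated CTPA
studies that are not redistributable; this module keeps its architecture —
scored 2D bounding boxes per axial slice, anatomical plausibility filtering,
mean-shift clustering of detections across slices, cluster ranking, one seed
point per surviving box — but trains the box scorer on phantom fixtures.

The scorer is deliberately simple and fast: intensity and gradient-magnitude
statistics pooled over concentric bands of each sliding window via integral
images, and a regularized logistic regression per chamber. It is a pluggable
interface; any model producing scored per-slice boxes can replace it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import CTVolume, SeedPoint
from .phantom import PhantomSpec, generate_phantom, truth_slice_box

BAND_FRACTIONS = (0.25, 0.5, 0.75, 1.0)


@dataclass
class Detection:
    """A scored candidate bounding box on one axial slice.

    ``box`` is (x0, y0, x1, y1) in voxel coordinates, half-open on the upper
    edges.
    """

    slice_index: int
    box: tuple[int, int, int, int]
    score: float
    chamber: str


@dataclass
class DetectionCluster:
    """A group of detections linked across slices by mean shift."""

    members: list
    mode: tuple[float, float, float]  # (x, y, slice) voxel coordinates
    rank_score: float
    chamber: str


@dataclass
class DetectorModel:
    """Linear per-chamber window scorer over integral-image features."""

    window_sizes_mm: tuple = (18.0, 24.0, 32.0, 42.0, 52.0)
    stride_vox: int = 4
    score_threshold: float = 0.0
    chambers: dict = field(default_factory=dict)  # name -> weights dict

    def to_json(self) -> str:
        d = {"format_version": 1,
             "window_sizes_mm": list(self.window_sizes_mm),
             "stride_vox": self.stride_vox,
             "score_threshold": self.score_threshold,
             "chambers": {k: {kk: (vv if isinstance(vv, (int, float)) else list(vv))
                              for kk, vv in v.items()}
                          for k, v in self.chambers.items()}}
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DetectorModel":
        d = json.loads(text)
        if d.get("format_version") != 1:
            raise ValueError("unsupported detector model version")
        chambers = {k: {kk: (np.asarray(vv, dtype=float)
                             if isinstance(vv, list) else float(vv))
                        for kk, vv in v.items()}
                    for k, v in d["chambers"].items()}
        return cls(window_sizes_mm=tuple(d["window_sizes_mm"]),
                   stride_vox=int(d["stride_vox"]),
                   score_threshold=float(d["score_threshold"]),
                   chambers=chambers)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "DetectorModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Integral-image window features
# ---------------------------------------------------------------------------

class _SliceFeatures:
    """Precomputed integral images of one axial slice for O(1) window sums.

    Window features are the overall mean/std plus a concentric "band
    profile": mean HU and mean gradient magnitude in nested square bands at
    fractions of the window half-width. A window well fitted to a chamber has
    bright inner bands, the edge ring in the outermost band and nothing
    beyond; undersized windows are bright everywhere, oversized ones carry
    the edge ring in an inner band.
    """

    PLANES = 3  # image, image^2, gradient magnitude

    def __init__(self, image: np.ndarray, spacing_xy) -> None:
        img = np.asarray(image, dtype=np.float64)
        gx, gy = np.gradient(img, spacing_xy[0], spacing_xy[1])
        mag = np.hypot(gx, gy)
        self.integrals = [self._integral(p) for p in (img, img * img, mag)]
        self.shape = img.shape

    @staticmethod
    def _integral(plane: np.ndarray) -> np.ndarray:
        out = np.zeros((plane.shape[0] + 1, plane.shape[1] + 1))
        np.cumsum(np.cumsum(plane, axis=0), axis=1, out=out[1:, 1:])
        return out

    def window_sums(self, x0, y0, x1, y1) -> np.ndarray:
        """Sums of every feature plane over boxes [x0:x1, y0:y1) (vectorized)."""
        sums = [ii[x1, y1] - ii[x0, y1] - ii[x1, y0] + ii[x0, y0]
                for ii in self.integrals]
        return np.stack(sums, axis=-1)

    def features(self, x0, y0, x1, y1) -> np.ndarray:
        """Feature vectors for boxes given as equal-length index arrays."""
        x0, y0 = np.asarray(x0), np.asarray(y0)
        x1, y1 = np.asarray(x1), np.asarray(y1)
        area = ((x1 - x0) * (y1 - y0)).astype(float)
        s = self.window_sums(x0, y0, x1, y1)
        mean = s[..., 0] / area
        var = np.maximum(s[..., 1] / area - mean**2, 0.0)
        # the squared mean lets a linear scorer represent an intensity
        # *interval* (each chamber has its own contrast level, and both
        # "too dark" and "too bright" argue against a chamber)
        cols = [mean, mean * mean / 100.0, np.sqrt(var)]
        prev = None
        for frac in BAND_FRACTIONS:
            qx = np.round((x1 - x0) * (1 - frac) / 2).astype(int)
            qy = np.round((y1 - y0) * (1 - frac) / 2).astype(int)
            sub = self.window_sums(x0 + qx, y0 + qy, x1 - qx, y1 - qy)
            sub_area = ((x1 - x0 - 2 * qx) * (y1 - y0 - 2 * qy)).astype(float)
            if prev is None:
                band = sub / np.maximum(sub_area, 1.0)[..., None]
            else:
                band = (sub - prev[0]) / np.maximum(sub_area - prev[1],
                                                    1.0)[..., None]
            band_var = np.maximum(band[..., 1] - band[..., 0] ** 2, 0.0)
            cols.extend([band[..., 0], band[..., 0] ** 2 / 100.0,
                         np.sqrt(band_var), band[..., 2]])
            prev = (sub, sub_area)
        return np.stack(cols, axis=-1)


def window_features(image: np.ndarray, boxes, spacing_xy=(1.0, 1.0)) -> np.ndarray:
    """Feature matrix for a list of (x0, y0, x1, y1) boxes on one slice."""
    sf = _SliceFeatures(image, spacing_xy)
    b = np.asarray(boxes, dtype=int)
    return sf.features(b[:, 0], b[:, 1], b[:, 2], b[:, 3])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _best_square_window(box, window_sizes_vox, shape):
    """Square window (centred on a truth box) with the highest IoU."""
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    best, best_iou = None, -1.0
    for w in window_sizes_vox:
        wx0 = int(round(cx - w / 2.0))
        wy0 = int(round(cy - w / 2.0))
        cand = (wx0, wy0, wx0 + w, wy0 + w)
        iou = box_iou(cand, (x0, y0, x1 + 1, y1 + 1))
        if iou > best_iou:
            best, best_iou = cand, iou
    x0, y0, x1, y1 = best
    if x0 < 0 or y0 < 0 or x1 > shape[0] or y1 > shape[1]:
        return None
    return best


def box_iou(a, b) -> float:
    """Intersection over union of two (x0, y0, x1, y1) half-open boxes."""
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1])
             - inter)
    return inter / union if union > 0 else 0.0


def train_detector(fixtures, negatives=(), *, window_sizes_mm=None,
                   spacing_xy=(1.0, 1.0), seed: int = 0,
                   stride_vox: int = 4,
                   extra_negative_features: dict | None = None) -> DetectorModel:
    """Train per-chamber window scorers from labelled axial slices.

    ``fixtures`` is a list of ``(slice_image, {chamber: (x0, y0, x1, y1)})``
    with inclusive voxel boxes; ``negatives`` a list of slice images without
    chambers. Each chamber's positives are windows centred on its boxes; its
    negatives pool random background windows, windows from the negative
    images, and the other chamber's positives. Training is seeded and
    deterministic.
    """
    from sklearn.linear_model import LogisticRegression

    model = DetectorModel(stride_vox=stride_vox)
    if window_sizes_mm is not None:
        model.window_sizes_mm = tuple(window_sizes_mm)
    sizes_vox = sorted({max(4, int(round(s / spacing_xy[0])))
                        for s in model.window_sizes_mm})
    rng = np.random.default_rng(seed)

    feats: dict[str, list] = {}
    chamber_names: list[str] = []
    bg_feats: list[np.ndarray] = []

    def _feat(sf, win):
        return sf.features(*[np.array([v]) for v in win])[0]

    for image, boxes in fixtures:
        sf = _SliceFeatures(image, spacing_xy)
        occupied = []
        for chamber, box in boxes.items():
            if chamber not in chamber_names:
                chamber_names.append(chamber)
            win = _best_square_window(box, sizes_vox, image.shape)
            if win is None:
                continue
            feats.setdefault(chamber, []).append(_feat(sf, win))
            # jittered copies teach tolerance to the sliding-window stride
            for jx, jy in ((2, 0), (-2, 0), (0, 2), (0, -2)):
                jit = (win[0] + jx, win[1] + jy, win[2] + jx, win[3] + jy)
                if jit[0] >= 0 and jit[1] >= 0 and jit[2] <= image.shape[0] \
                        and jit[3] <= image.shape[1]:
                    feats[chamber].append(_feat(sf, jit))
            occupied.append(win)
            # hard negatives around each labelled chamber: undersized and
            # oversized windows (wrong scale) and half-window shifts (wrong
            # position straddling the chamber edge)
            cx, cy = (win[0] + win[2]) // 2, (win[1] + win[3]) // 2
            w = win[2] - win[0]
            cands = []
            for factor in (0.45, 1.6):
                hw = int(round(w * factor / 2))
                if hw >= 3:
                    cands.append((cx - hw, cy - hw, cx + hw, cy + hw))
            for sx, sy in ((w // 2, 0), (0, w // 2), (-w // 2, 0),
                           (0, -w // 2)):
                cands.append((win[0] + sx, win[1] + sy,
                              win[2] + sx, win[3] + sy))
            for cand in cands:
                if cand[0] >= 0 and cand[1] >= 0 \
                        and cand[2] <= image.shape[0] \
                        and cand[3] <= image.shape[1]:
                    bg_feats.append(_feat(sf, cand))
        # random background windows avoiding the labelled chambers
        for _ in range(12):
            w = int(rng.choice(sizes_vox))
            if image.shape[0] <= w or image.shape[1] <= w:
                continue
            x0 = int(rng.integers(0, image.shape[0] - w))
            y0 = int(rng.integers(0, image.shape[1] - w))
            cand = (x0, y0, x0 + w, y0 + w)
            if all(box_iou(cand, o) < 0.1 for o in occupied):
                bg_feats.append(sf.features(*[np.array([v]) for v in cand])[0])
    for image in negatives:
        sf = _SliceFeatures(image, spacing_xy)
        for _ in range(8):
            w = int(rng.choice(sizes_vox))
            if image.shape[0] <= w or image.shape[1] <= w:
                continue
            x0 = int(rng.integers(0, image.shape[0] - w))
            y0 = int(rng.integers(0, image.shape[1] - w))
            bg_feats.append(sf.features(
                np.array([x0]), np.array([y0]),
                np.array([x0 + w]), np.array([y0 + w]))[0])

    for chamber in chamber_names:
        pos = np.asarray(feats.get(chamber, []))
        other = [np.asarray(feats[c]) for c in chamber_names
                 if c != chamber and feats.get(c)]
        if extra_negative_features and chamber in extra_negative_features \
                and len(extra_negative_features[chamber]):
            other.append(np.asarray(extra_negative_features[chamber]))
        neg = np.concatenate([np.asarray(bg_feats)] + other, axis=0) \
            if bg_feats or other else np.empty((0, pos.shape[1]))
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError(f"no training windows for chamber {chamber}")
        X = np.concatenate([pos, neg], axis=0)
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("degenerate (zero-variance) training features")
        clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed,
                                 class_weight="balanced")
        clf.fit((X - mu) / sd, y)
        self_w = clf.coef_[0]
        self_b = float(clf.intercept_[0])
        model.chambers[chamber] = {"coef": self_w, "intercept": self_b,
                                   "mean": mu, "scale": sd}
    return model


def score_windows(model: DetectorModel, chamber: str,
                  features: np.ndarray) -> np.ndarray:
    """Linear decision scores for pre-extracted window features."""
    p = model.chambers[chamber]
    z = (features - p["mean"]) / p["scale"]
    return z @ p["coef"] + p["intercept"]


# ---------------------------------------------------------------------------
# Detection on volumes
# ---------------------------------------------------------------------------

def _nms(dets: list[Detection], iou_threshold: float = 0.3,
         keep: int = 2) -> list[Detection]:
    dets = sorted(dets, key=lambda d: (-d.score, d.box))
    out: list[Detection] = []
    for d in dets:
        if all(box_iou(d.box, o.box) < iou_threshold for o in out):
            out.append(d)
            if len(out) >= keep:
                break
    return out


def detect_slices(volume: CTVolume, model: DetectorModel,
                  nms_iou: float = 0.3, per_slice_keep: int = 2) -> list[Detection]:
    """Run the sliding-window detector over every axial slice.

    Windows are squares of the model's configured physical sizes, swept at the
    configured voxel stride; windows scoring above the model threshold survive
    per-slice non-maximum suppression (keeping the locally best boxes).
    Deterministic: the same volume always yields the same detections.
    """
    spacing_xy = volume.spacing[:2]
    stride = model.stride_vox
    sizes_vox = sorted({max(4, int(round(s / spacing_xy[0])))
                        for s in model.window_sizes_mm})
    detections: list[Detection] = []
    vox = np.asarray(volume.voxels)
    cap = 30  # top candidates per chamber per slice entering NMS
    for k in range(volume.shape[2]):
        sf = _SliceFeatures(vox[:, :, k], spacing_xy)
        all_feats, all_boxes = [], []
        for w in sizes_vox:
            if vox.shape[0] <= w or vox.shape[1] <= w:
                continue
            xs = np.arange(0, vox.shape[0] - w + 1, stride)
            ys = np.arange(0, vox.shape[1] - w + 1, stride)
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            gx, gy = gx.ravel(), gy.ravel()
            all_feats.append(sf.features(gx, gy, gx + w, gy + w))
            all_boxes.append(np.stack([gx, gy, gx + w, gy + w], axis=1))
        if not all_feats:
            continue
        feats = np.concatenate(all_feats, axis=0)
        boxes = np.concatenate(all_boxes, axis=0)
        for chamber in model.chambers:
            scores = score_windows(model, chamber, feats)
            keep = np.nonzero(scores > model.score_threshold)[0]
            if keep.size == 0:
                continue
            if keep.size > cap:
                keep = keep[np.argsort(-scores[keep], kind="stable")[:cap]]
            dets = [Detection(slice_index=k, box=tuple(int(v) for v in boxes[i]),
                              score=float(scores[i]), chamber=chamber)
                    for i in keep]
            detections.extend(_nms(dets, nms_iou, per_slice_keep))
    return detections


@dataclass
class AnatomyPrior:
    """Plausibility bounds for chamber detections."""

    min_size_mm: float = 12.0
    max_size_mm: float = 90.0
    margin_fraction: float = 0.10
    blood_pool_floor_hu: float = 80.0


def filter_by_anatomy_prior(detections: list[Detection], volume: CTVolume,
                            prior: AnatomyPrior | None = None) -> list[Detection]:
    """Drop detections incompatible with heart location/size statistics.

    Removes boxes whose physical extent lies outside the chamber-size bounds,
    whose centre falls in the outer margin of the slice, or whose mean
    interior HU is below the blood-pool floor. Always returns a subset of the
    input.
    """
    prior = prior or AnatomyPrior()
    vox = np.asarray(volume.voxels)
    dx, dy = volume.spacing[:2]
    nxv, nyv = vox.shape[:2]
    out = []
    for d in detections:
        x0, y0, x1, y1 = d.box
        w_mm, h_mm = (x1 - x0) * dx, (y1 - y0) * dy
        if not (prior.min_size_mm <= w_mm <= prior.max_size_mm
                and prior.min_size_mm <= h_mm <= prior.max_size_mm):
            continue
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        m = prior.margin_fraction
        if not (m * nxv <= cx <= (1 - m) * nxv and m * nyv <= cy <= (1 - m) * nyv):
            continue
        if vox[x0:x1, y0:y1, d.slice_index].mean() < prior.blood_pool_floor_hu:
            continue
        out.append(d)
    return out


# ---------------------------------------------------------------------------
# Mean shift
# ---------------------------------------------------------------------------

def mean_shift_cluster(points, weights=None, bandwidth: float = 15.0,
                       tol: float = 1e-3, max_iter: int = 200):
    """Gaussian-kernel mean shift in mm space.

    Every point ascends to a mode of the weighted kernel density estimate by
    iterating the kernel-weighted mean until the displacement falls below
    ``tol * bandwidth``; ascent endpoints within ``bandwidth / 2`` of each
    other merge into one cluster. Returns ``[(mode, member_indices), ...]``
    sorted by descending total member weight (ties broken by mode
    coordinates, so the result is independent of input order).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("mean shift requires at least one point")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)

    modes = pts.copy()
    h2 = bandwidth * bandwidth
    for _ in range(max_iter):
        d2 = ((modes[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        kern = w[None, :] * np.exp(-0.5 * d2 / h2)
        new = (kern @ pts) / kern.sum(axis=1, keepdims=True)
        shift = np.linalg.norm(new - modes, axis=1).max()
        modes = new
        if shift < tol * bandwidth:
            break

    # merge ascent endpoints within bandwidth/2 (order-independent: process
    # points sorted by their endpoint coordinates)
    order = np.lexsort(modes.T[::-1])
    cluster_of = np.full(len(pts), -1, dtype=int)
    centers: list[np.ndarray] = []
    members: list[list[int]] = []
    for i in order:
        assigned = False
        for c, ctr in enumerate(centers):
            if np.linalg.norm(modes[i] - ctr) < bandwidth / 2.0:
                members[c].append(int(i))
                # running weighted mean of merged endpoints
                tw = sum(w[j] for j in members[c])
                centers[c] = sum(w[j] * modes[j] for j in members[c]) / tw
                cluster_of[i] = c
                assigned = True
                break
        if not assigned:
            centers.append(modes[i].copy())
            members.append([int(i)])
            cluster_of[i] = len(centers) - 1
    result = [(centers[c], sorted(members[c])) for c in range(len(centers))]
    result.sort(key=lambda cm: (-sum(w[j] for j in cm[1]), tuple(cm[0])))
    return result


# ---------------------------------------------------------------------------
# Cluster ranking and seeds
# ---------------------------------------------------------------------------

def cluster_detections(detections: list[Detection], volume: CTVolume,
                       bandwidth_mm: float = 10.0) -> list[DetectionCluster]:
    """Group per-slice detections of each chamber with mean shift in mm space."""
    clusters: list[DetectionCluster] = []
    spacing = np.asarray(volume.spacing)
    for chamber in sorted({d.chamber for d in detections}):
        dets = [d for d in detections if d.chamber == chamber]
        centers_vox = np.array([[(d.box[0] + d.box[2]) / 2.0,
                                 (d.box[1] + d.box[3]) / 2.0,
                                 d.slice_index] for d in dets])
        pts_mm = centers_vox * spacing[None, :]
        weights = np.array([max(d.score, 1e-6) for d in dets])
        for mode_mm, member_idx in mean_shift_cluster(pts_mm, weights,
                                                      bandwidth_mm):
            members = [dets[i] for i in member_idx]
            mode_vox = tuple(np.asarray(mode_mm) / spacing)
            clusters.append(DetectionCluster(
                members=members, mode=mode_vox,
                rank_score=float("nan"), chamber=chamber))
    return clusters


def rank_and_select(clusters: list[DetectionCluster], alpha: float = 0.5,
                    min_mode_separation_mm: float | None = None,
                    spacing=None) -> dict:
    """Keep the highest-ranking cluster per chamber.

    The rank is ``(sum of member scores) * (member count) ** alpha``,
    rewarding both confidence and persistence across slices. Ties break
    toward the more cranial cluster (lowest mean slice index). Chambers with
    no cluster map to None (a detection-failure flag, not an exception).

    With ``min_mode_separation_mm`` set (requires ``spacing``), the RV and LV
    selections are made jointly: the pair maximizing the summed rank among
    pairs whose modes are at least that far apart *in-plane* wins (the two
    chambers coexist on axial slices, so in-plane distance is the right
    measure — a cluster on the RV atrium is cranially offset but nearly
    coaxial with the RV). This guards against the degenerate case where both
    chambers' top-ranked clusters sit on the same blood pool; per-chamber
    arg-max is the fallback when no admissible pair exists.
    """
    best: dict[str, DetectionCluster | None] = {"RV": None, "LV": None}
    for cl in clusters:
        cl.rank_score = (sum(d.score for d in cl.members)
                         * len(cl.members) ** alpha)

    def key(c):
        mean_slice = np.mean([d.slice_index for d in c.members])
        return (-c.rank_score, mean_slice)

    cands = {ch: sorted([c for c in clusters if c.chamber == ch], key=key)
             for ch in best}
    for chamber in best:
        if cands[chamber]:
            best[chamber] = cands[chamber][0]

    if (min_mode_separation_mm is not None and spacing is not None
            and cands["RV"] and cands["LV"]):
        sp = np.asarray(spacing, dtype=float)
        pairs = []
        for rv in cands["RV"]:
            for lv in cands["LV"]:
                dist = np.linalg.norm(((np.asarray(rv.mode)
                                        - np.asarray(lv.mode)) * sp)[:2])
                if dist >= min_mode_separation_mm:
                    pairs.append((rv.rank_score + lv.rank_score, rv, lv))
        if pairs:
            _, rv, lv = max(pairs, key=lambda p: p[0])
            best["RV"], best["LV"] = rv, lv
    return best


def enforce_chamber_laterality(best: dict) -> dict:
    """Assign RV/LV labels of the selected cluster pair by anatomy.

    The right ventricle is the patient-right (smaller x in the canonical
    frame), anterior chamber. Appearance alone cannot separate the chambers
    when contrast enhancement varies (bolus timing changes the RV attenuation
    by hundreds of HU), so after the best pair of blood pools is selected the
    labels follow laterality, ties broken by the anterior (smaller y) rule.
    """
    rv, lv = best.get("RV"), best.get("LV")
    if rv is None or lv is None:
        return best
    if (rv.mode[0], rv.mode[1]) > (lv.mode[0], lv.mode[1]):
        rv, lv = lv, rv
        for cluster, chamber in ((rv, "RV"), (lv, "LV")):
            cluster.chamber = chamber
            for d in cluster.members:
                d.chamber = chamber
    return {"RV": rv, "LV": lv}


def seeds_from_cluster(cluster: DetectionCluster, volume: CTVolume,
                       snap_radius_vox: int = 3) -> list[SeedPoint]:
    """One seed per member slice: box centre snapped to the brightest voxel in
    a small central neighbourhood, so seeds land in the blood pool."""
    if not cluster.members:
        raise ValueError("cannot derive seeds from an empty cluster")
    vox = np.asarray(volume.voxels)
    best_per_slice: dict[int, Detection] = {}
    for d in cluster.members:
        cur = best_per_slice.get(d.slice_index)
        if cur is None or d.score > cur.score:
            best_per_slice[d.slice_index] = d
    seeds = []
    r = snap_radius_vox
    for k in sorted(best_per_slice):
        d = best_per_slice[k]
        cx = int(round((d.box[0] + d.box[2]) / 2.0))
        cy = int(round((d.box[1] + d.box[3]) / 2.0))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, vox.shape[0])
        y0, y1 = max(cy - r, 0), min(cy + r + 1, vox.shape[1])
        patch = vox[x0:x1, y0:y1, k]
        # stay at the box centre unless a strictly brighter voxel exists
        if patch.max() > vox[cx, cy, k] + 1e-6:
            ix, iy = np.unravel_index(int(np.argmax(patch)), patch.shape)
            cx, cy = x0 + ix, y0 + iy
        seeds.append(SeedPoint(position=(cx, cy, k),
                               chamber=cluster.chamber))
    return seeds


# ---------------------------------------------------------------------------
# Phantom-based default training
# ---------------------------------------------------------------------------

def phantom_fixtures(specs: list[PhantomSpec], slices_per_phantom: int = 7):
    """Labelled axial slices + chamber-free negatives from rendered phantoms."""
    fixtures, negatives = [], []
    for spec in specs:
        volume, truth = generate_phantom(spec)
        vox = np.asarray(volume.voxels)
        ks = np.nonzero(truth.rv_mask.any(axis=(0, 1))
                        & truth.lv_mask.any(axis=(0, 1)))[0]
        picks = np.unique(np.linspace(ks[0] + 1, ks[-1] - 1,
                                      slices_per_phantom).astype(int))
        for k in picks:
            boxes = {}
            for chamber, mask in (("RV", truth.rv_mask), ("LV", truth.lv_mask)):
                box = truth_slice_box(mask, k)
                if box is not None and (box[2] - box[0]) * volume.spacing[0] > 10:
                    boxes[chamber] = box
            if boxes:
                fixtures.append((vox[:, :, k], boxes))
        negatives.append(vox[:, :, 2])  # cranial slice without chambers
    return fixtures, negatives


def train_default_detector(seed: int = 0,
                           mining_rounds: int = 1) -> DetectorModel:
    """Train the shipped detector on the phantom training suite.

    After the initial fit, one round of hard-negative mining runs the
    detector over a subset of the training phantoms and feeds every false
    positive (a surviving box with IoU < 0.3 against its chamber's truth box)
    back into training as a negative. This systematically covers the misfit
    configurations a sliding window can produce instead of hand-enumerating
    them. Fully seeded and deterministic.
    """
    from .phantom import training_suite_specs

    specs = training_suite_specs()
    spacing_xy = specs[0].spacing[:2]
    fixtures, negatives = phantom_fixtures(specs)
    model = train_detector(fixtures, negatives, spacing_xy=spacing_xy,
                           seed=seed)
    for _ in range(mining_rounds):
        mined: dict[str, list] = {c: [] for c in model.chambers}
        for spec in specs[::2]:
            volume, truth = generate_phantom(spec)
            vox = np.asarray(volume.voxels)
            masks = {"RV": truth.rv_mask, "LV": truth.lv_mask}
            slice_cache: dict[int, _SliceFeatures] = {}
            for det in detect_slices(volume, model):
                tb = truth_slice_box(masks[det.chamber], det.slice_index)
                iou = 0.0
                if tb is not None:
                    iou = box_iou(det.box, (tb[0], tb[1], tb[2] + 1,
                                            tb[3] + 1))
                if iou >= 0.3:
                    continue
                if det.slice_index not in slice_cache:
                    slice_cache[det.slice_index] = _SliceFeatures(
                        vox[:, :, det.slice_index], spacing_xy)
                sf = slice_cache[det.slice_index]
                mined[det.chamber].append(
                    sf.features(*[np.array([v]) for v in det.box])[0])
        if not any(mined.values()):
            break
        model = train_detector(fixtures, negatives, spacing_xy=spacing_xy,
                               seed=seed, extra_negative_features=mined)
    return model
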