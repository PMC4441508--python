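"""Reading CT volumes (NIfTI, MetaImage, DICOM series) and writing case reports.

Volumes are returned in the canonical frame of :mod:`rvlvcad.core`: axis 2 is
craniocaudal (slice index increases caudally), intensities are HU with any
rescale applied, and slices are ordered by position, never by filename.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import _dicom
from .core import Caliper, CaseReport, CTVolume, SeptumPlane


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_volume(path: str) -> CTVolume:
    """Load a CT volume from a DICOM series directory, NIfTI or MetaImage file."""
    if os.path.isdir(path):
        voxels, spacing, origin = _dicom.read_series(path)
        return CTVolume(voxels, spacing, origin)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return _load_nifti(path)
    if lower.endswith((".mhd", ".mha")):
        return _load_metaimage(path)
    raise ValueError(f"unrecognized volume format: {path}")


def _load_nifti(path: str) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    if np.any(np.abs(affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))) > 1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) NIfTI "
                         "volumes are supported")
    diag = np.diag(affine[:3, :3]).copy()
    offset = affine[:3, 3].copy()
    # re-order axes so every world axis increases with its index
    for ax in range(3):
        if diag[ax] < 0:
            data = np.flip(data, axis=ax)
            offset[ax] = offset[ax] + diag[ax] * (data.shape[ax] - 1)
            diag[ax] = -diag[ax]
    spacing = tuple(float(s) for s in diag)
    origin = tuple(float(offset[i] - 0.5 * diag[i]) for i in range(3))
    return CTVolume(np.ascontiguousarray(data), spacing, origin)


def save_nifti(volume: CTVolume, path: str) -> None:
    """Write a volume as NIfTI with spacing and origin in the affine."""
    import nibabel as nib

    affine = np.eye(4)
    for i in range(3):
        affine[i, i] = volume.spacing[i]
        affine[i, 3] = volume.origin[i] + 0.5 * volume.spacing[i]
    nib.save(nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32),
                             affine), path)


def save_labelmap_nifti(masks: dict, spacing, path: str,
                        labels: dict | None = None) -> None:
    """Write chamber masks as a NIfTI labelmap (RV=1, LV=2 by default)."""
    import nibabel as nib

    labels = labels or {"RV": 1, "LV": 2}
    first = next(iter(masks.values()))
    lab = np.zeros(first.shape, dtype=np.int16)
    for name, mask in masks.items():
        lab[np.asarray(mask, dtype=bool)] = labels[name]
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = 0.5 * np.asarray(spacing)
    nib.save(nib.Nifti1Image(lab, affine), path)


# ---------------------------------------------------------------------------
# MetaImage (.mhd/.mha) — hand-rolled, no reader available in the environment
# ---------------------------------------------------------------------------

_MET_TYPES = {"MET_SHORT": np.int16, "MET_USHORT": np.uint16,
              "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
              "MET_UCHAR": np.uint8}


def save_metaimage(volume: CTVolume, path: str) -> None:
    """Write a volume as a single-file MetaImage (.mha, local raw data)."""
    if not path.lower().endswith(".mha"):
        raise ValueError("only single-file .mha output is supported")
    offset = [volume.origin[i] + 0.5 * volume.spacing[i] for i in range(3)]
    header = "\n".join([
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        f"DimSize = {volume.shape[0]} {volume.shape[1]} {volume.shape[2]}",
        f"ElementSpacing = {volume.spacing[0]} {volume.spacing[1]} {volume.spacing[2]}",
        f"Offset = {offset[0]} {offset[1]} {offset[2]}",
        "ElementType = MET_FLOAT",
        "ElementDataFile = LOCAL",
    ]) + "\n"
    with open(path, "wb") as fh:
        fh.write(header.encode())
        # MetaImage raw data is x-fastest: store as (z, y, x) C-order
        fh.write(np.ascontiguousarray(
            np.asarray(volume.voxels, dtype="<f4").transpose(2, 1, 0)).tobytes())


def _load_metaimage(path: str) -> CTVolume:
    with open(path, "rb") as fh:
        raw = fh.read()
    fields: dict[str, str] = {}
    pos = 0
    while True:
        eol = raw.index(b"\n", pos)
        line = raw[pos:eol].decode()
        pos = eol + 1
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
        if key.strip() == "ElementDataFile":
            break
    if fields.get("NDims") != "3":
        raise ValueError(f"{path}: only 3D MetaImage volumes are supported")
    if fields.get("BinaryDataByteOrderMSB", "False") == "True":
        raise ValueError(f"{path}: big-endian MetaImage data is unsupported")
    shape = tuple(int(v) for v in fields["DimSize"].split())
    if "ElementSpacing" not in fields:
        raise ValueError(f"{path}: missing ElementSpacing")
    spacing = tuple(float(v) for v in fields["ElementSpacing"].split())
    offset = tuple(float(v) for v in fields.get("Offset", "0 0 0").split())
    dtype = _MET_TYPES[fields.get("ElementType", "MET_FLOAT")]
    datafile = fields["ElementDataFile"]
    if datafile == "LOCAL":
        data = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"),
                             offset=pos, count=int(np.prod(shape)))
    else:
        with open(os.path.join(os.path.dirname(path), datafile), "rb") as fh:
            data = np.frombuffer(fh.read(), dtype=np.dtype(dtype).newbyteorder("<"),
                                 count=int(np.prod(shape)))
    voxels = data.reshape(shape[::-1]).transpose(2, 1, 0).astype(np.float32)
    origin = tuple(offset[i] - 0.5 * spacing[i] for i in range(3))
    return CTVolume(np.ascontiguousarray(voxels), spacing, origin)


def save_dicom_series(volume: CTVolume, directory: str,
                      slope: float = 1.0, intercept: float = -1024.0) -> list:
    """Write a volume as a synthetic single-frame-per-slice DICOM series."""
    return _dicom.write_series(directory, np.asarray(volume.voxels),
                               volume.spacing, volume.origin,
                               slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# Case reports
# ---------------------------------------------------------------------------

def _caliper_to_dict(cal: Caliper, volume: CTVolume | None) -> dict:
    d = {
        "slice_index": int(cal.slice_index),
        "chamber": cal.chamber,
        "length_mm": float(cal.length_mm),
        "endpoints_mm": [[float(x) for x in p] for p in cal.endpoints],
    }
    if volume is not None:
        d["endpoints_voxel"] = [[float(x) for x in volume.mm_to_index(p)]
                                for p in cal.endpoints]
    return d


def _caliper_from_dict(d: dict) -> Caliper:
    return Caliper(slice_index=d["slice_index"],
                   endpoints=(tuple(d["endpoints_mm"][0]),
                              tuple(d["endpoints_mm"][1])),
                   length_mm=d["length_mm"], chamber=d["chamber"])


def report_to_dict(report: CaseReport, volume: CTVolume | None = None) -> dict:
    d: dict = {"flags": sorted(report.flags),
               "timings_s": {k: float(v) for k, v in report.timings_s.items()}}
    if report.ratio is not None:
        d["ratio"] = float(report.ratio)
    for name, cal in (("rv_caliper", report.rv_caliper),
                      ("lv_caliper", report.lv_caliper)):
        if cal is not None:
            d[name] = _caliper_to_dict(cal, volume)
    if report.septum is not None:
        d["septum"] = {"point_mm": [float(x) for x in report.septum.point],
                       "normal": [float(x) for x in report.septum.normal],
                       "score": float(report.septum.score),
                       "scale_mm": float(report.septum.scale_mm),
                       "low_confidence": bool(report.septum.low_confidence)}
    return d


def report_from_dict(d: dict) -> CaseReport:
    septum = None
    if "septum" in d:
        s = d["septum"]
        septum = SeptumPlane(point=tuple(s["point_mm"]), normal=tuple(s["normal"]),
                             score=s["score"], scale_mm=s["scale_mm"],
                             low_confidence=s.get("low_confidence", False))
    return CaseReport(
        rv_caliper=_caliper_from_dict(d["rv_caliper"]) if "rv_caliper" in d else None,
        lv_caliper=_caliper_from_dict(d["lv_caliper"]) if "lv_caliper" in d else None,
        ratio=d.get("ratio"),
        flags=set(d.get("flags", [])),
        timings_s=dict(d.get("timings_s", {})),
        septum=septum,
    )


def write_report(report: CaseReport, volume: CTVolume | None, directory: str,
                 overlays: bool = True) -> str:
    """Write a machine-readable case report plus per-caliper overlay images.

    Returns the path of the JSON report. Overlay PNGs show the axial slice of
    each caliper with the measurement segment drawn on it.
    """
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, "report.json")
    with open(path, "w") as fh:
        json.dump(report_to_dict(report, volume), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if overlays and volume is not None:
        for cal in (report.rv_caliper, report.lv_caliper):
            if cal is not None:
                _write_overlay(volume, cal,
                               os.path.join(directory,
                                            f"{cal.chamber.lower()}_caliper.png"))
    return path


def read_report(path: str) -> CaseReport:
    with open(path) as fh:
        return report_from_dict(json.load(fh))


def _write_overlay(volume: CTVolume, cal: Caliper, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = cal.slice_index
    img = np.asarray(volume.voxels)[:, :, k]
    p0 = volume.mm_to_index(cal.endpoints[0])
    p1 = volume.mm_to_index(cal.endpoints[1])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img.T, cmap="gray", origin="lower", vmin=-200, vmax=500)
    ax.plot([p0[0], p1[0]], [p0[1], p1[1]], "-", color="yellow", lw=2)
    ax.set_title(f"{cal.chamber} caliper, slice {k}: {cal.length_mm:.1f} mm")
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
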