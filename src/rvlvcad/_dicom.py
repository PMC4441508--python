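"""Minimal DICOM codec for axial CT series (explicit VR little endian only).

There is no DICOM library in the runtime environment, so this module
implements the small subset of the standard the pipeline needs: writing a
synthetic single-frame CT series (geometry, rescale and pixel data tags) and
reading such series back. It is not a general DICOM implementation; files
using other transfer syntaxes, sequences or compressed pixel data are
rejected.
"""

from __future__ import annotations

import os
import struct

import numpy as np

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_CLASS_CT = "1.2.840.10008.5.1.4.1.1.2"

# VRs encoded with a 2-byte reserved field and 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_SERIES_UID = (0x0020, 0x000E)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _pad(value: bytes, pad_byte: bytes = b" ") -> bytes:
    return value + pad_byte if len(value) % 2 else value


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(*numbers) -> bytes:
    return _pad("\\".join(f"{x:.10g}" for x in numbers).encode())


def _write_slice(path: str, pixels: np.ndarray, position, pixel_spacing,
                 slice_thickness: float, slope: float, intercept: float,
                 series_uid: str, instance: int) -> None:
    """Write one axial slice. ``pixels`` is int16, shape (rows, cols)."""
    rows, cols = pixels.shape
    sop_uid = f"{series_uid}.{instance}"
    meta = b"".join([
        _element(0x0002, 0x0002, b"UI", _pad(SOP_CLASS_CT.encode(), b"\x00")),
        _element(0x0002, 0x0003, b"UI", _pad(sop_uid.encode(), b"\x00")),
        _element(0x0002, 0x0010, b"UI",
                 _pad(TRANSFER_SYNTAX_EXPLICIT_LE.encode(), b"\x00")),
    ])
    body = b"".join([
        _element(*TAG_SOP_CLASS, b"UI", _pad(SOP_CLASS_CT.encode(), b"\x00")),
        _element(*TAG_SOP_INSTANCE, b"UI", _pad(sop_uid.encode(), b"\x00")),
        _element(*TAG_SLICE_THICKNESS, b"DS", _ds(slice_thickness)),
        _element(*TAG_SERIES_UID, b"UI", _pad(series_uid.encode(), b"\x00")),
        _element(*TAG_INSTANCE_NUMBER, b"IS", _pad(str(instance).encode())),
        _element(*TAG_IMAGE_POSITION, b"DS", _ds(*position)),
        _element(*TAG_IMAGE_ORIENTATION, b"DS", _ds(1, 0, 0, 0, 1, 0)),
        _element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
        _element(0x0028, 0x0004, b"CS", _pad(b"MONOCHROME2")),
        _element(*TAG_ROWS, b"US", struct.pack("<H", rows)),
        _element(*TAG_COLS, b"US", struct.pack("<H", cols)),
        _element(*TAG_PIXEL_SPACING, b"DS", _ds(*pixel_spacing)),
        _element(*TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16)),
        _element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
        _element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
        _element(*TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 1)),
        _element(*TAG_RESCALE_INTERCEPT, b"DS", _ds(intercept)),
        _element(*TAG_RESCALE_SLOPE, b"DS", _ds(slope)),
        _element(*TAG_PIXEL_DATA, b"OW",
                 np.ascontiguousarray(pixels, dtype="<i2").tobytes()),
    ])
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta))))
        fh.write(meta)
        fh.write(body)


def read_slice(path: str) -> dict:
    """Parse one explicit-VR-little-endian DICOM file into a tag dictionary."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM part-10 file")
    pos = 132
    elements: dict[tuple[int, int], bytes] = {}
    while pos + 8 <= len(data):
        group, elem = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4:pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            start = pos + 8
        if vr == b"SQ" or length == 0xFFFFFFFF:
            raise ValueError(f"{path}: sequences/undefined lengths unsupported")
        elements[(group, elem)] = data[start:start + length]
        pos = start + length
    if (0x0002, 0x0010) in elements:
        ts = elements[(0x0002, 0x0010)].rstrip(b"\x00 ").decode()
        if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
            raise ValueError(f"{path}: unsupported transfer syntax {ts}")

    def req(tag, name):
        if tag not in elements:
            raise ValueError(f"{path}: missing required DICOM tag {name}")
        return elements[tag]

    def ds_values(raw: bytes):
        return [float(v) for v in raw.decode().strip("\x00 ").split("\\")]

    rows = struct.unpack("<H", req(TAG_ROWS, "Rows"))[0]
    cols = struct.unpack("<H", req(TAG_COLS, "Columns"))[0]
    signed = struct.unpack("<H", req(TAG_PIXEL_REPRESENTATION,
                                     "PixelRepresentation"))[0]
    dtype = "<i2" if signed else "<u2"
    pixels = np.frombuffer(req(TAG_PIXEL_DATA, "PixelData"),
                           dtype=dtype).reshape(rows, cols)
    return {
        "position": ds_values(req(TAG_IMAGE_POSITION, "ImagePositionPatient")),
        "pixel_spacing": ds_values(req(TAG_PIXEL_SPACING, "PixelSpacing")),
        "slice_thickness": ds_values(req(TAG_SLICE_THICKNESS, "SliceThickness"))[0],
        "slope": ds_values(elements.get(TAG_RESCALE_SLOPE, b"1"))[0],
        "intercept": ds_values(elements.get(TAG_RESCALE_INTERCEPT, b"0"))[0],
        "instance": int(elements.get(TAG_INSTANCE_NUMBER, b"0").decode().strip("\x00 ") or 0),
        "pixels": pixels,
    }


def write_series(directory: str, voxels_hu: np.ndarray, spacing, origin,
                 slope: float = 1.0, intercept: float = -1024.0,
                 series_uid: str = "1.2.826.0.1.3680043.9999.1") -> list[str]:
    """Write a volume (axes x, y, z; HU) as one DICOM file per axial slice.

    Stored pixel values are ``(HU - intercept) / slope`` rounded to int16; the
    per-slice ImagePositionPatient encodes the centre of the first pixel.
    """
    os.makedirs(directory, exist_ok=True)
    dx, dy, dz = spacing
    paths = []
    for k in range(voxels_hu.shape[2]):
        stored = np.round((voxels_hu[:, :, k].astype(np.float64) - intercept)
                          / slope).astype(np.int16)
        pos = (origin[0] + 0.5 * dx, origin[1] + 0.5 * dy,
               origin[2] + (k + 0.5) * dz)
        path = os.path.join(directory, f"slice_{k:04d}.dcm")
        # DICOM pixel matrix is rows (y) by columns (x)
        _write_slice(path, stored.T, pos, (dy, dx), dz, slope, intercept,
                     series_uid, k + 1)
        paths.append(path)
    return paths


def read_series(directory: str):
    """Read every .dcm file in a directory into (voxels_hu, spacing, origin).

    Slices are ordered by their craniocaudal position, never by filename.
    Raises if geometry tags are missing or inter-slice gaps are inconsistent
    beyond 10%.
    """
    files = sorted(os.path.join(directory, f) for f in os.listdir(directory)
                   if f.lower().endswith(".dcm"))
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    slices = [(read_slice(f), f) for f in files]
    slices.sort(key=lambda sf: sf[0]["position"][2])
    zs = np.array([s["position"][2] for s, _ in slices])
    if len(slices) > 1:
        gaps = np.diff(zs)
        median_gap = float(np.median(gaps))
        if median_gap <= 0:
            raise ValueError("duplicate or non-increasing slice positions")
        bad = np.nonzero(np.abs(gaps - median_gap) > 0.1 * median_gap)[0]
        if bad.size:
            raise ValueError(
                f"inconsistent inter-slice gap at {slices[bad[0] + 1][1]}: "
                f"{gaps[bad[0]]:.3f} mm vs median {median_gap:.3f} mm")
        dz = median_gap
    else:
        dz = slices[0][0]["slice_thickness"]
    first = slices[0][0]
    dy, dx = first["pixel_spacing"]
    vol = np.stack(
        [s["slope"] * s["pixels"].T.astype(np.float64) + s["intercept"]
         for s, _ in slices], axis=2)
    origin = (first["position"][0] - 0.5 * dx,
              first["position"][1] - 0.5 * dy,
              first["position"][2] - 0.5 * dz)
    return vol.astype(np.float32), (dx, dy, dz), origin
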