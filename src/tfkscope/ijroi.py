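"""Minimal ImageJ ROI (.roi / RoiSet .zip) reader and writer.

Implements the subset of the ImageJ ROI binary layout this package needs:
polygon, freehand/traced (read as polygons), rectangle and oval ROIs.
Coordinates follow the ImageJ convention (x = column, y = row, origin at
the top-left pixel corner).  ROI names are taken from / written to the zip
member filenames, which is how ImageJ's ROI Manager labels a RoiSet.
"""

from __future__ import annotations

import io
import struct
import zipfile

import numpy as np

_MAGIC = b"Iout"
_VERSION = 227

# ImageJ ROI type codes
POLYGON = 0
RECT = 1
OVAL = 2
FREEHAND = 7
TRACED = 8
_POLYGON_LIKE = (POLYGON, FREEHAND, TRACED)


def encode_roi(xs, ys, roi_type: int = POLYGON) -> bytes:
    """Encode a closed polygon (or bounding-box rect/oval) as .roi bytes."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    left, top = int(np.floor(xs.min())), int(np.floor(ys.min()))
    right, bottom = int(np.ceil(xs.max())), int(np.ceil(ys.max()))
    n = 0 if roi_type in (RECT, OVAL) else len(xs)
    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = roi_type
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = b""
    if n:
        rel_x = np.round(xs - left).astype(">i2")
        rel_y = np.round(ys - top).astype(">i2")
        body = rel_x.tobytes() + rel_y.tobytes()
    return bytes(header) + body


def decode_roi(data: bytes) -> dict:
    """Decode .roi bytes to a dict with type, bounds and absolute coords."""
    if data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack_from(">hhhh", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    out = {
        "type": roi_type,
        "top": top, "left": left, "bottom": bottom, "right": right,
    }
    if roi_type in _POLYGON_LIKE and n > 0:
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=64)
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n)
        out["x"] = xs.astype(float) + left
        out["y"] = ys.astype(float) + top
    elif roi_type not in (RECT, OVAL):
        raise ValueError(f"unsupported ImageJ ROI type code {roi_type}")
    return out


def read_roi_file(path) -> dict[str, dict]:
    """Read a single .roi file or a RoiSet .zip; returns name -> roi dict."""
    path = str(path)
    if zipfile.is_zipfile(path):
        rois: dict[str, dict] = {}
        with zipfile.ZipFile(path) as zf:
            for member in sorted(zf.namelist()):
                if not member.lower().endswith(".roi"):
                    continue
                name = member[:-4].split("/")[-1]
                rois[name] = decode_roi(zf.read(member))
        return rois
    with open(path, "rb") as fh:
        data = fh.read()
    name = path.rsplit("/", 1)[-1]
    name = name[:-4] if name.lower().endswith(".roi") else name
    return {name: decode_roi(data)}


def write_roi_zip(path, rois: dict[str, tuple]) -> None:
    """Write named polygon ROIs as a RoiSet zip.

    ``rois`` maps name -> (xs, ys) vertex arrays in ImageJ (x, y) order.
    """
    with zipfile.ZipFile(str(path), "w", zipfile.ZIP_DEFLATED) as zf:
        for name, (xs, ys) in rois.items():
            zf.writestr(f"{name}.roi", encode_roi(xs, ys))


def write_roi_bytes_zip(path, rois: dict[str, bytes]) -> None:
    with zipfile.ZipFile(str(path), "w", zipfile.ZIP_DEFLATED) as zf:
        for name, data in rois.items():
            zf.writestr(f"{name}.roi", data)


def roi_to_xy(roi: dict, oval_vertices: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Vertex arrays for any supported ROI (rect/oval are polygonized)."""
    if "x" in roi:
        return np.asarray(roi["x"], float), np.asarray(roi["y"], float)
    left, top = roi["left"], roi["top"]
    right, bottom = roi["right"], roi["bottom"]
    if roi["type"] == RECT:
        xs = np.array([left, right, right, left], float)
        ys = np.array([top, top, bottom, bottom], float)
        return xs, ys
    # oval inscribed in the bounding box
    t = np.linspace(0, 2 * np.pi, oval_vertices, endpoint=False)
    cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
    rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
    return cx + rx * np.cos(t), cy + ry * np.sin(t)


def _roi_buffer(xs, ys) -> bytes:
    buf = io.BytesIO()
    buf.write(encode_roi(xs, ys))
    return buf.getvalue()
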