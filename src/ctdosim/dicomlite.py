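"""Minimal DICOM part-10 reader/writer (explicit VR little endian only).

Covers the small tag subset needed for CT header mining and voxelization:
geometry tags, rescale tags, tube current, and uncompressed 16-bit pixel
data. Not a general DICOM implementation.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["Dataset", "read_file", "read_series", "write_ct_slice", "TAGS"]

_TRANSFER_SYNTAX_ELE = "1.2.840.10008.1.2.1"
_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"

# keyword -> (group, element, VR)
TAGS: dict[str, tuple[int, int, str]] = {
    "SOPClassUID": (0x0008, 0x0016, "UI"),
    "SOPInstanceUID": (0x0008, 0x0018, "UI"),
    "Modality": (0x0008, 0x0060, "CS"),
    "SliceThickness": (0x0018, 0x0050, "DS"),
    "KVP": (0x0018, 0x0060, "DS"),
    "XRayTubeCurrent": (0x0018, 0x1151, "IS"),
    "Exposure": (0x0018, 0x1152, "IS"),
    "StudyInstanceUID": (0x0020, 0x000D, "UI"),
    "SeriesInstanceUID": (0x0020, 0x000E, "UI"),
    "InstanceNumber": (0x0020, 0x0013, "IS"),
    "ImagePositionPatient": (0x0020, 0x0032, "DS"),
    "ImageOrientationPatient": (0x0020, 0x0037, "DS"),
    "SliceLocation": (0x0020, 0x1041, "DS"),
    "SamplesPerPixel": (0x0028, 0x0002, "US"),
    "PhotometricInterpretation": (0x0028, 0x0004, "CS"),
    "Rows": (0x0028, 0x0010, "US"),
    "Columns": (0x0028, 0x0011, "US"),
    "PixelSpacing": (0x0028, 0x0030, "DS"),
    "BitsAllocated": (0x0028, 0x0100, "US"),
    "BitsStored": (0x0028, 0x0101, "US"),
    "HighBit": (0x0028, 0x0102, "US"),
    "PixelRepresentation": (0x0028, 0x0103, "US"),
    "RescaleIntercept": (0x0028, 0x1052, "DS"),
    "RescaleSlope": (0x0028, 0x1053, "DS"),
    "PixelData": (0x7FE0, 0x0010, "OW"),
}
_TAG_TO_KEYWORD = {(g, e): (k, vr) for k, (g, e, vr) in TAGS.items()}

_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}


class Dataset(dict):
    """Keyword-keyed DICOM dataset; ``pixel_array`` holds decoded pixels."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as exc:
            raise AttributeError(name) from exc


def _encode_value(vr: str, value) -> bytes:
    if vr in ("UI", "CS", "DS", "IS", "LO", "SH", "DA", "TM", "PN"):
        if isinstance(value, (list, tuple, np.ndarray)):
            text = "\\".join(_fmt(vr, v) for v in value)
        else:
            text = _fmt(vr, value)
        raw = text.encode("ascii")
        if len(raw) % 2:
            raw += b"\x00" if vr == "UI" else b" "
        return raw
    if vr == "US":
        return struct.pack("<H", int(value))
    if vr == "UL":
        return struct.pack("<I", int(value))
    if vr == "OB":
        raw = bytes(value)
        return raw + b"\x00" * (len(raw) % 2)
    if vr == "OW":
        return np.asarray(value).astype("<u2").tobytes()
    raise ValueError(f"unsupported VR {vr}")


def _fmt(vr: str, v) -> str:
    if vr == "DS":
        s = f"{float(v):.10g}"
        return s
    if vr == "IS":
        return str(int(v))
    return str(v)


def _encode_element(group: int, element: int, vr: str, value) -> bytes:
    raw = _encode_value(vr, value)
    head = struct.pack("<HH", group, element) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(raw)) + raw
    return head + struct.pack("<H", len(raw)) + raw


def write_ct_slice(path, elements: dict, pixel_array: np.ndarray | None = None) -> None:
    """Write one CT slice as explicit-VR-LE part-10 DICOM.

    ``elements`` maps tag keywords (see ``TAGS``) to values; geometry and
    pixel-description tags are the caller's responsibility.
    """
    ds = dict(elements)
    ds.setdefault("SOPClassUID", _CT_SOP_CLASS)
    ds.setdefault("Modality", "CT")
    if pixel_array is not None:
        ds["Rows"], ds["Columns"] = pixel_array.shape
        ds.setdefault("BitsAllocated", 16)
        ds.setdefault("BitsStored", 16)
        ds.setdefault("HighBit", 15)
        ds.setdefault("PixelRepresentation", 0)
        ds.setdefault("SamplesPerPixel", 1)
        ds.setdefault("PhotometricInterpretation", "MONOCHROME2")
        ds["PixelData"] = pixel_array

    body = b""
    for keyword in sorted(ds, key=lambda k: TAGS[k][:2]):
        group, element, vr = TAGS[keyword]
        body += _encode_element(group, element, vr, ds[keyword])

    meta = (_encode_element(0x0002, 0x0001, "OB", b"\x00\x01")
            + _encode_element(0x0002, 0x0002, "UI", ds["SOPClassUID"])
            + _encode_element(0x0002, 0x0003, "UI", ds.get("SOPInstanceUID", "0"))
            + _encode_element(0x0002, 0x0010, "UI", _TRANSFER_SYNTAX_ELE)
            + _encode_element(0x0002, 0x0012, "UI", "2.25.4242"))
    meta = _encode_element(0x0002, 0x0000, "UL", len(meta)) + meta

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def _decode_value(vr: str, raw: bytes):
    if vr in ("UI", "CS", "LO", "SH", "DA", "TM", "PN"):
        return raw.decode("ascii", errors="replace").rstrip(" \x00")
    if vr == "DS":
        parts = raw.decode("ascii").rstrip(" \x00").split("\\")
        vals = [float(p) for p in parts if p]
        return vals if len(vals) > 1 else vals[0]
    if vr == "IS":
        parts = raw.decode("ascii").rstrip(" \x00").split("\\")
        vals = [int(p) for p in parts if p]
        return vals if len(vals) > 1 else vals[0]
    if vr == "US":
        return struct.unpack("<H", raw[:2])[0]
    if vr == "UL":
        return struct.unpack("<I", raw[:4])[0]
    return raw


def read_file(path, headers_only: bool = False) -> Dataset:
    """Parse an explicit-VR-LE part-10 file into a `Dataset`."""
    data = Path(path).read_bytes()
    if data[128:132] != b"DICM":
        raise ValueError(f"{path}: not a part-10 DICOM file")
    ds = Dataset()
    pos = 132
    n = len(data)
    while pos + 8 <= n:
        group, element = struct.unpack_from("<HH", data, pos)
        vr = data[pos + 4:pos + 6].decode("ascii")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", data, pos + 8)
            value_pos = pos + 12
        else:
            (length,) = struct.unpack_from("<H", data, pos + 6)
            value_pos = pos + 8
        raw = data[value_pos:value_pos + length]
        pos = value_pos + length
        if group == 0x0002:
            continue  # file meta: already implied by this reader
        key_vr = _TAG_TO_KEYWORD.get((group, element))
        if key_vr is None:
            continue
        keyword, expected_vr = key_vr
        if keyword == "PixelData":
            if not headers_only:
                ds["_pixel_raw"] = raw
        else:
            ds[keyword] = _decode_value(vr, raw)

    if "_pixel_raw" in ds:
        dtype = "<i2" if ds.get("PixelRepresentation", 0) == 1 else "<u2"
        arr = np.frombuffer(ds.pop("_pixel_raw"), dtype=dtype)
        ds["pixel_array"] = arr.reshape(ds["Rows"], ds["Columns"]).astype(np.int32)
    return ds


def read_series(directory, headers_only: bool = False) -> list[Dataset]:
    """Read every ``*.dcm`` file in a directory, sorted by slice z position."""
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no .dcm files in {directory}")
    series = [read_file(f, headers_only=headers_only) for f in files]
    series.sort(key=lambda ds: float(ds["ImagePositionPatient"][2])
                if "ImagePositionPatient" in ds else 0.0)
    return series
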