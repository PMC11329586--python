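"""Minimal DICOM Part-10 codec (little-endian, explicit or implicit VR).

Covers exactly what a metadata audit needs: reading tagged header
elements and writing small standards-shaped files for fixtures. Pixel
data is carried opaquely; no sequences, no big-endian, no compressed
transfer syntaxes.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Any, Optional

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1462.1"

# VRs whose explicit encoding uses 2 reserved bytes + 4-byte length.
_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST",
               "TM", "UI", "UR", "UT"}

# tag -> (VR, keyword); doubles as the implicit-VR dictionary.
DICT: dict[tuple[int, int], tuple[str, str]] = {
    (0x0008, 0x0016): ("UI", "SOPClassUID"),
    (0x0008, 0x0018): ("UI", "SOPInstanceUID"),
    (0x0008, 0x002A): ("DT", "AcquisitionDateTime"),
    (0x0008, 0x0060): ("CS", "Modality"),
    (0x0008, 0x0070): ("LO", "Manufacturer"),
    (0x0008, 0x103E): ("LO", "SeriesDescription"),
    (0x0010, 0x0010): ("PN", "PatientName"),
    (0x0010, 0x0020): ("LO", "PatientID"),
    (0x0018, 0x0021): ("CS", "SequenceVariant"),
    (0x0018, 0x0050): ("DS", "SliceThickness"),
    (0x0018, 0x0080): ("DS", "RepetitionTime"),
    (0x0018, 0x0081): ("DS", "EchoTime"),
    (0x0018, 0x0086): ("IS", "EchoNumbers"),
    (0x0018, 0x0087): ("DS", "MagneticFieldStrength"),
    (0x0018, 0x0089): ("IS", "NumberOfPhaseEncodingSteps"),
    (0x0018, 0x0091): ("IS", "EchoTrainLength"),
    (0x0018, 0x0095): ("DS", "PixelBandwidth"),
    (0x0018, 0x1030): ("LO", "ProtocolName"),
    (0x0018, 0x1100): ("DS", "ReconstructionDiameter"),
    (0x0018, 0x1120): ("DS", "GantryDetectorTilt"),
    (0x0018, 0x1312): ("CS", "InPlanePhaseEncodingDirection"),
    (0x0018, 0x1314): ("DS", "FlipAngle"),
    (0x0020, 0x000D): ("UI", "StudyInstanceUID"),
    (0x0020, 0x000E): ("UI", "SeriesInstanceUID"),
    (0x0020, 0x0011): ("IS", "SeriesNumber"),
    (0x0020, 0x0013): ("IS", "InstanceNumber"),
    (0x0028, 0x0002): ("US", "SamplesPerPixel"),
    (0x0028, 0x0010): ("US", "Rows"),
    (0x0028, 0x0011): ("US", "Columns"),
    (0x0028, 0x0100): ("US", "BitsAllocated"),
    (0x0028, 0x0101): ("US", "BitsStored"),
    (0x0028, 0x0102): ("US", "HighBit"),
    (0x0028, 0x0103): ("US", "PixelRepresentation"),
    (0x0029, 0x0010): ("LO", "PrivateCreator"),
    (0x0029, 0x1020): ("OB", "CSASeriesHeaderInfo"),
    (0x0054, 0x0081): ("US", "NumberOfSlices"),
    (0x7FE0, 0x0010): ("OW", "PixelData"),
}


class DicomParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# encoding

def _format_number(v: Any) -> str:
    if isinstance(v, int):
        return str(v)
    f = float(v)
    return repr(int(f)) if f.is_integer() else repr(f)


def _encode_value(vr: str, value: Any) -> bytes:
    if vr in ("OB", "OW", "UN"):
        raw = bytes(value)
        return raw + b"\x00" * (len(raw) % 2)
    if vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return b"".join(struct.pack("<H", int(v)) for v in vals)
    if vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return b"".join(struct.pack("<I", int(v)) for v in vals)
    if vr in ("DS", "IS"):
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(_format_number(v) for v in vals)
    else:
        vals = value if isinstance(value, (list, tuple)) else [value]
        text = "\\".join(str(v) for v in vals)
    raw = text.encode("ascii")
    if len(raw) % 2:
        raw += b"\x00" if vr == "UI" else b" "
    return raw


def _encode_element(group: int, elem: int, vr: str, value: Any,
                    explicit: bool) -> bytes:
    raw = _encode_value(vr, value)
    head = struct.pack("<HH", group, elem)
    if explicit:
        if vr in _LONG_VRS:
            return head + vr.encode() + b"\x00\x00" + struct.pack(
                "<I", len(raw)) + raw
        return head + vr.encode() + struct.pack("<H", len(raw)) + raw
    return head + struct.pack("<I", len(raw)) + raw


def write_dicom(path: Path | str,
                elements: dict[tuple[int, int], Any],
                transfer_syntax: str = EXPLICIT_VR_LE,
                sop_instance_uid: Optional[str] = None) -> None:
    """Write a Part-10 file: preamble, DICM magic, file meta, dataset.

    ``elements`` maps tag -> value; VRs come from the dictionary (UN for
    unknown tags). File meta is always explicit little-endian.
    """
    explicit = transfer_syntax != IMPLICIT_VR_LE
    sop_uid = sop_instance_uid or str(elements.get((0x0008, 0x0018), ""))

    meta_elems = [
        ((0x0002, 0x0001), "OB", b"\x00\x01"),
        ((0x0002, 0x0002), "UI", MR_IMAGE_STORAGE),
        ((0x0002, 0x0003), "UI", sop_uid),
        ((0x0002, 0x0010), "UI", transfer_syntax),
        ((0x0002, 0x0012), "UI", _IMPLEMENTATION_UID),
    ]
    meta_body = b"".join(
        _encode_element(g, e, vr, v, explicit=True)
        for (g, e), vr, v in meta_elems)
    meta = _encode_element(0x0002, 0x0000, "UL", len(meta_body),
                           explicit=True) + meta_body

    body = b"".join(
        _encode_element(g, e, DICT.get((g, e), ("UN", ""))[0], v, explicit)
        for (g, e), v in sorted(elements.items()))

    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + meta + body)


# ----------------------------------------------------------------------
# decoding

def _decode_value(vr: str, raw: bytes) -> Any:
    if vr in ("OB", "OW", "OF", "UN", "SQ"):
        return raw
    if vr == "US":
        n = len(raw) // 2
        vals = list(struct.unpack(f"<{n}H", raw[:2 * n]))
        return vals[0] if len(vals) == 1 else vals
    if vr == "UL":
        n = len(raw) // 4
        vals = list(struct.unpack(f"<{n}I", raw[:4 * n]))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FL":
        n = len(raw) // 4
        vals = list(struct.unpack(f"<{n}f", raw[:4 * n]))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FD":
        n = len(raw) // 8
        vals = list(struct.unpack(f"<{n}d", raw[:8 * n]))
        return vals[0] if len(vals) == 1 else vals
    text = raw.decode("ascii", errors="replace").rstrip(" \x00")
    if vr == "DS":
        parts = [float(p) for p in text.split("\\") if p.strip()]
        return parts[0] if len(parts) == 1 else parts
    if vr == "IS":
        parts = [int(p) for p in text.split("\\") if p.strip()]
        return parts[0] if len(parts) == 1 else parts
    if "\\" in text:
        return [p.strip() for p in text.split("\\")]
    return text.strip()


def _parse_elements(buf: bytes, offset: int, explicit: bool,
                    stop_before: Optional[int] = None,
                    stop_after_group: Optional[int] = None
                    ) -> tuple[dict[tuple[int, int], Any], int]:
    out: dict[tuple[int, int], Any] = {}
    n = len(buf)
    pos = offset
    while pos + 8 <= n:
        if stop_before is not None and pos >= stop_before:
            break
        group, elem = struct.unpack_from("<HH", buf, pos)
        if stop_after_group is not None and group != stop_after_group:
            break
        pos += 4
        if explicit:
            vr = buf[pos:pos + 2].decode("ascii", errors="replace")
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 4)
                pos += 8
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 2)
                pos += 4
        else:
            vr = DICT.get((group, elem), ("UN", ""))[0]
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        if length == 0xFFFFFFFF or pos + length > n:
            raise DicomParseError(
                f"element ({group:04X},{elem:04X}) overruns file")
        out[(group, elem)] = _decode_value(vr, buf[pos:pos + length])
        pos += length
    return out, pos


def read_dicom(path: Path | str) -> dict[tuple[int, int], Any]:
    """Parse a Part-10 file into a tag -> decoded-value map."""
    buf = Path(path).read_bytes()
    if len(buf) < 140 or buf[128:132] != b"DICM":
        # tolerate preamble-less files that still start with a plausible
        # little-endian element from an expected group
        if len(buf) >= 8 and struct.unpack_from("<H", buf, 0)[0] in (
                0x0002, 0x0008, 0x0010, 0x0018, 0x0020):
            return _read_headerless(buf)
        raise DicomParseError(f"not a DICOM file: {path}")
    try:
        meta, pos = _parse_elements(buf, 132, explicit=True,
                                    stop_after_group=0x0002)
        ts = meta.get((0x0002, 0x0010))
        if ts is None:
            raise DicomParseError("file meta lacks a transfer syntax "
                                  "(truncated?)")
        data, _ = _parse_elements(buf, pos, explicit=ts != IMPLICIT_VR_LE)
    except struct.error as exc:
        raise DicomParseError(f"truncated element: {exc}") from exc
    return data


def _read_headerless(buf: bytes) -> dict[tuple[int, int], Any]:
    for explicit in (True, False):
        try:
            data, end = _parse_elements(buf, 0, explicit=explicit)
        except (DicomParseError, struct.error, UnicodeDecodeError):
            continue
        if data and end == len(buf):
            return data
    raise DicomParseError("unparseable headerless candidate")


def is_dicom_file(path: Path | str) -> bool:
    """Extension-agnostic check: DICM magic or a parseable bare header."""
    p = Path(path)
    try:
        with open(p, "rb") as fh:
            head = fh.read(132)
    except OSError:
        return False
    if len(head) >= 132 and head[128:132] == b"DICM":
        return True
    try:
        read_dicom(p)
        return True
    except (DicomParseError, struct.error):
        return False
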