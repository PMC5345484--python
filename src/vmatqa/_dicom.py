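"""Minimal DICOM part-10 codec for the RT Plan subset this package needs.

Supports reading Explicit and Implicit VR Little Endian and writing Explicit
VR Little Endian.  A dataset is a plain ``dict`` mapping a 32-bit tag
(``group << 16 | element``) to a decoded Python value: ``str`` for text VRs,
``float``/``int`` (or lists thereof) for numeric VRs, ``list[dict]`` for
sequences, raw ``bytes`` for anything unrecognized.

This is not a general DICOM implementation; it covers exactly the elements
an RTPLAN reader/writer needs plus graceful skipping of everything else.
"""

from __future__ import annotations

import struct
from typing import Any

__all__ = ["Tag", "read_dicom", "write_dicom", "DicomError"]


class DicomError(ValueError):
    """Malformed or unsupported DICOM input."""


def _t(group: int, elem: int) -> int:
    return (group << 16) | elem


class Tag:
    """Tags used by the RT Plan reader/writer."""

    # file meta
    FileMetaGroupLength = _t(0x0002, 0x0000)
    FileMetaVersion = _t(0x0002, 0x0001)
    MediaStorageSOPClassUID = _t(0x0002, 0x0002)
    MediaStorageSOPInstanceUID = _t(0x0002, 0x0003)
    TransferSyntaxUID = _t(0x0002, 0x0010)
    ImplementationClassUID = _t(0x0002, 0x0012)
    # general
    SOPClassUID = _t(0x0008, 0x0016)
    SOPInstanceUID = _t(0x0008, 0x0018)
    Modality = _t(0x0008, 0x0060)
    PatientID = _t(0x0010, 0x0020)
    # RT plan
    RTPlanLabel = _t(0x300A, 0x0002)
    RTPlanName = _t(0x300A, 0x0003)
    FractionGroupSequence = _t(0x300A, 0x0070)
    NumberOfFractionsPlanned = _t(0x300A, 0x0078)
    BeamSequence = _t(0x300A, 0x00B0)
    BeamLimitingDeviceSequence = _t(0x300A, 0x00B6)
    RTBeamLimitingDeviceType = _t(0x300A, 0x00B8)
    NumberOfLeafJawPairs = _t(0x300A, 0x00BC)
    LeafPositionBoundaries = _t(0x300A, 0x00BE)
    BeamNumber = _t(0x300A, 0x00C0)
    BeamName = _t(0x300A, 0x00C2)
    BeamType = _t(0x300A, 0x00C4)
    RadiationType = _t(0x300A, 0x00C6)
    TreatmentDeliveryType = _t(0x300A, 0x00CE)
    FinalCumulativeMetersetWeight = _t(0x300A, 0x010E)
    NumberOfControlPoints = _t(0x300A, 0x0110)
    ControlPointSequence = _t(0x300A, 0x0111)
    ControlPointIndex = _t(0x300A, 0x0112)
    BeamLimitingDevicePositionSequence = _t(0x300A, 0x011A)
    LeafJawPositions = _t(0x300A, 0x011C)
    GantryAngle = _t(0x300A, 0x011E)
    GantryRotationDirection = _t(0x300A, 0x011F)
    CumulativeMetersetWeight = _t(0x300A, 0x0134)
    ReferencedBeamSequence = _t(0x300C, 0x0004)
    ReferencedBeamNumber = _t(0x300C, 0x0006)
    BeamMeterset = _t(0x300A, 0x0086)

    # sequence delimiters
    Item = _t(0xFFFE, 0xE000)
    ItemDelimiter = _t(0xFFFE, 0xE00D)
    SequenceDelimiter = _t(0xFFFE, 0xE0DD)


EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.8.498.1"

# VR per known tag; needed to decode values and to parse Implicit VR streams.
_VR: dict[int, str] = {
    Tag.FileMetaGroupLength: "UL",
    Tag.FileMetaVersion: "OB",
    Tag.MediaStorageSOPClassUID: "UI",
    Tag.MediaStorageSOPInstanceUID: "UI",
    Tag.TransferSyntaxUID: "UI",
    Tag.ImplementationClassUID: "UI",
    Tag.SOPClassUID: "UI",
    Tag.SOPInstanceUID: "UI",
    Tag.Modality: "CS",
    Tag.PatientID: "LO",
    Tag.RTPlanLabel: "SH",
    Tag.RTPlanName: "LO",
    Tag.FractionGroupSequence: "SQ",
    Tag.NumberOfFractionsPlanned: "IS",
    Tag.BeamSequence: "SQ",
    Tag.BeamLimitingDeviceSequence: "SQ",
    Tag.RTBeamLimitingDeviceType: "CS",
    Tag.NumberOfLeafJawPairs: "IS",
    Tag.LeafPositionBoundaries: "DS",
    Tag.BeamNumber: "IS",
    Tag.BeamName: "LO",
    Tag.BeamType: "CS",
    Tag.RadiationType: "CS",
    Tag.TreatmentDeliveryType: "CS",
    Tag.FinalCumulativeMetersetWeight: "DS",
    Tag.NumberOfControlPoints: "IS",
    Tag.ControlPointSequence: "SQ",
    Tag.ControlPointIndex: "IS",
    Tag.BeamLimitingDevicePositionSequence: "SQ",
    Tag.LeafJawPositions: "DS",
    Tag.GantryAngle: "DS",
    Tag.GantryRotationDirection: "CS",
    Tag.CumulativeMetersetWeight: "DS",
    Tag.ReferencedBeamSequence: "SQ",
    Tag.ReferencedBeamNumber: "IS",
    Tag.BeamMeterset: "DS",
}

_TEXT_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST", "TM", "UI", "UT"}
_SHORT_LEN_VRS = {
    "AE", "AS", "AT", "CS", "DA", "DS", "DT", "FL", "FD", "IS", "LO", "LT",
    "PN", "SH", "SL", "SS", "ST", "TM", "UI", "UL", "US",
}
_UNDEFINED = 0xFFFFFFFF


def _decode(vr: str, raw: bytes) -> Any:
    if vr in _TEXT_VRS:
        return raw.decode("ascii", errors="replace").rstrip(" \x00")
    if vr == "DS":
        text = raw.decode("ascii", errors="replace").strip(" \x00")
        if not text:
            return []
        vals = [float(v) for v in text.split("\\")]
        return vals[0] if len(vals) == 1 else vals
    if vr == "IS":
        text = raw.decode("ascii", errors="replace").strip(" \x00")
        if not text:
            return []
        vals = [int(v) for v in text.split("\\")]
        return vals[0] if len(vals) == 1 else vals
    if vr == "UL":
        return struct.unpack("<L", raw)[0] if len(raw) == 4 else raw
    if vr == "US":
        return struct.unpack("<H", raw)[0] if len(raw) == 2 else raw
    if vr == "FD":
        vals = list(struct.unpack(f"<{len(raw) // 8}d", raw))
        return vals[0] if len(vals) == 1 else vals
    return raw


def _encode(vr: str, value: Any) -> bytes:
    if vr in _TEXT_VRS:
        raw = str(value).encode("ascii")
        pad = b"\x00" if vr == "UI" else b" "
    elif vr in ("DS", "IS"):
        if not isinstance(value, (list, tuple)):
            value = [value]
        if vr == "DS":
            parts = [f"{float(v):.10g}" for v in value]
        else:
            parts = [str(int(v)) for v in value]
        raw = "\\".join(parts).encode("ascii")
        pad = b" "
    elif vr == "UL":
        raw, pad = struct.pack("<L", int(value)), b""
    elif vr == "US":
        raw, pad = struct.pack("<H", int(value)), b""
    elif vr == "FD":
        if not isinstance(value, (list, tuple)):
            value = [value]
        raw, pad = struct.pack(f"<{len(value)}d", *[float(v) for v in value]), b""
    elif vr == "OB":
        raw, pad = bytes(value), b"\x00"
    else:
        raw, pad = bytes(value), b"\x00"
    if len(raw) % 2:
        raw += pad
    return raw


class _Reader:
    def __init__(self, buf: bytes, explicit: bool):
        self.buf = buf
        self.pos = 0
        self.explicit = explicit

    def eof(self) -> bool:
        return self.pos >= len(self.buf)

    def _u16(self) -> int:
        v = struct.unpack_from("<H", self.buf, self.pos)[0]
        self.pos += 2
        return v

    def _u32(self) -> int:
        v = struct.unpack_from("<L", self.buf, self.pos)[0]
        self.pos += 4
        return v

    def read_tag(self) -> int:
        group = self._u16()
        elem = self._u16()
        return _t(group, elem)

    def read_element(self) -> tuple[int, str, int]:
        """Return (tag, vr, value_length); caller consumes the value."""
        tag = self.read_tag()
        if tag in (Tag.Item, Tag.ItemDelimiter, Tag.SequenceDelimiter):
            return tag, "NA", self._u32()
        if self.explicit:
            vr = self.buf[self.pos : self.pos + 2].decode("ascii")
            self.pos += 2
            if vr in _SHORT_LEN_VRS:
                length = self._u16()
            else:
                self.pos += 2  # reserved
                length = self._u32()
        else:
            vr = _VR.get(tag, "UN")
            length = self._u32()
            if length == _UNDEFINED:
                vr = "SQ"
        return tag, vr, length

    def read_dataset(self, end: int | None = None) -> dict[int, Any]:
        ds: dict[int, Any] = {}
        stop = len(self.buf) if end is None else end
        while self.pos < stop:
            mark = self.pos
            tag, vr, length = self.read_element()
            if tag == Tag.ItemDelimiter:
                break
            if tag == Tag.Item:  # stray item outside a sequence
                raise DicomError(f"unexpected item tag at byte {mark}")
            if vr == "SQ":
                ds[tag] = self.read_sequence(length)
            elif length == _UNDEFINED:
                raise DicomError(f"undefined length on non-sequence tag {tag:08X}")
            else:
                raw = self.buf[self.pos : self.pos + length]
                if len(raw) != length:
                    raise DicomError(f"truncated value for tag {tag:08X}")
                self.pos += length
                ds[tag] = _decode(vr, raw)
        return ds

    def read_sequence(self, length: int) -> list[dict[int, Any]]:
        items: list[dict[int, Any]] = []
        end = None if length == _UNDEFINED else self.pos + length
        while (end is None and self.pos < len(self.buf)) or (
            end is not None and self.pos < end
        ):
            tag, _, item_len = self.read_element()
            if tag == Tag.SequenceDelimiter:
                break
            if tag != Tag.Item:
                raise DicomError(f"expected sequence item, got tag {tag:08X}")
            if item_len == _UNDEFINED:
                items.append(self.read_dataset(None))
            else:
                items.append(self.read_dataset(self.pos + item_len))
        return items


def read_dicom(path: str) -> dict[int, Any]:
    """Read a part-10 DICOM file into a tag->value dict (file meta merged in)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError(f"{path}: not a DICOM part-10 file (missing DICM magic)")
    meta_reader = _Reader(buf, explicit=True)
    meta_reader.pos = 132
    tag, vr, length = meta_reader.read_element()
    if tag != Tag.FileMetaGroupLength:
        raise DicomError(f"{path}: file meta group length element missing")
    group_len = _decode(vr, buf[meta_reader.pos : meta_reader.pos + length])
    meta_reader.pos += length
    meta = meta_reader.read_dataset(meta_reader.pos + int(group_len))
    syntax = meta.get(Tag.TransferSyntaxUID, EXPLICIT_VR_LE)
    if syntax not in (EXPLICIT_VR_LE, IMPLICIT_VR_LE):
        raise DicomError(f"{path}: unsupported transfer syntax {syntax!r}")
    body = _Reader(buf, explicit=(syntax == EXPLICIT_VR_LE))
    body.pos = meta_reader.pos
    ds = body.read_dataset()
    ds.update(meta)
    return ds


def _write_element(out: bytearray, tag: int, value: Any) -> None:
    vr = _VR.get(tag)
    if vr is None:
        raise DicomError(f"cannot write tag {tag:08X}: no VR registered")
    out += struct.pack("<HH", tag >> 16, tag & 0xFFFF)
    if vr == "SQ":
        body = bytearray()
        for item in value:
            item_body = bytearray()
            for k in sorted(item):
                _write_element(item_body, k, item[k])
            body += struct.pack("<HHL", 0xFFFE, 0xE000, len(item_body))
            body += item_body
        out += b"SQ\x00\x00" + struct.pack("<L", len(body)) + body
        return
    raw = _encode(vr, value)
    if vr in _SHORT_LEN_VRS:
        out += vr.encode("ascii") + struct.pack("<H", len(raw)) + raw
    else:
        out += vr.encode("ascii") + b"\x00\x00" + struct.pack("<L", len(raw)) + raw


def write_dicom(path: str, dataset: dict[int, Any]) -> None:
    """Write a dataset as Explicit VR Little Endian part-10 file.

    ``dataset`` holds body elements only; file meta is derived from the
    SOP class/instance UIDs present in the dataset.
    """
    sop_class = dataset.get(Tag.SOPClassUID, RTPLAN_SOP_CLASS)
    sop_instance = dataset.get(Tag.SOPInstanceUID, _IMPLEMENTATION_UID + ".0")
    meta = bytearray()
    for tag, value in (
        (Tag.FileMetaVersion, b"\x00\x01"),
        (Tag.MediaStorageSOPClassUID, sop_class),
        (Tag.MediaStorageSOPInstanceUID, sop_instance),
        (Tag.TransferSyntaxUID, EXPLICIT_VR_LE),
        (Tag.ImplementationClassUID, _IMPLEMENTATION_UID),
    ):
        _write_element(meta, tag, value)
    out = bytearray(b"\x00" * 128 + b"DICM")
    _write_element(out, Tag.FileMetaGroupLength, len(meta))
    out += meta
    for tag in sorted(dataset):
        if tag >> 16 == 0x0002:
            continue
        _write_element(out, tag, dataset[tag])
    with open(path, "wb") as fh:
        fh.write(bytes(out))
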