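"""Minimal DICOM data model for the benchmark.

Backed by pydicom for Part-10 serialization, the data dictionary and
private-block bookkeeping.  The benchmark fixes the transfer syntax to
Explicit VR Little Endian, uncompressed, single frame: every file the toolkit
writes is readable by any DICOM implementation, and every file it scores must
be in that encoding (compressed candidates are rejected, not silently
decoded).

Also hosts the modality attribute-type profiles (which attributes are
mandatory, per SOP class) and the private-attribute dictionary with its
process-operation descriptions (kept / hashed / offset / deleted / emptied).
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.datadict import dictionary_VR, dictionary_description
from pydicom.tag import Tag
from pydicom.uid import ExplicitVRLittleEndian

from .tags import TagPath, TagError, parse_tag, format_tag

__all__ = [
    "Element",
    "InstanceObject",
    "AttributeTypeCode",
    "ModalityProfile",
    "PrivateDictEntry",
    "UnsupportedFormatError",
    "VrError",
    "MODALITIES",
    "SOP_CLASS_UIDS",
    "validate_value",
    "read_instance",
    "write_instance",
    "resolve_private",
    "load_profiles",
    "load_private_dictionary",
    "attribute_type",
    "NOT_PROFILED",
    "validate_instance",
]

MODALITIES = ("CT", "MR", "PT", "DX", "CR", "MG", "SC")

SOP_CLASS_UIDS = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "MR": "1.2.840.10008.5.1.4.1.1.4",
    "PT": "1.2.840.10008.5.1.4.1.1.128",
    "DX": "1.2.840.10008.5.1.4.1.1.1.1",
    "CR": "1.2.840.10008.5.1.4.1.1.1",
    "MG": "1.2.840.10008.5.1.4.1.1.1.2",
    "SC": "1.2.840.10008.5.1.4.1.1.7",
}

_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1342.1"

TEXT_VRS = {"PN", "LO", "SH", "ST", "LT", "DA", "TM", "UI", "CS", "IS", "DS", "AE", "AS"}


class UnsupportedFormatError(ValueError):
    """Stream is not Part-10 Explicit VR Little Endian."""


class VrError(ValueError):
    """Value violates its value-representation constraints."""


# ---------------------------------------------------------------------------
# VR validation

_DA_RE = re.compile(r"^\d{8}$")
_UI_RE = re.compile(r"^[0-9.]+$")


def validate_value(vr: str, value: str | bytes | None) -> None:
    """Raise :class:`VrError` if *value* violates *vr*'s constraints.

    Empty values are legal for every VR (DICOM Type 2 semantics).  Only the
    constraints the benchmark relies on are enforced: calendar-valid DA,
    digits-and-dots UI (max 64 chars), ASCII throughout.
    """
    if value in (None, "", b""):
        return
    if isinstance(value, bytes):
        return
    text = str(value)
    try:
        text.encode("ascii")
    except UnicodeEncodeError as exc:
        raise VrError(f"non-ASCII value for VR {vr}: {text!r}") from exc
    for item in text.split("\\"):
        if vr == "DA":
            if not _DA_RE.match(item):
                raise VrError(f"DA value not YYYYMMDD: {item!r}")
            try:
                _dt.date(int(item[:4]), int(item[4:6]), int(item[6:8]))
            except ValueError as exc:
                raise VrError(f"DA value not a calendar date: {item!r}") from exc
        elif vr == "UI":
            if len(item) > 64 or not _UI_RE.match(item):
                raise VrError(f"invalid UID: {item!r}")
        elif vr in ("IS", "US"):
            if not re.match(r"^[+-]?\d+$", item.strip()):
                raise VrError(f"non-integer for VR {vr}: {item!r}")
        elif vr == "DS":
            try:
                float(item)
            except ValueError as exc:
                raise VrError(f"non-decimal for VR DS: {item!r}") from exc


@dataclass(frozen=True)
class Element:
    """Read-only view of one data element."""

    tag: TagPath
    vr: str
    value: str | bytes | None

    @property
    def multiplicity(self) -> int:
        if self.value in (None, "", b"") or isinstance(self.value, bytes):
            return 0 if self.value in (None, "", b"") else 1
        return str(self.value).count("\\") + 1


# ---------------------------------------------------------------------------
# Instance object


def _normalize(value) -> str | bytes | None:
    """pydicom element value -> plain str/bytes."""
    if value is None:
        return ""
    if isinstance(value, bytes):
        return value
    if isinstance(value, (list, pydicom.multival.MultiValue)):
        return "\\".join(str(v) for v in value)
    return str(value)


class InstanceObject:
    """One DICOM image instance: ordered header elements plus a pixel matrix.

    Thin wrapper over a :class:`pydicom.dataset.Dataset`; accessors speak
    :class:`~deidbench.tags.TagPath` so callers address private attributes by
    creator label rather than raw block-dependent element numbers.
    """

    def __init__(self, ds: Dataset):
        self.ds = ds

    # -- identity ----------------------------------------------------------
    @property
    def sop_class(self) -> str:
        return str(self.ds.Modality)

    @property
    def uids(self) -> tuple[str, str, str]:
        return (
            str(self.ds.StudyInstanceUID),
            str(self.ds.SeriesInstanceUID),
            str(self.ds.SOPInstanceUID),
        )

    @property
    def instance_uid(self) -> str:
        return str(self.ds.SOPInstanceUID)

    @property
    def patient_id(self) -> str:
        return str(self.ds.get("PatientID", ""))

    # -- pixels ------------------------------------------------------------
    @property
    def pixels(self) -> np.ndarray:
        rows, cols = int(self.ds.Rows), int(self.ds.Columns)
        return np.frombuffer(self.ds.PixelData, dtype="<u2").reshape(rows, cols)

    def set_pixels(self, arr: np.ndarray) -> None:
        if arr.ndim != 2 or arr.dtype != np.uint16:
            raise ValueError("pixels must be a 2-D uint16 array")
        self.ds.Rows, self.ds.Columns = arr.shape
        self.ds.PixelData = arr.astype("<u2").tobytes()

    # -- element access ----------------------------------------------------
    def _locate(self, tag: TagPath) -> Tag | None:
        if not tag.is_private:
            t = Tag(tag.group, tag.element)
            return t if t in self.ds else None
        for elem_no in range(0x10, 0x100):
            t = Tag(tag.group, elem_no)
            if t in self.ds and _normalize(self.ds[t].value).strip() == tag.creator:
                resolved = Tag(tag.group, tag.resolved_element(elem_no))
                return resolved if resolved in self.ds else None
        return None

    def get_element(self, tag: TagPath) -> Element | None:
        t = self._locate(tag)
        if t is None:
            return None
        el = self.ds[t]
        return Element(tag=tag, vr=el.VR, value=_normalize(el.value))

    def get_value(self, tag: TagPath) -> str | bytes | None:
        el = self.get_element(tag)
        return None if el is None else el.value

    def set_value(self, tag: TagPath, value: str | bytes, vr: str | None = None) -> None:
        """Create or overwrite an element; reserves a private block if needed."""
        if tag.is_private:
            if vr is None:
                vr = "LO"
            validate_value(vr, value)
            block = self.ds.private_block(tag.group, tag.creator, create=True)
            if tag.private_byte in block:
                del block[tag.private_byte]
            block.add_new(tag.private_byte, vr, value)
            return
        t = Tag(tag.group, tag.element)
        if vr is None:
            try:
                vr = dictionary_VR(t)
            except KeyError:
                vr = "LO"
        validate_value(vr, value)
        if vr in ("US",) and value not in ("", None):
            self.ds.add_new(t, vr, int(value))
        else:
            self.ds.add_new(t, vr, value)

    def delete(self, tag: TagPath) -> bool:
        t = self._locate(tag)
        if t is None:
            return False
        del self.ds[t]
        return True

    def iter_text_elements(self) -> Iterator[tuple[str, str]]:
        """Yield (tag-notation, text value) for every text-VR element,
        descending one level into sequences."""
        def walk(ds: Dataset, prefix: str = ""):
            for el in ds:
                if el.VR == "SQ":
                    for item in el.value or []:
                        yield from walk(item, prefix=f"{el.tag} ")
                    continue
                if el.VR in TEXT_VRS:
                    val = _normalize(el.value)
                    if isinstance(val, str) and val:
                        yield f"{prefix}({el.tag.group:04x},{el.tag.element:04x})", val
        yield from walk(self.ds)

    def copy(self) -> "InstanceObject":
        return read_instance(write_instance(self))

    def __eq__(self, other) -> bool:
        return isinstance(other, InstanceObject) and write_instance(self) == write_instance(other)


def resolve_private(instance: InstanceObject, tag: TagPath) -> Element | None:
    """Look up a private attribute through its creator reservation.

    Scans the reservation elements ``(gggg,0010)..(gggg,00ff)`` for one whose
    value equals ``tag.creator``; absent reservation or absent element is a
    valid ``None`` result, never an error.
    """
    if not tag.is_private:
        raise TagError(f"resolve_private requires a private tag, got {tag}")
    return instance.get_element(tag)


# ---------------------------------------------------------------------------
# Part-10 read/write


def write_instance(instance: InstanceObject) -> bytes:
    """Serialize to a Part-10 stream (Explicit VR Little Endian).

    Deterministic: equal instances yield identical bytes; pydicom emits
    elements in ascending tag order.  Text elements are validated against
    their VR constraints first.
    """
    ds = instance.ds
    for el in ds:
        if el.VR in TEXT_VRS:
            validate_value(el.VR, _normalize(el.value))
    if "PixelData" in ds:
        expected = int(ds.Rows) * int(ds.Columns) * 2
        if len(ds.PixelData) != expected:
            raise VrError(
                f"pixel data length {len(ds.PixelData)} != Rows*Columns*2 = {expected}"
            )
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _IMPLEMENTATION_UID
    meta.ImplementationVersionName = "DEIDBENCH"
    ds.file_meta = meta
    buf = io.BytesIO()
    pydicom.dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


def read_instance(stream: bytes | str | Path) -> InstanceObject:
    """Parse a Part-10 stream; rejects non-DICOM and compressed encodings."""
    if isinstance(stream, (str, Path)):
        stream = Path(stream).read_bytes()
    if len(stream) < 132 or stream[128:132] != b"DICM":
        raise UnsupportedFormatError("missing DICM magic at offset 128")
    ds = pydicom.dcmread(io.BytesIO(stream))
    ts = ds.file_meta.TransferSyntaxUID
    if ts != ExplicitVRLittleEndian:
        raise UnsupportedFormatError(
            f"unsupported transfer syntax {ts} (only Explicit VR Little Endian)"
        )
    return InstanceObject(ds)


# ---------------------------------------------------------------------------
# Modality profiles (attribute types per SOP class)


@dataclass(frozen=True)
class AttributeTypeCode:
    """DICOM attribute requirement level: T1 required-with-value, T2
    required-may-be-empty, T3 optional, T1C/T2C conditional."""

    code: str

    VALID = ("T1", "T1C", "T2", "T2C", "T3")

    def __post_init__(self):
        if self.code not in self.VALID:
            raise ValueError(f"unknown attribute type {self.code!r}")


@dataclass(frozen=True)
class ProfileEntry:
    tag: TagPath
    name: str
    type_code: str  # T1 / T1C / T2 / T2C / T3
    modality: str  # "All" or a modality code
    rule: str  # value-generation rule id, "none" for conditionals


@dataclass
class ModalityProfile:
    sop_class: str
    entries: list[ProfileEntry] = field(default_factory=list)


NOT_PROFILED = "not_profiled"

_TYPE_MAP = {"1": "T1", "1C": "T1C", "2": "T2", "2C": "T2C", "3": "T3"}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("deidbench").joinpath("data").joinpath(name)))


def load_profiles(path: str | Path | None = None) -> list[ProfileEntry]:
    """Load the attribute-type profile table (tag, name, type, modality, rule)."""
    path = Path(path) if path else _data_path("modality_profiles.csv")
    out: list[ProfileEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ProfileEntry(
                    tag=parse_tag(row["tag"]),
                    name=row["name"],
                    type_code=_TYPE_MAP.get(row["type"], row["type"]),
                    modality=row["modality"],
                    rule=row["rule"],
                )
            )
    return out


def attribute_type(
    sop_class: str, tag: TagPath, profiles: list[ProfileEntry] | None = None
) -> str:
    """Requirement level of *tag* for *sop_class*; modality rows override
    the "All" row; returns :data:`NOT_PROFILED` for unknown tags."""
    if profiles is None:
        profiles = _default_profiles()
    result = NOT_PROFILED
    for entry in profiles:
        if entry.tag != tag:
            continue
        if entry.modality == sop_class:
            return entry.type_code
        if entry.modality == "All":
            result = entry.type_code
    return result


_PROFILE_CACHE: list[ProfileEntry] | None = None


def _default_profiles() -> list[ProfileEntry]:
    global _PROFILE_CACHE
    if _PROFILE_CACHE is None:
        _PROFILE_CACHE = load_profiles()
    return _PROFILE_CACHE


def profile_for(sop_class: str, profiles: list[ProfileEntry] | None = None) -> ModalityProfile:
    """Effective profile for a modality: "All" rows with modality overrides."""
    if profiles is None:
        profiles = _default_profiles()
    chosen: dict[TagPath, ProfileEntry] = {}
    for entry in profiles:
        if entry.modality == "All" and entry.tag not in chosen:
            chosen[entry.tag] = entry
    for entry in profiles:
        if entry.modality == sop_class:
            chosen[entry.tag] = entry
    return ModalityProfile(sop_class=sop_class, entries=sorted(chosen.values(), key=lambda e: e.tag))


def validate_instance(
    instance: InstanceObject, profiles: list[ProfileEntry] | None = None
) -> list[str]:
    """Profile-compliance violations: missing/empty T1, absent T2."""
    prof = profile_for(instance.sop_class, profiles)
    problems: list[str] = []
    for entry in prof.entries:
        if entry.type_code not in ("T1", "T2"):
            continue
        el = instance.get_element(entry.tag)
        if entry.type_code == "T1":
            if el is None or el.value in ("", b"", None):
                problems.append(f"T1 {entry.tag} {entry.name}: missing or empty")
        else:
            if el is None:
                problems.append(f"T2 {entry.tag} {entry.name}: absent")
    return problems


# ---------------------------------------------------------------------------
# Private-attribute dictionary


@dataclass(frozen=True)
class PrivateDictEntry:
    """Catalogue row for a private attribute: address, description, and the
    process-operation description applied during curation."""

    tag: TagPath
    description: str
    pod: str

    PODS = ("kept", "hashed", "offset", "deleted", "emptied")

    def __post_init__(self):
        if self.pod not in self.PODS:
            raise ValueError(f"unknown POD {self.pod!r}")


def load_private_dictionary(path: str | Path | None = None) -> list[PrivateDictEntry]:
    path = Path(path) if path else _data_path("private_dictionary.csv")
    out: list[PrivateDictEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PrivateDictEntry(
                    tag=parse_tag(row["tag"]),
                    description=row["description"],
                    pod=row["pod"],
                )
            )
    return out


def tag_name(tag: TagPath) -> str:
    """Human-readable attribute name (data dictionary, private catalogue, or
    the tag notation itself)."""
    if not tag.is_private:
        try:
            desc = dictionary_description(Tag(tag.group, tag.element))
        except KeyError:
            desc = ""
        if desc:
            return desc
    for entry in _private_dict_cached():
        if entry.tag == tag:
            return entry.description
    return format_tag(tag)


_PRIVATE_CACHE: list[PrivateDictEntry] | None = None


def _private_dict_cached() -> list[PrivateDictEntry]:
    global _PRIVATE_CACHE
    if _PRIVATE_CACHE is None:
        _PRIVATE_CACHE = load_private_dictionary()
    return _PRIVATE_CACHE
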