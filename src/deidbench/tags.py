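"""Addresses of standard and private DICOM attributes.

A standard attribute is addressed by (group, element). A private attribute is
addressed by (group, creator, byte): the vendor reserves a block inside an
odd-numbered group with a private-creator element ``(gggg,00xx)`` whose value
is the creator label, and the attribute then lives at element
``(xx << 8) | byte``. The textual notation follows common curation-log usage::

    (0010,0010)                    standard
    (0009,"GEMS_PETD_01",37)       private, creator GEMS_PETD_01, byte 0x37
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["TagPath", "TagError", "parse_tag", "format_tag"]


class TagError(ValueError):
    """Malformed tag notation or inconsistent tag fields."""


# straight or typographic quotes around the creator label
_STANDARD_RE = re.compile(r"^\(([0-9a-fA-F]{4}),([0-9a-fA-F]{4})\)$")
_PRIVATE_RE = re.compile(
    r"^\(([0-9a-fA-F]{4}),[\"“”]([^\"“”]+)[\"“”],([0-9a-fA-F]{1,2})\)$"
)


@dataclass(frozen=True, order=True)
class TagPath:
    """Address of a standard or private DICOM attribute.

    For a standard attribute ``element`` is set and ``creator``/``private_byte``
    are ``None``; for a private attribute the converse holds.  Private groups
    are odd, standard groups even.
    """

    group: int
    element: int | None = None
    creator: str | None = None
    private_byte: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.group <= 0xFFFF:
            raise TagError(f"group out of range: {self.group:#x}")
        if self.creator is not None:
            if self.group % 2 == 0:
                raise TagError(
                    f"creator notation on even (standard) group {self.group:04x}"
                )
            if self.private_byte is None or not 0 <= self.private_byte <= 0xFF:
                raise TagError("private_byte must be in [0x00, 0xFF]")
            if self.element is not None:
                raise TagError("private TagPath carries creator+byte, not element")
        else:
            if self.group % 2 == 1 and self.group > 8:
                # odd group without creator: allowed only for the raw
                # creator-reservation elements themselves, which callers
                # address as standard (group, element) pairs
                pass
            if self.element is None or not 0 <= self.element <= 0xFFFF:
                raise TagError("standard TagPath requires a 16-bit element")

    @property
    def is_private(self) -> bool:
        return self.creator is not None

    def resolved_element(self, block_hi: int) -> int:
        """Element number once the creator block ``(gggg,00xx)`` is known."""
        if not self.is_private:
            raise TagError("resolved_element applies to private tags only")
        return (block_hi << 8) | self.private_byte

    def __str__(self) -> str:
        return format_tag(self)


def parse_tag(text: str) -> TagPath:
    """Parse ``(gggg,eeee)`` or ``(gggg,"CREATOR",xx)`` notation.

    >>> parse_tag("(0010,0010)")
    TagPath(group=16, element=16, creator=None, private_byte=None)
    """
    m = _STANDARD_RE.match(text.strip())
    if m:
        return TagPath(group=int(m.group(1), 16), element=int(m.group(2), 16))
    m = _PRIVATE_RE.match(text.strip())
    if m:
        group = int(m.group(1), 16)
        if group % 2 == 0:
            raise TagError(f"creator notation on even group in {text!r}")
        return TagPath(
            group=group,
            creator=m.group(2),
            private_byte=int(m.group(3), 16),
        )
    raise TagError(f"malformed tag notation: {text!r}")


def format_tag(tag: TagPath) -> str:
    """Inverse of :func:`parse_tag` (round-trips)."""
    if tag.is_private:
        return f'({tag.group:04x},"{tag.creator}",{tag.private_byte:02x})'
    return f"({tag.group:04x},{tag.element:04x})"
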