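"""Built-in 5x7 bitmap font for pixel burn-in.

Glyphs are rendered as set/unset pixels only — no anti-aliasing — so tests
can enumerate exactly which pixels a burn-in touched.  Covers uppercase
letters, digits and the punctuation that appears in clinical annotations
(``^ . , - / # ( ) :`` and space).  Lowercase input is rendered uppercase.
"""

from __future__ import annotations

import numpy as np

__all__ = ["render_text", "GLYPH_H", "GLYPH_W", "LINE_LEADING", "FontError"]

GLYPH_W = 5
GLYPH_H = 7
LINE_LEADING = 2  # blank rows between lines
_TRACKING = 1  # blank columns between glyphs


class FontError(ValueError):
    """Text cannot be rendered (unknown glyph handled; rect too small not)."""


_RAW = {
    "A": ["01110", "10001", "10001", "11111", "10001", "10001", "10001"],
    "B": ["11110", "10001", "10001", "11110", "10001", "10001", "11110"],
    "C": ["01110", "10001", "10000", "10000", "10000", "10001", "01110"],
    "D": ["11110", "10001", "10001", "10001", "10001", "10001", "11110"],
    "E": ["11111", "10000", "10000", "11110", "10000", "10000", "11111"],
    "F": ["11111", "10000", "10000", "11110", "10000", "10000", "10000"],
    "G": ["01110", "10001", "10000", "10111", "10001", "10001", "01111"],
    "H": ["10001", "10001", "10001", "11111", "10001", "10001", "10001"],
    "I": ["01110", "00100", "00100", "00100", "00100", "00100", "01110"],
    "J": ["00111", "00010", "00010", "00010", "00010", "10010", "01100"],
    "K": ["10001", "10010", "10100", "11000", "10100", "10010", "10001"],
    "L": ["10000", "10000", "10000", "10000", "10000", "10000", "11111"],
    "M": ["10001", "11011", "10101", "10101", "10001", "10001", "10001"],
    "N": ["10001", "11001", "10101", "10011", "10001", "10001", "10001"],
    "O": ["01110", "10001", "10001", "10001", "10001", "10001", "01110"],
    "P": ["11110", "10001", "10001", "11110", "10000", "10000", "10000"],
    "Q": ["01110", "10001", "10001", "10001", "10101", "10010", "01101"],
    "R": ["11110", "10001", "10001", "11110", "10100", "10010", "10001"],
    "S": ["01111", "10000", "10000", "01110", "00001", "00001", "11110"],
    "T": ["11111", "00100", "00100", "00100", "00100", "00100", "00100"],
    "U": ["10001", "10001", "10001", "10001", "10001", "10001", "01110"],
    "V": ["10001", "10001", "10001", "10001", "10001", "01010", "00100"],
    "W": ["10001", "10001", "10001", "10101", "10101", "11011", "10001"],
    "X": ["10001", "10001", "01010", "00100", "01010", "10001", "10001"],
    "Y": ["10001", "10001", "01010", "00100", "00100", "00100", "00100"],
    "Z": ["11111", "00001", "00010", "00100", "01000", "10000", "11111"],
    "0": ["01110", "10001", "10011", "10101", "11001", "10001", "01110"],
    "1": ["00100", "01100", "00100", "00100", "00100", "00100", "01110"],
    "2": ["01110", "10001", "00001", "00010", "00100", "01000", "11111"],
    "3": ["11110", "00001", "00001", "01110", "00001", "00001", "11110"],
    "4": ["00010", "00110", "01010", "10010", "11111", "00010", "00010"],
    "5": ["11111", "10000", "11110", "00001", "00001", "10001", "01110"],
    "6": ["00110", "01000", "10000", "11110", "10001", "10001", "01110"],
    "7": ["11111", "00001", "00010", "00100", "01000", "01000", "01000"],
    "8": ["01110", "10001", "10001", "01110", "10001", "10001", "01110"],
    "9": ["01110", "10001", "10001", "01111", "00001", "00010", "01100"],
    " ": ["00000", "00000", "00000", "00000", "00000", "00000", "00000"],
    "^": ["00100", "01010", "10001", "00000", "00000", "00000", "00000"],
    ".": ["00000", "00000", "00000", "00000", "00000", "00100", "00100"],
    ",": ["00000", "00000", "00000", "00000", "00100", "00100", "01000"],
    "-": ["00000", "00000", "00000", "01110", "00000", "00000", "00000"],
    "/": ["00001", "00010", "00010", "00100", "01000", "01000", "10000"],
    "#": ["01010", "01010", "11111", "01010", "11111", "01010", "01010"],
    "(": ["00010", "00100", "01000", "01000", "01000", "00100", "00010"],
    ")": ["01000", "00100", "00010", "00010", "00010", "00100", "01000"],
    ":": ["00000", "00100", "00100", "00000", "00100", "00100", "00000"],
    "?": ["01110", "10001", "00001", "00010", "00100", "00000", "00100"],
}

_GLYPHS = {
    ch: np.array([[c == "1" for c in row] for row in rows], dtype=bool)
    for ch, rows in _RAW.items()
}


def _glyph(ch: str) -> np.ndarray:
    return _GLYPHS.get(ch.upper(), _GLYPHS["?"])


def render_text(text: str, scale: int = 1) -> np.ndarray:
    """Render (possibly multi-line) text to a boolean mask.

    Lines are stacked with a fixed leading of ``LINE_LEADING * scale`` rows.
    """
    if scale < 1:
        raise FontError("scale must be >= 1")
    lines = text.split("\n")
    line_masks = []
    for line in lines:
        if line:
            cols = []
            for k, ch in enumerate(line):
                if k:
                    cols.append(np.zeros((GLYPH_H, _TRACKING), dtype=bool))
                cols.append(_glyph(ch))
            mask = np.hstack(cols)
        else:
            mask = np.zeros((GLYPH_H, 1), dtype=bool)
        line_masks.append(mask)
    width = max(m.shape[1] for m in line_masks)
    rows = []
    for i, m in enumerate(line_masks):
        if i:
            rows.append(np.zeros((LINE_LEADING, width), dtype=bool))
        padded = np.zeros((GLYPH_H, width), dtype=bool)
        padded[:, : m.shape[1]] = m
        rows.append(padded)
    mask = np.vstack(rows)
    if scale > 1:
        mask = np.kron(mask, np.ones((scale, scale), dtype=bool))
    return mask
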