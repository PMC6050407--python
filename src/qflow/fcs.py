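"""Minimal FCS 3.0/3.1 list-mode codec.

Reads the subset of the FCS standard that modern analyzers emit: version
3.0 or 3.1, list mode (``$MODE/L``), datatype ``F`` (float32), ``D``
(float64) or ``I`` (unsigned integers of 8/16/32/64 bits), with
``$BYTEORD`` 1,2,3,4 (little-endian) or 4,3,2,1 (big-endian). FCS 2.0
files are rejected with a clear message. Writing exists to produce test
fixtures and simulator output: FCS 3.1, float32, little-endian.

Channel names come from ``$PnN``; when ``$PnS`` (the stain label) is
present it populates the event table's panel map.
"""

from __future__ import annotations

import numpy as np

from .io import EventTable, EventTableError

__all__ = ["FcsFormatError", "read_fcs", "write_fcs"]

_HEADER_LEN = 58  # 6-byte version + 4 spaces + 6 right-justified 8-byte offsets


class FcsFormatError(ValueError):
    """Malformed or unsupported FCS content; the message names the offender."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("TEXT segment is empty")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    if len(tokens) % 2 != 0:
        raise FcsFormatError("TEXT segment has an odd number of tokens (unpaired keyword)")
    text: dict[str, str] = {}
    for i in range(0, len(tokens), 2):
        key = tokens[i].decode("utf-8", "replace").strip()
        if not key:
            raise FcsFormatError(f"empty keyword name at TEXT token {i}")
        text[key.upper()] = tokens[i + 1].decode("utf-8", "replace")
    return text


def _require(text: dict[str, str], key: str) -> str:
    if key not in text:
        raise FcsFormatError(f"required keyword {key} missing from TEXT segment")
    return text[key]


def read_fcs(path, sample_id: str | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _HEADER_LEN:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("ascii", "replace")
    if version.startswith("FCS2"):
        raise FcsFormatError(
            f"{path}: FCS 2.0 files are not supported; re-export as FCS 3.0/3.1"
        )
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unrecognized FCS version {version!r}")

    def _offset(start: int) -> int:
        fieldbytes = blob[start : start + 8]
        txt = fieldbytes.decode("ascii", "replace").strip()
        if txt == "":
            return 0
        try:
            return int(txt)
        except ValueError:
            raise FcsFormatError(f"{path}: non-numeric header offset {txt!r}") from None

    text_start, text_end = _offset(10), _offset(18)
    data_start, data_end = _offset(26), _offset(34)
    if text_start <= 0 or text_end < text_start:
        raise FcsFormatError(f"{path}: invalid TEXT segment offsets")
    text = _parse_text_segment(blob[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:  # large files defer offsets to TEXT
        data_start = int(_require(text, "$BEGINDATA"))
        data_end = int(_require(text, "$ENDDATA"))

    mode = _require(text, "$MODE").upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode is supported ($MODE={mode})")
    n_par = int(_require(text, "$PAR"))
    n_tot = int(_require(text, "$TOT"))
    if n_tot == 0:
        raise EventTableError(f"{path}: $TOT=0, file contains no events")

    datatype = _require(text, "$DATATYPE").upper()
    byteord = _require(text, "$BYTEORD")
    if byteord == "1,2,3,4":
        endian = "<"
    elif byteord == "4,3,2,1":
        endian = ">"
    else:
        raise FcsFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    bits = []
    names = []
    panel: dict[str, str] = {}
    for i in range(1, n_par + 1):
        bits.append(int(_require(text, f"$P{i}B")))
        name = _require(text, f"$P{i}N")
        names.append(name)
        stain = text.get(f"$P{i}S")
        if stain:
            panel[name] = stain

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE/F requires $PnB=32")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE/D requires $PnB=64")
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        widths = set(bits)
        if len(widths) != 1 or bits[0] not in (8, 16, 32, 64):
            raise FcsFormatError(
                f"{path}: integer data needs one common $PnB of 8/16/32/64, got {sorted(widths)}"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_tot * n_par * dtype.itemsize
    raw = blob[data_start : data_end + 1]
    if len(raw) < expected:
        raise FcsFormatError(
            f"{path}: DATA segment holds {len(raw)} bytes, "
            f"$TOT×$PAR×width needs {expected}"
        )
    matrix = (
        np.frombuffer(raw[:expected], dtype=dtype)
        .reshape(n_tot, n_par)
        .astype(float)
    )
    sid = sample_id if sample_id is not None else text.get("$FIL", str(path))
    return EventTable(sid, names, matrix, panel)


def write_fcs(table: EventTable, path) -> None:
    """Write an :class:`EventTable` as FCS 3.1 (float32, little-endian).

    Intended for fixtures and simulator output; values round-trip within
    float32 representation.
    """
    n, p = table.intensities.shape
    delim = "\x0c"
    data = table.intensities.astype("<f4").tobytes()

    keywords: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(p)),
        ("$TOT", str(n)),
        ("$NEXTDATA", "0"),
        ("$FIL", table.sample_id),
    ]
    for i, name in enumerate(table.channels, start=1):
        if delim in name:
            raise FcsFormatError(f"channel name {name!r} contains the TEXT delimiter")
        col = table.intensities[:, i - 1]
        rng_top = max(1.0, float(np.max(np.abs(col))))
        keywords += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", name),
            (f"$P{i}R", f"{int(np.ceil(rng_top)) + 1}"),
        ]
        stain = table.panel.get(name)
        if stain:
            keywords.append((f"$P{i}S", stain))

    def _render_text(begin_data: int, end_data: int) -> bytes:
        parts = [delim]
        for k, v in keywords + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]:
            parts.append(f"{k}{delim}{v}{delim}")
        return "".join(parts).encode("utf-8")

    # text length depends on the data offsets it embeds; two passes settle it
    text_start = _HEADER_LEN
    begin_data = end_data = 0
    for _ in range(3):
        text = _render_text(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _render_text(begin_data, end_data)
    text_end = text_start + len(text) - 1

    header = "FCS3.1    " + "".join(
        f"{v:>8d}" for v in (text_start, text_end, begin_data, end_data, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text)
        fh.write(data)
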