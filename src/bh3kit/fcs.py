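"""Minimal FCS 3.1 reader/writer.

Covers the subset of the Flow Cytometry Standard this pipeline produces and
consumes: list-mode (``$MODE L``), single data set, floating-point data
(``$DATATYPE F`` or ``D``), linear amplification (``$PnE 0,0``). Files
written here carry correct ``$PAR``/``$TOT`` keywords and segment offsets in
both the 58-byte header and the TEXT segment, so any conformant FCS 3.0/3.1
reader can open them. Keyword values containing the delimiter are not
supported (the writer never emits them).
"""

from __future__ import annotations

import numpy as np

from .errors import AcquisitionError, ValidationError

_DELIM = b"/"
_HEADER_LEN = 58


def _serialize_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        k, v = key.encode("ascii"), str(value).encode("ascii")
        if _DELIM in k or _DELIM in v:
            raise ValidationError(f"FCS keyword {key!r} contains the TEXT delimiter")
        parts += [k, _DELIM, v, _DELIM]
    return b"".join(parts)


def write_fcs(path, channel_names: list[str], data: np.ndarray, extra_keywords: dict | None = None) -> None:
    """Write events as FCS 3.1, float32 little-endian list mode.

    ``data`` is an (n_events, n_channels) array matching ``channel_names``.
    """
    data = np.ascontiguousarray(np.asarray(data, dtype="<f4"))
    if data.ndim != 2 or data.shape[1] != len(channel_names):
        raise ValidationError("data must be (n_events, n_channels) matching channel_names")
    n_tot, n_par = data.shape
    if n_tot == 0:
        raise ValidationError("refusing to write an FCS file with zero events")

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # 10-digit placeholders keep TEXT length fixed across the two passes
        "$BEGINDATA": "0" * 10,
        "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(data[:, i - 1])) + 1)))
    if extra_keywords:
        keywords.update({str(k): str(v) for k, v in extra_keywords.items()})

    text = _serialize_text(keywords)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    keywords["$BEGINDATA"] = str(data_start).zfill(10)
    keywords["$ENDDATA"] = str(data_end).zfill(10)
    text = _serialize_text(keywords)
    assert text_start + len(text) - 1 == text_end  # fixed-width pass invariant

    def _off(x: int) -> bytes:
        s = str(x) if x <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _off(x) for x in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Read an FCS 3.0/3.1 file; returns (channel names, event matrix, keywords)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_LEN or not raw[:3] == b"FCS":
        raise AcquisitionError(f"{path}: not an FCS file")
    version = raw[:10].decode("ascii", "replace").strip()
    if version not in {"FCS3.0", "FCS3.1"}:
        raise AcquisitionError(f"{path}: unsupported FCS version {version!r}")

    def _int_at(lo: int) -> int:
        field = raw[lo : lo + 8].decode("ascii", "replace").strip()
        return int(field) if field else 0

    text_start, text_end = _int_at(10), _int_at(18)
    data_start, data_end = _int_at(26), _int_at(34)
    if text_end <= text_start:
        raise AcquisitionError(f"{path}: corrupt FCS header (TEXT offsets)")
    text = raw[text_start : text_end + 1]
    delim = text[:1]
    fields = text[1:].split(delim)
    if fields and fields[-1] == b"":
        fields = fields[:-1]
    if len(fields) % 2:
        raise AcquisitionError(f"{path}: malformed TEXT segment")
    kw = {
        fields[i].decode("ascii", "replace").strip().upper(): fields[i + 1].decode("ascii", "replace")
        for i in range(0, len(fields), 2)
    }

    if kw.get("$MODE", "L").strip() != "L":
        raise AcquisitionError(f"{path}: only list-mode FCS is supported")
    dtype_code = kw.get("$DATATYPE", "").strip().upper()
    if dtype_code not in {"F", "D"}:
        raise AcquisitionError(f"{path}: unsupported $DATATYPE {dtype_code!r} (need F or D)")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if not data_start:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8
    expected = n_par * n_tot * itemsize
    blob = raw[data_start : data_start + expected]
    if len(blob) != expected:
        raise AcquisitionError(
            f"{path}: DATA segment truncated (expected {expected} bytes, got {len(blob)})"
        )
    matrix = np.frombuffer(blob, dtype=f"{endian}f{itemsize}").reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        names.append(name.strip())
    return names, np.asarray(matrix, dtype=float), kw
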