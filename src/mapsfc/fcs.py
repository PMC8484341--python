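"""Minimal FCS 3.0 list-mode writer and reader.

Implements the subset of the FCS 3.0 standard needed for cytometry
interchange: list mode (``$MODE L``), single-precision float data
(``$DATATYPE F``), little-endian byte order, one data segment, no
analysis segment. The reader additionally accepts big-endian files and
``$DATATYPE D``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError

_DELIM = b"/"
_HEADER_LEN = 58  # "FCS3.0" + 4 spaces + 6 x 8-char ASCII offsets


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        parts.append(str(key).encode("ascii"))
        parts.append(_DELIM)
        parts.append(str(value).encode("ascii"))
        parts.append(_DELIM)
    return b"".join(parts)


def write_fcs(destination, frame: pd.DataFrame, extra_keywords: dict | None = None) -> None:
    """Write a numeric DataFrame as one FCS 3.0 list-mode data set."""
    names = [str(c) for c in frame.columns]
    data = frame.to_numpy(dtype="<f4")
    n_events, n_par = data.shape if data.ndim == 2 else (0, len(names))

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(names, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = name.replace("/", "_")
        col = data[:, i - 1] if n_events else np.zeros(0)
        rng = float(col.max()) if col.size else 1.0
        keywords[f"$P{i}R"] = str(int(np.ceil(max(rng, 1.0))) + 1)
    if extra_keywords:
        keywords.update({str(k): str(v) for k, v in extra_keywords.items()})

    # BEGINDATA/ENDDATA values change the TEXT length; zero-pad to fixed width
    keywords["$BEGINDATA"] = "0" * 10
    keywords["$ENDDATA"] = "0" * 10
    text_len = len(_text_segment(keywords))
    text_begin = _HEADER_LEN
    text_end = text_begin + text_len - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1 if data.nbytes else 0
    keywords["$BEGINDATA"] = f"{data_begin:010d}"
    keywords["$ENDDATA"] = f"{max(data_end, 0):010d}"
    text = _text_segment(keywords)
    assert len(text) == text_len

    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}".encode() + f"{text_end:8d}".encode()
        + (f"{data_begin:8d}".encode() if data_end < 10 ** 8 else b"       0")
        + (f"{data_end:8d}".encode() if data_end < 10 ** 8 else b"       0")
        + f"{0:8d}".encode() + f"{0:8d}".encode()
    )
    with open(destination, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(source) -> tuple[dict[str, str], pd.DataFrame]:
    """Parse an FCS 3.0 file; returns (keywords, events DataFrame)."""
    with open(source, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3.0"):
        raise FormatError(f"not an FCS 3.0 file (header {raw[:6]!r})")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise FormatError("unreadable TEXT offsets in FCS header") from exc

    text = raw[text_begin:text_end + 1]
    delim = text[:1]
    fields = text[1:].split(delim)
    if fields and fields[-1] == b"":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FormatError("odd number of TEXT fields in FCS file")
    keywords = {
        fields[i].decode("ascii", "replace").strip(): fields[i + 1].decode("ascii", "replace")
        for i in range(0, len(fields), 2)
    }

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    data_begin = int(keywords.get("$BEGINDATA") or raw[26:34])
    data_end = int(keywords.get("$ENDDATA") or raw[34:42])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    else:
        raise FormatError(f"unsupported $DATATYPE {datatype!r}")

    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if n_tot == 0:
        return keywords, pd.DataFrame(columns=names)
    count = n_par * n_tot
    if data_end - data_begin + 1 < count * dtype.itemsize:
        raise FormatError("FCS data segment shorter than $PAR x $TOT values")
    values = np.frombuffer(raw, dtype=dtype, count=count, offset=data_begin)
    return keywords, pd.DataFrame(values.reshape(n_tot, n_par), columns=names)
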