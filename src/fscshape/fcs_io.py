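"""Reading, writing and binning of flow-cytometry event data.

The analyses in this package operate on the forward-scatter (FSC) channel
of a conventional cytometer acquiring on a linear scale with 1024 integer
channels (0..1023), as on a BD FacsCalibur.  Two on-disk representations
are supported:

* FCS files (versions 2.0 / 3.0 / 3.1), via a minimal reader that handles
  list-mode data in float (``$DATATYPE F``/``D``) or integer (``I``)
  format, and a minimal FCS 3.0 writer used for fixtures and simulated
  samples;
* plain-text event lists (one value per line, optional ``# key=value``
  header block), which round-trip at full precision.

Shape indicators that are moment-based (kurtosis, PCD) are computed from
raw event values; the Spherical Index is defined on the binned channel
histogram produced by :func:`to_histogram`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EventSample",
    "Histogram",
    "FCSFormatError",
    "ChannelNotFoundError",
    "TextParseError",
    "N_CHANNELS",
    "read_fcs",
    "write_fcs",
    "read_events_text",
    "write_events_text",
    "to_histogram",
    "read_histogram_csv",
    "write_histogram_csv",
]

#: Channel resolution of a linear FacsCalibur FSC axis.
N_CHANNELS = 1024


class FCSFormatError(ValueError):
    """Raised when a file cannot be parsed as FCS."""


class ChannelNotFoundError(KeyError):
    """Raised when the requested channel is absent; names the available ones."""

    def __init__(self, requested: str, available: list[str]):
        self.requested = requested
        self.available = list(available)
        super().__init__(
            f"channel {requested!r} not found; available channels: "
            f"{', '.join(available) if available else '(none)'}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class TextParseError(ValueError):
    """Raised for malformed plain-text event files; cites the line number."""


@dataclass
class EventSample:
    """One acquisition: per-event FSC values plus free-form metadata.

    ``events`` are linear channel units, real-valued, expected (not
    enforced) to lie in [0, 1023].  ``meta`` carries sample annotations
    such as subject id, time point, density fraction, antibody label,
    flow rate or buffer osmolarity.
    """

    events: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 1:
            raise ValueError("events must be one-dimensional")
        if self.events.size < 1:
            raise ValueError("an EventSample needs at least one event")
        if not np.all(np.isfinite(self.events)):
            raise ValueError("events must be finite")

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass
class Histogram:
    """Binned FSC counts on integer channels ``0..n_channels-1``."""

    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return int(self.counts.size)

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


def to_histogram(sample: EventSample, n_channels: int = N_CHANNELS) -> Histogram:
    """Bin events onto integer channels: value ``v`` goes to ``floor(v)``,
    clamped into ``[0, n_channels-1]``.

    Clamped events are retained (count conservation holds exactly); their
    number is surfaced as ``meta["n_clamped"]`` for QC.  No gating of any
    kind is applied.
    """
    ch = np.floor(sample.events).astype(np.int64)
    n_clamped = int(np.count_nonzero((ch < 0) | (ch > n_channels - 1)))
    ch = np.clip(ch, 0, n_channels - 1)
    counts = np.bincount(ch, minlength=n_channels)
    meta = dict(sample.meta)
    meta["n_clamped"] = n_clamped
    return Histogram(counts=counts, meta=meta)


# ---------------------------------------------------------------------------
# Plain-text event lists


def write_events_text(sample: EventSample, path) -> None:
    """One event value per line, preceded by ``# key=value`` metadata lines.

    Uses ``repr()`` of the float so that read-back is bit-exact.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in sample.meta.items():
            fh.write(f"# {key}={value}\n")
        for v in sample.events:
            fh.write(f"{float(v)!r}\n")


def read_events_text(path) -> EventSample:
    """Read a plain-text event list written by :func:`write_events_text`.

    Raises :class:`TextParseError` citing the 1-based line number of the
    first non-numeric payload line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such event file: {path}")
    values: list[float] = []
    meta: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise TextParseError(
                    f"{path}: line {lineno}: not a number: {line!r}"
                ) from None
    if not values:
        raise TextParseError(f"{path}: contains no event values")
    return EventSample(events=np.array(values, dtype=float), meta=meta)


# ---------------------------------------------------------------------------
# FCS


def _parse_text_segment(raw: bytes) -> dict:
    """Parse a delimited FCS TEXT segment into a keyword dict.

    The first byte is the delimiter; doubled delimiters inside values are
    the standard escape and are unescaped here.
    """
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    text = raw.decode("latin-1")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Split on single delimiters; re-join doubled (escaped) ones.
    parts = body.split(delim)
    tokens: list[str] = []
    i = 0
    while i < len(parts):
        tok = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            # empty part ⇒ doubled delimiter ⇒ literal delimiter in value
            tok = tok + delim + parts[i + 2]
            i += 2
        tokens.append(tok)
        i += 1
    if len(tokens) % 2:
        tokens = tokens[:-1]
    keywords: dict = {}
    for key, value in zip(tokens[::2], tokens[1::2]):
        keywords[key.strip().upper()] = value
    return keywords


def _decode(parts) -> list[str]:
    return [p.decode("latin-1") for p in parts]


def read_fcs(path, channel_name: str = "FSC-H") -> EventSample:
    """Read one channel of list-mode data from an FCS 2.0/3.0/3.1 file.

    The values are returned untransformed (the analyses here assume a
    linear acquisition scale).  If ``channel_name`` is absent, the first
    channel whose ``$PnN`` short name starts with ``"FSC"`` is used as a
    fallback; if none exists, :class:`ChannelNotFoundError` lists the
    channels that are present.  All TEXT-segment keywords are copied into
    ``meta``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FCS file: {path}")
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSFormatError(f"{path}: too short to be an FCS file")
    version = blob[:6].decode("latin-1", errors="replace")
    if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported or missing FCS version ({version!r})")

    def header_int(a: int, b: int) -> int:
        fieldtxt = blob[a:b].decode("latin-1").strip() or "0"
        try:
            return int(fieldtxt)
        except ValueError:
            raise FCSFormatError(f"{path}: malformed header offset {fieldtxt!r}") from None

    text_begin = header_int(10, 18)
    text_end = header_int(18, 26)
    data_begin = header_int(26, 34)
    data_end = header_int(34, 42)
    if text_begin <= 0 or text_end < text_begin or text_end >= len(blob):
        raise FCSFormatError(f"{path}: invalid TEXT segment offsets")
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
    if data_end == 0:
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin or data_end >= len(blob):
        raise FCSFormatError(f"{path}: invalid DATA segment offsets")

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from None
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise FCSFormatError(f"{path}: only list mode ($MODE L) is supported")

    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2,1"):
        endian = ">"
    else:
        raise FCSFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if datatype == "F":
        dtypes = [np.dtype(endian + "f4")] * n_par
    elif datatype == "D":
        dtypes = [np.dtype(endian + "f8")] * n_par
    elif datatype == "I":
        dtypes = []
        for i in range(1, n_par + 1):
            bits = int(kw.get(f"$P{i}B", "16"))
            if bits not in (8, 16, 32, 64):
                raise FCSFormatError(
                    f"{path}: integer channel width {bits} bits not supported"
                )
            dtypes.append(np.dtype(endian + f"u{bits // 8}"))
    else:
        raise FCSFormatError(f"{path}: $DATATYPE {datatype!r} not supported")

    rec = np.dtype([(f"f{i}", dt) for i, dt in enumerate(dtypes)])
    expected = rec.itemsize * n_tot
    raw = blob[data_begin : data_begin + expected]
    if len(raw) < expected:
        raise FCSFormatError(
            f"{path}: DATA segment truncated ({len(raw)} bytes, expected {expected})"
        )
    table = np.frombuffer(raw, dtype=rec, count=n_tot)

    if channel_name in names:
        col = names.index(channel_name)
    else:
        fsc_cols = [i for i, n in enumerate(names) if n.upper().startswith("FSC")]
        if not fsc_cols:
            raise ChannelNotFoundError(channel_name, names)
        col = fsc_cols[0]

    events = table[f"f{col}"].astype(float)
    meta = {k: v for k, v in kw.items()}
    meta["channel"] = names[col]
    return EventSample(events=events, meta=meta)


def write_fcs(sample: EventSample, path, channel_name: str = "FSC-H") -> None:
    """Write a single-channel FCS 3.0 file (list mode, float32 data).

    Sufficient for fixtures and simulated samples; metadata values are
    stored as extra TEXT keywords with delimiter escaping.
    """
    path = Path(path)
    data = np.asarray(sample.events, dtype="<f4")
    n_tot = data.size
    delim = "/"

    def esc(v) -> str:
        s = str(v)
        return s.replace(delim, delim + delim) or " "

    text_start = 256
    extra = {
        str(k).upper(): esc(v)
        for k, v in sample.meta.items()
        if str(k).strip() and not str(k).startswith("$")
    }

    def build(data_begin: int, data_end: int) -> bytes:
        pairs = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": f"{data_begin:010d}",
            "$ENDDATA": f"{data_end:010d}",
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$PAR": "1",
            "$TOT": str(n_tot),
            "$P1N": esc(channel_name),
            "$P1B": "32",
            "$P1E": "0,0",
            "$P1R": str(N_CHANNELS),
            **extra,
        }
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim
        return body.encode("latin-1")

    # Zero-padded offsets keep the TEXT length independent of their value,
    # so one rebuild with the true offsets suffices.
    text = build(0, 0)
    text_end = text_start + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    text = build(data_begin, data_end)
    assert text_start + len(text) - 1 == text_end

    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    blob = header + b" " * (text_start - len(header)) + text + data.tobytes()
    path.write_bytes(blob)


# ---------------------------------------------------------------------------
# Histogram CSV ("channel,count")


def write_histogram_csv(hist: Histogram, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("channel,count\n")
        for ch, c in enumerate(hist.counts):
            fh.write(f"{ch},{int(c)}\n")


def read_histogram_csv(path) -> Histogram:
    path = Path(path)
    rows: list[tuple[int, int]] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip().lower() != "channel,count":
            raise TextParseError(f"{path}: expected 'channel,count' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                ch_s, c_s = line.split(",")
                rows.append((int(ch_s), int(c_s)))
            except ValueError:
                raise TextParseError(f"{path}: line {lineno}: malformed row {line!r}") from None
    n = max([N_CHANNELS] + [ch + 1 for ch, _ in rows])
    counts = np.zeros(n, dtype=np.int64)
    for ch, c in rows:
        if ch < 0:
            raise TextParseError(f"{path}: negative channel {ch}")
        counts[ch] = c
    return Histogram(counts=counts)
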