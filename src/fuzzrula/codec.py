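"""Encode/decode fixed-length IMU data frames and read/write plain-text signal logs.

The wearable sensors ship each reading as a 20-byte frame over a BLE
notification: a header octet, a frame-type octet, then nine little-endian
signed 16-bit words carrying tri-axial acceleration, angular velocity and
orientation.  Raw words are scaled to physical units by the full-scale
ranges of the device (±16 g, ±2000 °/s, ±180°).  Offline, the same readings
appear as delimited text logs (one row per sample); both representations
round-trip through this module.
"""

from __future__ import annotations

import dataclasses
import io
import re
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    CodecError,
    LogParseError,
    MalformedFrameError,
    RangeError,
    UnknownFrameError,
)

FRAME_LENGTH = 20
FRAME_HEADER = 0x55
#: frame type carrying the nine measurement words (acc, gyro, angle)
FLAG_MEASUREMENT = 0x61
#: recognised-but-skipped frame types (e.g. quaternion register reads)
SKIP_FLAGS = frozenset({0x71})

_WORDS = struct.Struct("<9h")
_INT16_FULL = 32768.0

PLACEMENTS = ("LA", "LS", "C", "S", "RS", "RA")
_MAC_RE = re.compile(r"^([0-9A-Fa-f]{2}:){5}[0-9A-Fa-f]{2}$")

ACC_CHANNELS = ("acc_x", "acc_y", "acc_z")
GYRO_CHANNELS = ("gyro_x", "gyro_y", "gyro_z")
ANGLE_CHANNELS = ("angle_x", "angle_y", "angle_z")
CHANNELS = ACC_CHANNELS + GYRO_CHANNELS + ANGLE_CHANNELS
LOG_COLUMNS = ("t",) + CHANNELS
ANGLE_LOG_COLUMNS = ("t",) + ANGLE_CHANNELS


@dataclass(frozen=True)
class CodecSettings:
    """Full-scale ranges used to map int16 words to physical units.

    Defaults follow the manufacturer's documented ranges; other sensor
    variants can substitute their own.
    """

    acc_range: float = 16.0  # g
    gyro_range: float = 2000.0  # deg/s
    angle_range: float = 180.0  # deg

    @property
    def scales(self) -> tuple[float, ...]:
        return (self.acc_range,) * 3 + (self.gyro_range,) * 3 + (self.angle_range,) * 3


DEFAULT_SETTINGS = CodecSettings()


@dataclass(frozen=True)
class DecodedSample:
    """One time-stamped nine-channel IMU reading.

    ``t`` is seconds since stream start and is ``None`` straight out of
    :func:`decode_frame` (a lone frame carries no clock); stream decoding
    assigns ``sample_index / rate``.
    """

    t: float | None
    acc_x: float
    acc_y: float
    acc_z: float
    gyro_x: float
    gyro_y: float
    gyro_z: float
    angle_x: float
    angle_y: float
    angle_z: float

    def channel_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in CHANNELS)


@dataclass(frozen=True)
class SensorIdentity:
    """A sensor's label, hardware address and body placement."""

    name: str
    mac: str
    placement: str

    def __post_init__(self) -> None:
        if not _MAC_RE.match(self.mac):
            raise ValueError(f"not a colon-separated MAC address: {self.mac!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(
                f"placement {self.placement!r} not one of {PLACEMENTS}"
            )


@dataclass
class StreamStats:
    """Bookkeeping from resynchronising decode of a byte stream."""

    decoded: int = 0
    junk_bytes: int = 0
    skipped_frames: int = 0


def decode_frame(
    frame: bytes | bytearray | Sequence[int],
    settings: CodecSettings = DEFAULT_SETTINGS,
) -> DecodedSample:
    """Decode one 20-byte frame into physical units (timestamp left unset).

    Raises :class:`MalformedFrameError` for a wrong length and
    :class:`UnknownFrameError` for unrecognised header/type octets.
    """
    frame = bytes(frame)
    if len(frame) != FRAME_LENGTH:
        raise MalformedFrameError(
            f"expected {FRAME_LENGTH}-byte frame, got {len(frame)} bytes"
        )
    if frame[0] != FRAME_HEADER or frame[1] != FLAG_MEASUREMENT:
        raise UnknownFrameError(
            f"unrecognised frame header/type 0x{frame[0]:02x} 0x{frame[1]:02x}"
        )
    raw = _WORDS.unpack(frame[2:])
    vals = [r / _INT16_FULL * s for r, s in zip(raw, settings.scales)]
    return DecodedSample(None, *vals)


def encode_frame(
    sample: DecodedSample, settings: CodecSettings = DEFAULT_SETTINGS
) -> bytes:
    """Encode a sample back into a 20-byte frame (inverse of decode to 1 LSB)."""
    words = []
    for value, scale, name in zip(sample.channel_values(), settings.scales, CHANNELS):
        if abs(value) > scale:
            raise RangeError(f"{name}={value} exceeds full-scale range ±{scale}")
        raw = round(value / scale * _INT16_FULL)
        words.append(max(-32768, min(32767, raw)))
    return bytes((FRAME_HEADER, FLAG_MEASUREMENT)) + _WORDS.pack(*words)


def decode_stream(
    data: bytes,
    rate: float = 50.0,
    settings: CodecSettings = DEFAULT_SETTINGS,
) -> tuple[list[DecodedSample], StreamStats]:
    """Decode a byte stream, resynchronising on the header pattern.

    Bytes that do not start a recognisable frame are skipped one at a time
    and counted; frames with a recognised header but a non-measurement type
    (e.g. quaternion blocks) are skipped whole and counted separately.
    Timestamps are assigned as ``index / rate``.
    """
    samples: list[DecodedSample] = []
    stats = StreamStats()
    i = 0
    n = len(data)
    while i < n:
        if data[i] == FRAME_HEADER and i + 1 < n:
            flag = data[i + 1]
            if flag == FLAG_MEASUREMENT and i + FRAME_LENGTH <= n:
                s = decode_frame(data[i : i + FRAME_LENGTH], settings)
                samples.append(
                    dataclasses.replace(s, t=len(samples) / rate)
                )
                stats.decoded += 1
                i += FRAME_LENGTH
                continue
            if flag in SKIP_FLAGS and i + FRAME_LENGTH <= n:
                stats.skipped_frames += 1
                i += FRAME_LENGTH
                continue
        stats.junk_bytes += 1
        i += 1
    return samples, stats


def parse_hex_dump(text: str) -> bytes:
    """Convert a hex-dump (two hex chars per octet, whitespace-insensitive)."""
    cleaned = re.sub(r"\s+", "", text)
    try:
        return bytes.fromhex(cleaned)
    except ValueError as exc:
        raise CodecError(f"invalid hex dump: {exc}") from exc


def _dialect_sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown log dialect {dialect!r} (expected 'tsv' or 'csv')")


def parse_log(
    path: str | Path | io.StringIO,
    dialect: str = "tsv",
    strict: bool = True,
) -> list[DecodedSample]:
    """Read a delimited signal log into samples, in nondecreasing time order.

    Accepts the nine-channel layout (``t`` + acc/gyro/angle × XYZ) or the
    orientation-only layout (``t`` + angle × XYZ, other channels zero).
    In strict mode an unparseable row raises :class:`LogParseError` naming
    the row; lenient mode skips and counts it (count attached to the
    returned list as ``.skipped_rows``).
    """
    sep = _dialect_sep(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = tuple(df.columns)
    if cols == LOG_COLUMNS:
        full = True
    elif cols == ANGLE_LOG_COLUMNS:
        full = False
    else:
        raise LogParseError(
            f"unexpected columns {cols}; want {LOG_COLUMNS} or {ANGLE_LOG_COLUMNS}"
        )
    coerced = df.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    bad = coerced.isna().any(axis=1) | df.isna().any(axis=1)
    skipped = int(bad.sum())
    if skipped and strict:
        row = int(bad.idxmax()) + 1  # 1-based data-row number
        raise LogParseError(f"non-numeric value in data row {row}")
    # convert via float() for correctly-rounded (round-trip exact) parsing
    numeric = df[~bad].astype(float)
    if not numeric["t"].is_monotonic_increasing:
        numeric = numeric.sort_values("t", kind="stable")
    samples: list[DecodedSample] = []
    for row in numeric.itertuples(index=False):
        if full:
            samples.append(DecodedSample(*row))
        else:
            t, ax, ay, az = row
            samples.append(DecodedSample(t, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, ax, ay, az))

    class _SampleList(list):
        skipped_rows = skipped

    out = _SampleList(samples)
    return out


def write_log(
    samples: Iterable[DecodedSample],
    path: str | Path | io.StringIO,
    dialect: str = "tsv",
    angles_only: bool = False,
) -> None:
    """Write samples as a delimited text log with a header row.

    Floats are written at full repr precision so a parse round-trip is
    bit-exact. Raises ``ValueError`` on empty input.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot write an empty log")
    sep = _dialect_sep(dialect)
    cols = ANGLE_LOG_COLUMNS if angles_only else LOG_COLUMNS
    rows = [[getattr(s, c) for c in cols] for s in samples]
    pd.DataFrame(rows, columns=list(cols)).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def samples_to_frame(samples: Sequence[DecodedSample]) -> pd.DataFrame:
    """Tabular view of a sample sequence (columns: t + nine channels)."""
    return pd.DataFrame(
        [[getattr(s, c) for c in LOG_COLUMNS] for s in samples],
        columns=list(LOG_COLUMNS),
    )
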