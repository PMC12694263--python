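"""Multi-sensor channel series, length alignment and acquisition-quality metrics.

A 5-minute acquisition block at the nominal 50 Hz yields an expected 15,000
samples per sensor.  Real BLE streams under- or over-shoot that count
(packet loss vs. delayed manual stop), so series are aligned to the nominal
length before kinematic analysis, and per-trial counts are summarised into
loss/efficiency percentages and descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import codec

NOMINAL_RATE = 50.0  # Hz
NOMINAL_DURATION = 300.0  # s
DEFAULT_EXPECTED_SAMPLES = int(round(NOMINAL_RATE * NOMINAL_DURATION))  # 15,000


@dataclass
class ChannelSeries:
    """One channel of one sensor: an ordered real sequence at a fixed rate."""

    values: np.ndarray
    rate: float = NOMINAL_RATE
    channel: str = "angle_y"
    placement: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("channel values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class Recording:
    """Per-(placement, channel) series for one acquisition session."""

    series: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    nominal_rate: float = NOMINAL_RATE
    nominal_duration: float = NOMINAL_DURATION

    @property
    def expected_samples(self) -> int:
        return int(round(self.nominal_rate * self.nominal_duration))

    def placements(self) -> tuple[str, ...]:
        return tuple(self.series)

    def channel(self, placement: str, channel: str) -> ChannelSeries:
        return ChannelSeries(
            self.series[placement][channel],
            rate=self.nominal_rate,
            channel=channel,
            placement=placement,
        )

    def n_samples(self, placement: str) -> int:
        chans = self.series[placement]
        return len(next(iter(chans.values())))

    def set_channel(self, placement: str, channel: str, values) -> None:
        if placement not in codec.PLACEMENTS:
            raise ValueError(f"unknown placement {placement!r}")
        self.series.setdefault(placement, {})[channel] = np.asarray(values, float)

    def align_all(self, target: int | None = None) -> "Recording":
        """Return a copy with every channel aligned to ``target`` samples."""
        target = self.expected_samples if target is None else target
        out = Recording({}, self.nominal_rate, self.nominal_duration)
        for placement, chans in self.series.items():
            out.series[placement] = {
                ch: align_to_length(vals, target) for ch, vals in chans.items()
            }
        return out

    def iter_samples(self, placement: str) -> Iterator[codec.DecodedSample]:
        chans = self.series[placement]
        n = self.n_samples(placement)
        cols = [
            chans.get(c, np.zeros(n)) for c in codec.CHANNELS
        ]
        for i in range(n):
            yield codec.DecodedSample(i / self.nominal_rate, *(col[i] for col in cols))

    def write_logs(self, directory: str | Path, dialect: str = "tsv") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ext = "tsv" if dialect == "tsv" else "csv"
        for placement in self.series:
            codec.write_log(
                list(self.iter_samples(placement)),
                directory / f"{placement}.{ext}",
                dialect=dialect,
            )

    @classmethod
    def from_logs(
        cls,
        directory: str | Path,
        dialect: str = "tsv",
        rate: float = NOMINAL_RATE,
        duration: float | None = None,
    ) -> "Recording":
        """Load per-placement logs; with ``duration=None`` the nominal block
        length is inferred from the longest log."""
        directory = Path(directory)
        ext = "tsv" if dialect == "tsv" else "csv"
        rec = cls({}, rate, duration if duration is not None else NOMINAL_DURATION)
        for placement in codec.PLACEMENTS:
            path = directory / f"{placement}.{ext}"
            if not path.exists():
                continue
            samples = codec.parse_log(path, dialect=dialect)
            frame = codec.samples_to_frame(samples)
            rec.series[placement] = {
                c: frame[c].to_numpy() for c in codec.CHANNELS
            }
        if not rec.series:
            raise FileNotFoundError(f"no per-placement logs found in {directory}")
        if duration is None:
            longest = max(rec.n_samples(p) for p in rec.series)
            rec.nominal_duration = longest / rate
        return rec


@dataclass(frozen=True)
class AcquisitionMetrics:
    """Summary statistics of received sample counts over repeated trials."""

    expected: int
    n_trials: int
    mean: float
    sd: float
    variance: float
    minimum: float
    maximum: float
    range: float
    cv_pct: float
    bias: float
    mpe_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "expected": self.expected,
            "n_trials": self.n_trials,
            "mean": self.mean,
            "sd": self.sd,
            "variance": self.variance,
            "min": self.minimum,
            "max": self.maximum,
            "range": self.range,
            "cv_pct": self.cv_pct,
            "bias": self.bias,
            "mpe_pct": self.mpe_pct,
        }


def align_to_length(series, target: int):
    """Bring a series to exactly ``target`` samples.

    Shorter series are linearly interpolated on a uniform index grid
    (endpoints preserved, no overshoot); longer series are truncated to
    their first ``target`` samples (excess arises from delayed manual stop,
    i.e. at the end); equal-length series are returned unchanged.

    Accepts a :class:`ChannelSeries` (returned type matches) or any 1-D
    array-like.
    """
    if isinstance(series, ChannelSeries):
        aligned = align_to_length(series.values, target)
        if aligned is series.values:
            return series
        return ChannelSeries(aligned, series.rate, series.channel, series.placement)
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("cannot align an empty series")
    if target < 2:
        raise ValueError("target length must be at least 2")
    n = values.size
    if n == target:
        return values
    if n > target:
        return values[:target].copy()
    new_index = np.linspace(0.0, n - 1, target)
    return np.interp(new_index, np.arange(n), values)


def loss_pct(received: int, expected: int) -> float:
    """Residual count error: (expected − received) / expected × 100.

    Negative values mean an excess of collected data (delayed stop), not a
    gain in fidelity.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return (expected - received) / expected * 100.0


def efficiency_pct(received: int, expected: int) -> float:
    """Acquisition efficiency: received / expected × 100 (= 100 − loss)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return received / expected * 100.0


def trial_statistics(
    counts: Sequence[float], expected: int = DEFAULT_EXPECTED_SAMPLES
) -> AcquisitionMetrics:
    """Descriptive statistics of received counts over ≥2 repeated trials.

    SD and variance use the n−1 (sample) denominator; CV = SD/mean × 100;
    bias = mean − expected; MPE = bias/expected × 100.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 trials")
    if expected <= 0:
        raise ValueError("expected count must be positive")
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    bias = mean - expected
    return AcquisitionMetrics(
        expected=int(expected),
        n_trials=int(counts.size),
        mean=mean,
        sd=sd,
        variance=float(np.var(counts, ddof=1)),
        minimum=float(np.min(counts)),
        maximum=float(np.max(counts)),
        range=float(np.ptp(counts)),
        cv_pct=sd / mean * 100.0 if mean else float("nan"),
        bias=bias,
        mpe_pct=bias / expected * 100.0,
    )


def theoretical_throughput(
    rate: float, packet_bytes: int, n_sensors: int
) -> tuple[float, float]:
    """Per-sensor bytes/s and aggregate kbps for a notification stream.

    ``rate`` packets/s × ``packet_bytes`` bytes gives the per-sensor byte
    rate; the aggregate bit rate multiplies by 8 bits/byte and the sensor
    count.  (50, 20, 6) → (1000 bytes/s, 48 kbps).
    """
    if rate <= 0 or packet_bytes <= 0 or n_sensors <= 0:
        raise ValueError("all throughput inputs must be positive")
    bytes_per_s = rate * packet_bytes
    kbps = bytes_per_s * 8 * n_sensors / 1000.0
    return bytes_per_s, kbps
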