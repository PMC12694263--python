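"""Ground-truthed synthetic recordings, frame streams and rating tables.

Stands in for the body-worn six-sensor acquisition: each scenario fixes a
per-placement mean orientation triplet (roll, pitch, yaw) for a seated
posture, and the generator adds Gaussian sensor noise, a slow linear drift
and optional sample-count jitter / packet drops, at 50 Hz for 5-minute
blocks by default.  Scenario presets emulate the three study postures
qualitatively — upright desk work, slouched sitting and reclined sitting —
and every generated recording carries its noise-free relative angles and
the risk category they imply through the crisp worksheet chain, so the full
fuzzy pipeline can be checked against an intended label.

A single global seed fans out to per-sensor substreams, so adding a sensor
never perturbs the noise of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import codec, rula_tables
from .biomech import DEFAULT_AXIS_MAP, SIDES, PostureAngles
from .recording import NOMINAL_DURATION, NOMINAL_RATE, Recording
from .risk_profile import CATEGORIES

#: mean (roll, pitch, yaw) per placement, degrees, for each posture preset.
#: Right-side rolls are mirrored (negative roll = abduction away from trunk
#: under the default axis/sign convention).
PRESET_MEANS: dict[str, dict[str, tuple[float, float, float]]] = {
    # near-neutral trunk and arms: medium risk either side
    "upright": {
        "LA": (2.0, 12.0, 0.0),
        "LS": (0.0, 2.0, 0.0),
        "RA": (-2.0, 12.0, 0.0),
        "RS": (0.0, 2.0, 0.0),
        "C": (0.0, 2.0, 0.0),
        "S": (0.0, 0.0, 0.0),
    },
    # trunk flexed ~30°, arms reaching: high risk
    "slouched": {
        "LA": (5.0, 85.0, 0.0),
        "LS": (0.0, 30.0, 0.0),
        "RA": (-5.0, 85.0, 0.0),
        "RS": (0.0, 30.0, 0.0),
        "C": (0.0, 32.0, 2.0),
        "S": (0.0, 2.0, 0.0),
    },
    # backrest lean ~-35° with splayed, raised arms: high risk
    "reclined": {
        "LA": (25.0, 40.0, 0.0),
        "LS": (0.0, -20.0, 0.0),
        "RA": (-25.0, 40.0, 0.0),
        "RS": (0.0, -20.0, 0.0),
        "C": (0.0, -35.0, 0.0),
        "S": (0.0, 0.0, 0.0),
    },
}


@dataclass(frozen=True)
class PostureScenario:
    """One simulated acquisition condition."""

    name: str = "upright"
    placement_means: Mapping[str, tuple[float, float, float]] | None = None
    noise_sd: float = 2.0  # deg, Gaussian per sample
    drift: float = 0.5  # deg/min, linear
    duration: float = NOMINAL_DURATION  # s
    rate: float = NOMINAL_RATE  # Hz
    sample_jitter: float = 0.0  # signed % of the expected count
    packet_drop: float = 0.0  # probability per frame
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if not 0.0 <= self.packet_drop < 1.0:
            raise ValueError("packet_drop must be in [0, 1)")
        if self.placement_means is None:
            if self.name not in PRESET_MEANS:
                raise ValueError(
                    f"unknown preset {self.name!r}; provide placement_means "
                    f"or one of {sorted(PRESET_MEANS)}"
                )
            object.__setattr__(self, "placement_means", PRESET_MEANS[self.name])

    @property
    def expected_samples(self) -> int:
        return int(round(self.rate * self.duration))

    @property
    def n_samples(self) -> int:
        return int(round(self.expected_samples * (1.0 + self.sample_jitter / 100.0)))


def preset(name: str, **overrides) -> PostureScenario:
    """A scenario for one of the named study postures, with overrides."""
    return PostureScenario(name=name, **overrides)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free relative angles and the risk category they imply."""

    arm_flexion: dict[str, float]
    arm_abduction: dict[str, float]
    trunk_flexion: float
    trunk_twist: float
    category: dict[str, str]  # per side

    def as_dict(self) -> dict:
        return {
            "arm_flexion": self.arm_flexion,
            "arm_abduction": self.arm_abduction,
            "trunk_flexion": self.trunk_flexion,
            "trunk_twist": self.trunk_twist,
            "category": self.category,
        }


def _placement_rng(seed: int | None, placement: str) -> np.random.Generator:
    idx = codec.PLACEMENTS.index(placement)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def ground_truth(scenario: PostureScenario, static: bool = True) -> GroundTruth:
    """Intended relative angles/categories, via the crisp worksheet chain."""
    means = scenario.placement_means
    axis = DEFAULT_AXIS_MAP
    flex, abd, cat = {}, {}, {}
    c_pitch = means["C"][1] - means["S"][1]
    c_twist = means["C"][2] - means["S"][2]
    for side in SIDES:
        arm, shoulder = ("LA", "LS") if side == "left" else ("RA", "RS")
        flex[side] = means[arm][1] - means[shoulder][1]
        abd[side] = axis.abduction_sign[side] * (means[arm][0] - means[shoulder][0])
        _, _, c = rula_tables.crisp_scores(
            flex[side], abd[side], c_pitch, c_twist, static=static
        )
        cat[side] = CATEGORIES[0] if c <= 4 else CATEGORIES[1] if c <= 6 else CATEGORIES[2]
    return GroundTruth(flex, abd, c_pitch, c_twist, cat)


def generate_recording(
    scenario: PostureScenario, seed: int | None = None
) -> tuple[Recording, PostureAngles, GroundTruth]:
    """Simulate one acquisition block for all six sensors.

    Returns the noisy :class:`Recording`, the noise-free
    :class:`PostureAngles` ground truth (constant series at the expected
    length) and the per-side intended risk category.  Deterministic under a
    fixed seed.
    """
    seed = scenario.seed if seed is None else seed
    n = scenario.n_samples
    t_min = np.arange(n) / scenario.rate / 60.0  # minutes, for drift
    rec = Recording({}, scenario.rate, scenario.duration)
    for placement in codec.PLACEMENTS:
        rng = _placement_rng(seed, placement)
        roll, pitch, yaw = scenario.placement_means[placement]
        drift = scenario.drift * t_min
        chans: dict[str, np.ndarray] = {}
        for channel, mean in (("angle_x", roll), ("angle_y", pitch), ("angle_z", yaw)):
            noise = rng.normal(0.0, scenario.noise_sd, n)
            values = np.clip(mean + drift + noise, -180.0, 180.0)
            chans[channel] = values
        for channel in codec.ACC_CHANNELS:
            base = 1.0 if channel == "acc_z" else 0.0  # gravity, roughly
            chans[channel] = base + rng.normal(0.0, 0.02, n)
        for channel in codec.GYRO_CHANNELS:
            chans[channel] = rng.normal(0.0, 5.0, n)
        rec.series[placement] = chans
    truth = ground_truth(scenario)
    m = scenario.expected_samples
    posture = PostureAngles(
        arm_flexion={s: np.full(m, truth.arm_flexion[s]) for s in SIDES},
        arm_abduction={s: np.full(m, truth.arm_abduction[s]) for s in SIDES},
        trunk_flexion=np.full(m, truth.trunk_flexion),
        trunk_twist=np.full(m, truth.trunk_twist),
        rate=scenario.rate,
    )
    return rec, posture, truth


def generate_frame_stream(
    rec: Recording,
    drop: float = 0.0,
    seed: int | None = None,
    placement: str | None = None,
) -> bytes:
    """Encode a recording's samples as a raw byte stream of 20-byte frames.

    Frames are dropped independently with probability ``drop``.  With a
    single placement the stream mirrors one sensor's notification channel;
    otherwise all placements are concatenated in canonical order.
    """
    if not 0.0 <= drop <= 1.0:
        raise ValueError("drop must be in [0, 1]")
    rng = np.random.default_rng(seed)
    placements = (placement,) if placement else tuple(rec.series)
    chunks = []
    for p in placements:
        for sample in rec.iter_samples(p):
            if drop and rng.random() < drop:
                continue
            chunks.append(codec.encode_frame(sample))
    if not chunks:
        import warnings

        warnings.warn("all frames dropped; stream is empty", stacklevel=2)
    return b"".join(chunks)


def generate_rating_table(
    true_categories: Sequence[str],
    n_raters: int = 4,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate raters labelling subjects whose true category is known.

    Each rater reports the truth, perturbed to an adjacent category on the
    ordinal Medium < High < Severe scale with probability ``error_rate``
    (ties between two neighbours broken uniformly).
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = list(CATEGORIES)
    table = np.empty((len(true_categories), n_raters), dtype=object)
    for i, true in enumerate(true_categories):
        k = order.index(true)
        for j in range(n_raters):
            if rng.random() < error_rate:
                neighbours = [k - 1, k + 1]
                neighbours = [x for x in neighbours if 0 <= x < len(order)]
                table[i, j] = order[rng.choice(neighbours)]
            else:
                table[i, j] = true
    return table


def simulate_trial_counts(
    n_trials: int,
    expected: int,
    jitter_sd_pct: float,
    seed: int | None = None,
) -> np.ndarray:
    """Received-sample counts for repeated trials with Gaussian count jitter.

    Mirrors the shape of the loss/efficiency analysis: each trial's count is
    ``expected × (1 + ε/100)`` with ε ~ N(0, jitter_sd_pct), rounded.
    """
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, jitter_sd_pct, n_trials)
    return np.rint(expected * (1.0 + eps / 100.0)).astype(int)
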