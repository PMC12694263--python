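"""Relative joint/trunk angles from absolute sensor orientations.

An arm sensor alone cannot distinguish a flexed arm from a tilted trunk:
the arm's absolute pitch mixes both.  Subtracting the proximal reference
sensor (shoulder for the arms, sacrum for the trunk) isolates the joint
angle.  All differences are taken on the shortest signed arc so circular
yaw wraps correctly.

Axis mapping (configurable per placement): pitch = ``angle_y`` carries
flexion/extension, roll = ``angle_x`` carries abduction/lateral tilt,
yaw = ``angle_z`` carries twist.  Sign conventions: flexion forward,
twist to the right, and abduction away from the trunk are positive, so the
right-side roll sign is flipped by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .recording import ChannelSeries, Recording

SIDES = ("left", "right")


@dataclass(frozen=True)
class AxisMap:
    """Which Euler channel plays which kinematic role, plus sign flips."""

    pitch: str = "angle_y"
    roll: str = "angle_x"
    yaw: str = "angle_z"
    #: sign applied to the *relative* abduction angle per side
    abduction_sign: dict = field(
        default_factory=lambda: {"left": 1.0, "right": -1.0}
    )
    flexion_sign: float = 1.0
    twist_sign: float = 1.0


DEFAULT_AXIS_MAP = AxisMap()

#: (arm, shoulder) sensor placements per body side
SIDE_SENSORS = {"left": ("LA", "LS"), "right": ("RA", "RS")}


@dataclass
class PostureAngles:
    """Per-sample relative angles consumed by the risk models (degrees)."""

    arm_flexion: dict[str, np.ndarray]
    arm_abduction: dict[str, np.ndarray]
    trunk_flexion: np.ndarray
    trunk_twist: np.ndarray
    rate: float = 50.0

    def __post_init__(self) -> None:
        lengths = {
            len(self.arm_flexion[s]) for s in SIDES
        } | {
            len(self.arm_abduction[s]) for s in SIDES
        } | {len(self.trunk_flexion), len(self.trunk_twist)}
        if len(lengths) != 1:
            raise AlignmentError(
                f"posture series lengths disagree: {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.trunk_flexion)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "t": np.arange(n) / self.rate,
                "arm_flexion_left": self.arm_flexion["left"],
                "arm_flexion_right": self.arm_flexion["right"],
                "arm_abduction_left": self.arm_abduction["left"],
                "arm_abduction_right": self.arm_abduction["right"],
                "trunk_flexion": self.trunk_flexion,
                "trunk_twist": self.trunk_twist,
            }
        )


def wrap_angle(angle):
    """Wrap angles to the half-open interval [−180, 180) degrees."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def _values(series) -> np.ndarray:
    if isinstance(series, ChannelSeries):
        return series.values
    return np.asarray(series, dtype=float)


def relative_angle(segment, reference) -> np.ndarray:
    """Shortest signed arc from the reference to the segment angle."""
    seg, ref = _values(segment), _values(reference)
    if seg.shape != ref.shape:
        raise AlignmentError(
            f"series lengths differ ({seg.size} vs {ref.size}); "
            "run align_to_length on both first"
        )
    return wrap_angle(seg - ref)


def arm_flexion_extension(arm_pitch, shoulder_pitch, sign: float = 1.0) -> np.ndarray:
    """Arm flexion(+)/extension(−) relative to the trunk reference.

    Subtracting the shoulder pitch removes trunk inclination, so a tilted
    trunk with a hanging arm reads 0° flexion rather than the trunk angle.
    """
    return sign * relative_angle(arm_pitch, shoulder_pitch)


def arm_abduction(arm_roll, shoulder_roll, sign: float = 1.0) -> np.ndarray:
    """Arm abduction (positive away from the trunk) on the roll axis."""
    return sign * relative_angle(arm_roll, shoulder_roll)


def trunk_angles(cervical: dict, sacrum: dict, axis_map: AxisMap = DEFAULT_AXIS_MAP):
    """(trunk_flexion, trunk_twist) from cervical minus sacral orientation.

    ``cervical``/``sacrum`` map channel names to series (as stored in a
    :class:`~fuzzrula.recording.Recording`).
    """
    flexion = axis_map.flexion_sign * relative_angle(
        cervical[axis_map.pitch], sacrum[axis_map.pitch]
    )
    twist = axis_map.twist_sign * relative_angle(
        cervical[axis_map.yaw], sacrum[axis_map.yaw]
    )
    return flexion, twist


def compute_posture(
    rec: Recording, axis_map: AxisMap = DEFAULT_AXIS_MAP
) -> PostureAngles:
    """Derive all relative posture angles from an aligned six-sensor recording."""
    arm_flexion = {}
    abduction = {}
    for side in SIDES:
        arm, shoulder = SIDE_SENSORS[side]
        arm_flexion[side] = arm_flexion_extension(
            rec.series[arm][axis_map.pitch],
            rec.series[shoulder][axis_map.pitch],
            sign=axis_map.flexion_sign,
        )
        abduction[side] = arm_abduction(
            rec.series[arm][axis_map.roll],
            rec.series[shoulder][axis_map.roll],
            sign=axis_map.abduction_sign[side],
        )
    trunk_flexion, trunk_twist = trunk_angles(
        rec.series["C"], rec.series["S"], axis_map
    )
    return PostureAngles(
        arm_flexion=arm_flexion,
        arm_abduction=abduction,
        trunk_flexion=trunk_flexion,
        trunk_twist=trunk_twist,
        rate=rec.nominal_rate,
    )
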