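"""Crisp RULA worksheet tables and category bins.

The published Rapid Upper Limb Assessment worksheet (McAtamney & Corlett)
combines ordinal posture categories through three lookup tables: Table A
(upper arm × lower arm × wrist × wrist twist), Table B (neck × trunk ×
legs) and Table C (wrist/arm score × neck/trunk/leg score → grand score).
These crisp tables are the ground truth from which the fuzzy rule bases in
:mod:`fuzzrula.rula` are generated, and they double as the independent
reference path for synthetic ground-truth labelling.
"""

from __future__ import annotations

import numpy as np

# Table A: indexed [upper_arm 1-6][lower_arm 1-3][wrist 1-4][wrist_twist 1-2]
_TABLE_A = np.array(
    [  # upper arm 1
        [[[1, 2], [2, 2], [2, 3], [3, 3]],
         [[2, 2], [2, 2], [3, 3], [3, 3]],
         [[2, 3], [3, 3], [3, 3], [4, 4]]],
        # upper arm 2
        [[[2, 3], [3, 3], [3, 4], [4, 4]],
         [[3, 3], [3, 3], [3, 4], [4, 4]],
         [[3, 4], [4, 4], [4, 4], [5, 5]]],
        # upper arm 3
        [[[3, 3], [4, 4], [4, 4], [5, 5]],
         [[3, 4], [4, 4], [4, 4], [5, 5]],
         [[4, 4], [4, 4], [4, 5], [5, 5]]],
        # upper arm 4
        [[[4, 4], [4, 4], [4, 5], [5, 5]],
         [[4, 4], [4, 4], [4, 5], [5, 5]],
         [[4, 4], [4, 5], [5, 5], [6, 6]]],
        # upper arm 5
        [[[5, 5], [5, 5], [5, 6], [6, 7]],
         [[5, 6], [6, 6], [6, 7], [7, 7]],
         [[6, 6], [6, 7], [7, 7], [7, 8]]],
        # upper arm 6
        [[[7, 7], [7, 7], [7, 8], [8, 9]],
         [[8, 8], [8, 8], [8, 9], [9, 9]],
         [[9, 9], [9, 9], [9, 9], [9, 9]]],
    ]
)

# Table B: indexed [neck 1-6][trunk 1-6][legs 1-2]
_TABLE_B = np.array(
    [
        [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],
        [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],
        [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],
        [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],
        [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],
        [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]],
    ]
)

# Table C: indexed [wrist_arm 1-8][neck_trunk_leg 1-7]; higher inputs clip
_TABLE_C = np.array(
    [
        [1, 2, 3, 3, 4, 5, 5],
        [2, 2, 3, 4, 4, 5, 5],
        [3, 3, 3, 4, 4, 5, 6],
        [3, 3, 3, 4, 5, 6, 6],
        [4, 4, 4, 5, 6, 7, 7],
        [4, 4, 5, 6, 6, 7, 7],
        [5, 5, 6, 6, 7, 7, 7],
        [5, 5, 6, 7, 7, 7, 7],
    ]
)


def table_a(upper_arm: int, lower_arm: int, wrist: int, wrist_twist: int) -> int:
    """Group A (wrist & arm) posture score, 1–9."""
    return int(_TABLE_A[upper_arm - 1, lower_arm - 1, wrist - 1, wrist_twist - 1])


def table_b(neck: int, trunk: int, legs: int) -> int:
    """Group B (neck, trunk, legs) posture score, 1–9."""
    return int(_TABLE_B[neck - 1, trunk - 1, legs - 1])


def table_c(score_a: int, score_b: int) -> int:
    """Grand (Total C) score, 1–7; inputs above 8/7 clip to the last row/col."""
    return int(_TABLE_C[min(int(score_a), 8) - 1, min(int(score_b), 7) - 1])


# --- angle → ordinal category bins -------------------------------------------
# Bin edges sit at the 0.5-crossover points of the corresponding fuzzy
# membership functions (see configs/rula_default.yaml), so the crisp and
# fuzzy pathways agree away from category boundaries.

def upper_arm_category(
    flexion_deg: float, abducted: bool = False, shoulder_raised: bool = False
) -> int:
    """Upper-arm posture category from flexion(+)/extension(−), with modifiers.

    ±20° is neutral (1); extension beyond 20° or flexion 20–45° scores 2;
    45–90° scores 3; beyond 90° scores 4.  Abduction and a raised shoulder
    add one point each.
    """
    f = float(flexion_deg)
    if f < -20.0:
        base = 2
    elif f <= 20.0:
        base = 1
    elif f <= 45.0:
        base = 2
    elif f <= 90.0:
        base = 3
    else:
        base = 4
    return min(6, base + int(bool(abducted)) + int(bool(shoulder_raised)))


def is_abducted(abduction_deg: float) -> bool:
    """Arm counts as abducted past 12.5° away from the trunk."""
    return float(abduction_deg) > 12.5


def trunk_category(flexion_deg: float, twisted: bool = False) -> int:
    """Trunk posture category from flexion(+)/extension(−), with twist modifier.

    Near-upright (|angle| < 7.5°, seated and supported) scores 1; slight
    flexion to 20° or slight extension to 20° scores 2; flexion 20–60° or
    extension beyond 20° scores 3; flexion beyond 60° scores 4.  Twisting
    adds one point.
    """
    f = float(flexion_deg)
    if f < -20.0:
        base = 3
    elif f < -7.5:
        base = 2
    elif f <= 7.5:
        base = 1
    elif f <= 20.0:
        base = 2
    elif f <= 60.0:
        base = 3
    else:
        base = 4
    return min(6, base + int(bool(twisted)))


def is_twisted(twist_deg: float) -> bool:
    """Trunk counts as twisted past 7.5° either way (±5° plateau + crossover)."""
    return abs(float(twist_deg)) > 7.5


def crisp_scores(
    arm_flexion: float,
    arm_abduction_deg: float,
    trunk_flexion: float,
    trunk_twist: float,
    *,
    lower_arm: int = 2,
    wrist: int = 2,
    wrist_twist: int = 1,
    neck: int = 1,
    legs: int = 1,
    shoulder_raised: bool = False,
    static: bool = True,
) -> tuple[int, int, int]:
    """Full crisp worksheet chain: (score A, score B, grand score C).

    The static-posture adjustment (+1 to each group when held > 1 min)
    is applied before the Table C lookup, mirroring the fuzzy pipeline.
    """
    ua = upper_arm_category(
        arm_flexion, is_abducted(arm_abduction_deg), shoulder_raised
    )
    a = table_a(ua, lower_arm, wrist, wrist_twist)
    b = table_b(neck, trunk_category(trunk_flexion, is_twisted(trunk_twist)), legs)
    inc = 1 if static else 0
    return a, b, table_c(a + inc, b + inc)
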