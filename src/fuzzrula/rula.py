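"""The three concrete fuzzy models adapting RULA, plus the static adjustment.

Stage one scores the arm (Group A: flexion/extension and abduction measured
by the sensors, with the evaluator's forearm/wrist categories fixed per
trial); stage two scores the trunk (Group B: flexion and twist, with neck
and legs categories fixed).  Both crisp group scores then receive the +1
static-posture adjustment (posture held beyond one minute), and stage three
combines the adjusted scores into the final risk score on [3, 7].

Rule bases are generated from the crisp RULA worksheet tables for the
evaluator categories in force, so editing the shipped YAML config (membership
breakpoints, evaluator defaults) re-derives consistent rules without code
changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import rula_tables
from .biomech import SIDES, PostureAngles
from .errors import ConfigError
from .fuzzy import FISModel, FuzzyRule, LinguisticVariable, MembershipFunction

GROUP_A_UNIVERSE = (3.0, 7.0)
GROUP_B_UNIVERSE = (1.0, 6.0)
FINAL_UNIVERSE = (3.0, 7.0)


@dataclass(frozen=True)
class EvaluatorInputs:
    """Per-trial ordinal worksheet categories entered by the rater.

    These stay constant across a recording; only the sensor-derived angles
    vary per sample.
    """

    lower_arm: int = 2
    wrist: int = 2
    wrist_twist: int = 1
    neck: int = 1
    legs: int = 1
    shoulder_raised: bool = False

    def __post_init__(self) -> None:
        checks = {
            "lower_arm": (self.lower_arm, 1, 3),
            "wrist": (self.wrist, 1, 4),
            "wrist_twist": (self.wrist_twist, 1, 2),
            "neck": (self.neck, 1, 6),
            "legs": (self.legs, 1, 2),
        }
        for name, (value, lo, hi) in checks.items():
            if not lo <= int(value) <= hi:
                raise ConfigError(f"{name}={value} outside worksheet range {lo}–{hi}")


@dataclass
class RulaScores:
    """Per-sample crisp scores for one body side."""

    score_a: np.ndarray  # raw Group A, [3, 7]
    score_b: np.ndarray  # raw Group B, [1, 6]
    adjusted_a: np.ndarray  # [4, 8] with the static increment
    adjusted_b: np.ndarray  # [2, 7]
    score_c: np.ndarray  # final risk, [3, 7]
    rate: float = 50.0

    def __len__(self) -> int:
        return len(self.score_c)


def default_config_path() -> Path:
    return Path(
        importlib.resources.files("fuzzrula") / "configs" / "rula_default.yaml"
    )


def load_config(path: str | Path | None = None) -> dict:
    path = default_config_path() if path is None else Path(path)
    if not path.exists():
        raise ConfigError(f"model config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("group_a", "group_b", "final"):
        if key not in cfg:
            raise ConfigError(f"model config {path} lacks section {key!r}")
    return cfg


def evaluator_from_config(cfg: Mapping) -> EvaluatorInputs:
    return EvaluatorInputs(**cfg.get("evaluator_defaults", {}))


def _variable(name: str, spec: Mapping) -> tuple[LinguisticVariable, dict[str, int]]:
    """Build an input variable; return it plus term → category/modifier map."""
    terms, meta = [], {}
    for t in spec["terms"]:
        terms.append(MembershipFunction.trapezoid(t["label"], *map(float, t["params"])))
        meta[t["label"]] = int(t.get("category", t.get("modifier", 0)))
    return LinguisticVariable(name, tuple(spec["universe"]), terms), meta


def _integer_score_output(name: str, universe, half_width: float) -> LinguisticVariable:
    """Symmetric narrow triangles at each integer score of the universe."""
    lo, hi = universe
    terms = [
        MembershipFunction.triangle(str(i), i - half_width, i, i + half_width)
        for i in range(int(lo), int(hi) + 1)
    ]
    return LinguisticVariable(name, tuple(map(float, universe)), terms)


def _integer_score_input(name: str, universe) -> LinguisticVariable:
    """Staggered trapezoids at each integer score of the universe.

    Each score owns a plateau [i − 0.5, i + 0.5]; the next term's rise
    ([i + 0.3, i + 0.5]) completes before this term's fall ([i + 0.5,
    i + 0.7]) begins.  Under minimum-AND with maximum aggregation this
    staggering keeps the defuzzified surface monotone along a monotone rule
    table: a simultaneous two-term crossfade would let a lower consequent's
    strength dip and recover while a higher one stays capped, rippling the
    surface.
    """
    lo, hi = int(universe[0]), int(universe[1])
    terms = []
    for i in range(lo, hi + 1):
        a = float(lo) if i == lo else i - 0.7
        b = float(lo) if i == lo else i - 0.5
        c = float(hi) if i == hi else i + 0.5
        d = float(hi) if i == hi else i + 0.7
        terms.append(MembershipFunction.trapezoid(str(i), a, b, c, d))
    return LinguisticVariable(name, (float(lo), float(hi)), terms)


def _clamp_label(score: int, universe) -> str:
    lo, hi = int(universe[0]), int(universe[1])
    return str(max(lo, min(hi, score)))


def build_group_a_model(
    config: Mapping | None = None, evaluator: EvaluatorInputs | None = None
) -> FISModel:
    """Group A model: arm flexion/extension × abduction → score on [3, 7].

    The consequent of each (flexion term, abduction term) pair is the crisp
    Table A score for the implied upper-arm category under the evaluator's
    forearm/wrist categories, clamped to the output universe.
    """
    cfg = load_config() if config is None else config
    ev = evaluator_from_config(cfg) if evaluator is None else evaluator
    spec = cfg["group_a"]
    flexion, flex_cat = _variable("arm_flexion", spec["flexion"])
    abduction, abd_mod = _variable("arm_abduction", spec["abduction"])
    out_spec = spec["output"]
    output = _integer_score_output(
        "score_a", out_spec["universe"], float(out_spec.get("half_width", 0.5))
    )
    rules = []
    for f_label, base in flex_cat.items():
        for a_label, mod in abd_mod.items():
            ua = min(6, base + mod + int(ev.shoulder_raised))
            score = rula_tables.table_a(ua, ev.lower_arm, ev.wrist, ev.wrist_twist)
            rules.append(
                FuzzyRule.of(
                    {"arm_flexion": f_label, "arm_abduction": a_label},
                    _clamp_label(score, out_spec["universe"]),
                )
            )
    model = FISModel(
        [flexion, abduction], output, rules,
        resolution=int(cfg.get("defuzz_resolution", 1001)),
    )
    model.validate_coverage()
    return model


def build_group_b_model(
    config: Mapping | None = None, evaluator: EvaluatorInputs | None = None
) -> FISModel:
    """Group B model: trunk flexion × trunk twist → score on [1, 6]."""
    cfg = load_config() if config is None else config
    ev = evaluator_from_config(cfg) if evaluator is None else evaluator
    spec = cfg["group_b"]
    flexion, flex_cat = _variable("trunk_flexion", spec["trunk_flexion"])
    twist, twist_mod = _variable("trunk_twist", spec["trunk_twist"])
    out_spec = spec["output"]
    output = _integer_score_output(
        "score_b", out_spec["universe"], float(out_spec.get("half_width", 0.5))
    )
    rules = []
    for f_label, base in flex_cat.items():
        for t_label, mod in twist_mod.items():
            trunk = min(6, base + mod)
            score = rula_tables.table_b(ev.neck, trunk, ev.legs)
            rules.append(
                FuzzyRule.of(
                    {"trunk_flexion": f_label, "trunk_twist": t_label},
                    _clamp_label(score, out_spec["universe"]),
                )
            )
    model = FISModel(
        [flexion, twist], output, rules,
        resolution=int(cfg.get("defuzz_resolution", 1001)),
    )
    model.validate_coverage()
    return model


def apply_static_adjustment(score, static: bool = True):
    """Add the +1 point for a posture held beyond one minute.

    Raw Group A scores on [3, 7] become [4, 8]; Group B [1, 6] becomes
    [2, 7].  Scalars and arrays both pass through.
    """
    if not static:
        return score
    return np.asarray(score, dtype=float) + 1.0 if np.ndim(score) else float(score) + 1.0


def build_final_model(config: Mapping | None = None) -> FISModel:
    """Final model: adjusted A [4, 8] × adjusted B [2, 7] → risk on [3, 7].

    Input terms are staggered trapezoids at each integer score; the output has
    a medium trapezoid over scores 3–4, a high trapezoid over 5–6 and a
    severe triangle at 7, all symmetric so their clipped centroids stay
    put.  Rule consequents follow the crisp Table C grand-score matrix.
    """
    cfg = load_config() if config is None else config
    spec = cfg["final"]
    a_var = _integer_score_input("adjusted_a", spec["input_a"]["universe"])
    b_var = _integer_score_input("adjusted_b", spec["input_b"]["universe"])
    out_spec = spec["output"]
    output = LinguisticVariable(
        "score_c",
        tuple(map(float, out_spec["universe"])),
        [MembershipFunction.from_dict(t) for t in out_spec["terms"]],
    )
    labels = list(output.terms)
    if len(labels) != 3:
        raise ConfigError("final output must define exactly three risk terms")
    medium, high, severe = labels

    def category(c: int) -> str:
        if c <= 4:
            return medium
        if c <= 6:
            return high
        return severe

    rules = []
    for i in range(int(spec["input_a"]["universe"][0]), int(spec["input_a"]["universe"][1]) + 1):
        for j in range(int(spec["input_b"]["universe"][0]), int(spec["input_b"]["universe"][1]) + 1):
            rules.append(
                FuzzyRule.of(
                    {"adjusted_a": str(i), "adjusted_b": str(j)},
                    category(rula_tables.table_c(i, j)),
                )
            )
    model = FISModel(
        [a_var, b_var], output, rules,
        resolution=int(cfg.get("defuzz_resolution", 1001)),
    )
    model.validate_coverage()
    return model


@dataclass
class RulaPipeline:
    """The assembled three-stage scorer for one evaluator configuration."""

    group_a: FISModel
    group_b: FISModel
    final: FISModel
    evaluator: EvaluatorInputs = field(default_factory=EvaluatorInputs)

    @classmethod
    def from_config(
        cls,
        config: Mapping | str | Path | None = None,
        evaluator: EvaluatorInputs | None = None,
    ) -> "RulaPipeline":
        if config is None or isinstance(config, (str, Path)):
            config = load_config(config)
        ev = evaluator_from_config(config) if evaluator is None else evaluator
        return cls(
            group_a=build_group_a_model(config, ev),
            group_b=build_group_b_model(config, ev),
            final=build_final_model(config),
            evaluator=ev,
        )

    def score_side(
        self,
        arm_flexion: np.ndarray,
        arm_abduction: np.ndarray,
        trunk_flexion: np.ndarray,
        trunk_twist: np.ndarray,
        static: bool = True,
        rate: float = 50.0,
    ) -> RulaScores:
        a = self.group_a.infer_many(
            {"arm_flexion": arm_flexion, "arm_abduction": arm_abduction}
        )
        b = self.group_b.infer_many(
            {"trunk_flexion": trunk_flexion, "trunk_twist": trunk_twist}
        )
        a_adj = apply_static_adjustment(a, static)
        b_adj = apply_static_adjustment(b, static)
        c = self.final.infer_many({"adjusted_a": a_adj, "adjusted_b": b_adj})
        return RulaScores(a, b, np.asarray(a_adj), np.asarray(b_adj), c, rate)

    def score_timeline(
        self, posture: PostureAngles, static: bool = True
    ) -> dict[str, RulaScores]:
        """Per-sample score chain for both body sides of an aligned posture."""
        return {
            side: self.score_side(
                posture.arm_flexion[side],
                posture.arm_abduction[side],
                posture.trunk_flexion,
                posture.trunk_twist,
                static=static,
                rate=posture.rate,
            )
            for side in SIDES
        }


def score_timeline(
    posture: PostureAngles,
    evaluator: EvaluatorInputs | None = None,
    static: bool = True,
    config: Mapping | str | Path | None = None,
) -> dict[str, RulaScores]:
    """Convenience wrapper: build the default pipeline and score a posture."""
    return RulaPipeline.from_config(config, evaluator).score_timeline(posture, static)
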