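"""Mamdani engine: membership evaluation, inference, centroid defuzzification.

The engine is cross-checked against an independently written fine-grid
numeric centroid (piecewise membership evaluated with np.select, Riemann
centroid on ≥10⁵ points) that shares no code with the engine's
trapezoid-integration path.
"""

import numpy as np
import pytest

from fuzzrula.errors import InferenceError, ModelValidationError
from fuzzrula.fuzzy import (
    FISModel,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
)

# ---------------------------------------------------------------- oracle

def oracle_mu(x, a, b, c, d):
    """Independent trapezoid membership (np.select formulation)."""
    x = np.asarray(x, dtype=float)
    rising = (x - a) / (b - a) if b > a else np.ones_like(x)
    falling = (d - x) / (d - c) if d > c else np.ones_like(x)
    return np.select(
        [x < a, x < b, x <= c, x < d],
        [0.0, rising, 1.0, falling],
        default=0.0,
    )


def oracle_centroid(model, crisp, points=100_001):
    """Brute-force Mamdani centroid on a dense grid."""
    lo = min(
        [model.output.universe[0]] + [mf.a for mf in model.output.terms.values()]
    )
    hi = max(
        [model.output.universe[1]] + [mf.d for mf in model.output.terms.values()]
    )
    grid = np.linspace(lo, hi, points)
    agg = np.zeros_like(grid)
    for rule in model.rules:
        strength = 1.0
        for var, term in rule.antecedents:
            v = model.inputs[var]
            x = min(max(crisp[var], v.universe[0]), v.universe[1])
            mf = v.terms[term]
            strength = min(strength, float(oracle_mu(x, mf.a, mf.b, mf.c, mf.d)))
        out = model.output.terms[rule.consequent]
        agg = np.maximum(agg, np.minimum(strength, oracle_mu(grid, out.a, out.b, out.c, out.d)))
    total = agg.sum()
    if total == 0:
        return None
    return float((agg * grid).sum() / total)


def random_partition_variable(name, rng, lo=0.0, hi=10.0, n_terms=3):
    """Shouldered trapezoids covering [lo, hi] so every input fires a rule."""
    knots = np.sort(rng.uniform(lo + 0.5, hi - 0.5, n_terms - 1))
    width = rng.uniform(0.2, 0.6)
    edges = np.concatenate([[lo], knots, [hi]])
    terms = []
    for i in range(n_terms):
        a = lo if i == 0 else edges[i] - width
        b = lo if i == 0 else edges[i] + width
        c = hi if i == n_terms - 1 else edges[i + 1] - width
        d = hi if i == n_terms - 1 else edges[i + 1] + width
        b, c = min(b, c), max(b, c)
        a = min(a, b)
        d = max(c, d)
        terms.append(MembershipFunction.trapezoid(f"t{i}", a, b, c, d))
    return LinguisticVariable(name, (lo, hi), terms)


def random_model(rng):
    n_in = int(rng.integers(1, 3))
    inputs = [
        random_partition_variable(f"x{i}", rng, n_terms=int(rng.integers(2, 4)))
        for i in range(n_in)
    ]
    n_out = int(rng.integers(2, 5))
    centers = np.sort(rng.uniform(0.5, 9.5, n_out))
    half = rng.uniform(0.4, 1.5, n_out)
    out_terms = [
        MembershipFunction.trapezoid(
            f"o{i}", c - h, c - h / 3, c + h / 3, c + h
        )
        for i, (c, h) in enumerate(zip(centers, half))
    ]
    output = LinguisticVariable("y", (0.0, 10.0), out_terms)
    from itertools import product

    rules = [
        FuzzyRule.of(
            {v.name: t for v, t in zip(inputs, combo)},
            f"o{rng.integers(0, n_out)}",
        )
        for combo in product(*(list(v.terms) for v in inputs))
    ]
    return FISModel(inputs, output, rules, resolution=1001)


# ---------------------------------------------------------------- tests

class TestMembership:
    @pytest.mark.parametrize(
        "mf,x,mu",
        [
            (MembershipFunction.triangle("m", 2, 3, 4), 3.0, 1.0),
            (MembershipFunction.triangle("m", 2, 3, 4), 5.0, 0.0),
            (MembershipFunction.triangle("m", 2, 3, 4), 2.5, 0.5),
            (MembershipFunction.trapezoid("m", 0, 1, 2, 3), 0.5, 0.5),
            (MembershipFunction.trapezoid("m", 0, 1, 2, 3), 1.5, 1.0),
            (MembershipFunction.trapezoid("m", 0, 0, 2, 3), 0.0, 1.0),  # shoulder
        ],
    )
    def test_piecewise_linear_evaluation(self, mf, x, mu):
        assert float(mf(x)) == pytest.approx(mu)

    def test_breakpoint_order_enforced(self):
        with pytest.raises(ModelValidationError):
            MembershipFunction.trapezoid("bad", 3, 2, 4, 5)

    def test_dict_roundtrip(self):
        mf = MembershipFunction.trapezoid("m", 0, 1, 2, 3)
        assert MembershipFunction.from_dict(mf.to_dict()) == mf


def single_rule_model(consequent, universe=(0.0, 10.0)):
    x = LinguisticVariable(
        "x", (0.0, 1.0), [MembershipFunction.trapezoid("on", 0, 0, 1, 1)]
    )
    y = LinguisticVariable("y", universe, [consequent])
    return FISModel([x], y, [FuzzyRule.of({"x": "on"}, consequent.label)])


class TestInference:
    def test_full_strength_symmetric_triangle_centres(self):
        m = single_rule_model(MembershipFunction.triangle("mid", 2, 3, 4))
        assert m.infer({"x": 0.5}) == pytest.approx(3.0, abs=1e-9)

    def test_clipped_symmetric_triangle_still_centres(self):
        # strength 0.5 via a half-membership antecedent
        x = LinguisticVariable(
            "x", (0.0, 1.0), [MembershipFunction.trapezoid("ramp", 0, 1, 1, 1)]
        )
        y = LinguisticVariable(
            "y", (0.0, 10.0), [MembershipFunction.triangle("mid", 2, 3, 4)]
        )
        m = FISModel([x], y, [FuzzyRule.of({"x": "ramp"}, "mid")])
        assert m.infer({"x": 0.5}) == pytest.approx(3.0, abs=1e-6)

    def test_two_equal_rules_average_symmetric_consequents(self):
        x = LinguisticVariable(
            "x", (0.0, 1.0), [MembershipFunction.trapezoid("on", 0, 0, 1, 1)]
        )
        y = LinguisticVariable(
            "y",
            (0.0, 10.0),
            [
                MembershipFunction.triangle("lo", 2, 3, 4),
                MembershipFunction.triangle("hi", 4, 5, 6),
            ],
        )
        m = FISModel(
            [x], y, [FuzzyRule.of({"x": "on"}, "lo"), FuzzyRule.of({"x": "on"}, "hi")]
        )
        got = m.infer({"x": 0.5})
        want = oracle_centroid(m, {"x": 0.5})
        assert got == pytest.approx(4.0, abs=1e-6)
        assert got == pytest.approx(want, abs=1e-6)

    def test_missing_input_is_an_error(self):
        m = single_rule_model(MembershipFunction.triangle("mid", 2, 3, 4))
        with pytest.raises(InferenceError):
            m.infer({})

    def test_no_rule_fired_strict_vs_midpoint(self):
        x = LinguisticVariable(
            "x", (0.0, 10.0), [MembershipFunction.trapezoid("low", 0, 0, 1, 2)]
        )
        y = LinguisticVariable(
            "y", (0.0, 10.0), [MembershipFunction.triangle("mid", 4, 5, 6)]
        )
        rules = [FuzzyRule.of({"x": "low"}, "mid")]
        strict = FISModel([x], y, rules, fallback="error")
        with pytest.raises(InferenceError):
            strict.infer({"x": 9.0})
        soft = FISModel([x], y, rules, fallback="midpoint")
        assert soft.infer({"x": 9.0}) == pytest.approx(5.0)

    def test_inputs_outside_universe_are_clipped(self):
        m = single_rule_model(MembershipFunction.triangle("mid", 2, 3, 4))
        assert m.infer({"x": 99.0}) == pytest.approx(m.infer({"x": 1.0}))

    def test_validation_catches_unknown_terms(self):
        x = LinguisticVariable(
            "x", (0.0, 1.0), [MembershipFunction.trapezoid("on", 0, 0, 1, 1)]
        )
        y = LinguisticVariable(
            "y", (0.0, 1.0), [MembershipFunction.triangle("mid", 0, 0.5, 1)]
        )
        with pytest.raises(ModelValidationError):
            FISModel([x], y, [FuzzyRule.of({"x": "nope"}, "mid")])
        with pytest.raises(ModelValidationError):
            FISModel([x], y, [FuzzyRule.of({"x": "on"}, "nope")])

    def test_model_dict_roundtrip_preserves_inference(self):
        rng = np.random.default_rng(7)
        m = random_model(rng)
        m2 = FISModel.from_dict(m.to_dict())
        xs = {name: 3.3 for name in m.inputs}
        assert m2.infer(xs) == pytest.approx(m.infer(xs), abs=1e-12)


class TestCentroidProperties:
    def test_engine_matches_independent_oracle_on_random_models(self):
        """Engine vs ≥10⁵-point brute-force centroid, 200 random models."""
        rng = np.random.default_rng(20240917)
        checked = 0
        while checked < 200:
            model = random_model(rng)
            crisp = {name: float(rng.uniform(0, 10)) for name in model.inputs}
            want = oracle_centroid(model, crisp)
            if want is None:
                continue
            got = model.infer(crisp)
            assert got == pytest.approx(want, abs=1e-3)
            checked += 1

    def test_centroid_lies_within_aggregated_support(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            model = random_model(rng)
            crisp = {name: float(rng.uniform(0, 10)) for name in model.inputs}
            strengths = model.firing_strengths(
                {k: np.array([v]) for k, v in crisp.items()}
            )[:, 0]
            supports = [
                model.output.terms[r.consequent].support
                for r, s in zip(model.rules, strengths)
                if s > 0
            ]
            if not supports:
                continue
            lo = min(s[0] for s in supports)
            hi = max(s[1] for s in supports)
            got = model.infer(crisp)
            assert lo - 1e-9 <= got <= hi + 1e-9

    def test_uniform_strength_scaling_keeps_symmetric_centroid(self):
        for strength_x in (1.0, 0.6, 0.25):
            x = LinguisticVariable(
                "x", (0.0, 1.0), [MembershipFunction.trapezoid("ramp", 0, 1, 1, 1)]
            )
            y = LinguisticVariable(
                "y", (0.0, 10.0), [MembershipFunction.triangle("mid", 2, 3, 4)]
            )
            m = FISModel([x], y, [FuzzyRule.of({"x": "ramp"}, "mid")])
            assert m.infer({"x": strength_x}) == pytest.approx(3.0, abs=1e-6)

    def test_vectorised_and_scalar_paths_agree(self):
        rng = np.random.default_rng(3)
        model = random_model(rng)
        names = list(model.inputs)
        xs = {n: rng.uniform(0, 10, 64) for n in names}
        many = model.infer_many(xs)
        for i in rng.integers(0, 64, 8):
            one = model.infer({n: float(xs[n][i]) for n in names})
            assert many[i] == pytest.approx(one, abs=1e-12)
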