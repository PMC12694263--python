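"""A generic Mamdani fuzzy-inference engine.

Four classical stages: fuzzification through piecewise-linear
(trapezoidal/triangular) membership functions, AND-rule evaluation with the
minimum t-norm, implication by clipping each consequent at its rule's
firing strength, pointwise-maximum aggregation, and centroid
defuzzification of the aggregated shape on a uniform grid over the output
universe.

The engine is vectorised: :meth:`FISModel.infer_many` evaluates thousands
of crisp input tuples at once, which is what makes per-sample risk scoring
of 15,000-sample recordings practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InferenceError, ModelValidationError

DEFAULT_RESOLUTION = 1001


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoid ``(a, b, c, d)``; a triangle is the degenerate case b == c.

    Membership rises linearly on [a, b], is 1 on the plateau [b, c] and
    falls linearly on [c, d].  Coincident breakpoints give vertical edges
    (shoulders), with membership 1 at the shared abscissa.
    """

    label: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ModelValidationError(
                f"{self.label}: breakpoints must satisfy a ≤ b ≤ c ≤ d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    @classmethod
    def trapezoid(cls, label: str, a: float, b: float, c: float, d: float):
        return cls(label, a, b, c, d)

    @classmethod
    def triangle(cls, label: str, a: float, b: float, c: float):
        return cls(label, a, b, b, c)

    @property
    def is_triangle(self) -> bool:
        return self.b == self.c

    @property
    def support(self) -> tuple[float, float]:
        return (self.a, self.d)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.b > self.a:
            up = (x - self.a) / (self.b - self.a)
        else:  # vertical left edge: full membership from b onward
            up = np.where(x >= self.b, 1.0, 0.0)
        if self.d > self.c:
            down = (self.d - x) / (self.d - self.c)
        else:
            down = np.where(x <= self.c, 1.0, 0.0)
        return np.clip(np.minimum(up, down), 0.0, 1.0)

    def to_dict(self) -> dict:
        if self.is_triangle:
            return {"label": self.label, "shape": "triangle",
                    "params": [self.a, self.b, self.d]}
        return {"label": self.label, "shape": "trapezoid",
                "params": [self.a, self.b, self.c, self.d]}

    @classmethod
    def from_dict(cls, spec: Mapping) -> "MembershipFunction":
        shape = spec.get("shape", "trapezoid")
        params = [float(p) for p in spec["params"]]
        if shape == "triangle":
            return cls.triangle(spec["label"], *params)
        if shape == "trapezoid":
            return cls.trapezoid(spec["label"], *params)
        raise ModelValidationError(f"unknown MF shape {shape!r}")


@dataclass
class LinguisticVariable:
    """A named crisp axis with its linguistic terms."""

    name: str
    universe: tuple[float, float]
    terms: dict[str, MembershipFunction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ModelValidationError(f"{self.name}: universe must have lo < hi")
        if isinstance(self.terms, (list, tuple)):
            self.terms = {mf.label: mf for mf in self.terms}
        # allow supports to spill modestly (half a span) past the universe,
        # e.g. symmetric edge terms centred on a universe endpoint
        margin = 0.5 * (hi - lo)
        for mf in self.terms.values():
            if mf.a < lo - margin or mf.d > hi + margin:
                raise ModelValidationError(
                    f"{self.name}/{mf.label}: support {mf.support} far outside "
                    f"universe {self.universe}"
                )

    def add(self, mf: MembershipFunction) -> None:
        self.terms[mf.label] = mf

    def clip(self, x) -> np.ndarray:
        lo, hi = self.universe
        return np.clip(np.asarray(x, dtype=float), lo, hi)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "universe": list(self.universe),
            "terms": [mf.to_dict() for mf in self.terms.values()],
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "LinguisticVariable":
        return cls(
            name=spec["name"],
            universe=tuple(spec["universe"]),
            terms=[MembershipFunction.from_dict(t) for t in spec["terms"]],
        )


@dataclass(frozen=True)
class FuzzyRule:
    """IF antecedents (ANDed) THEN output term."""

    antecedents: tuple[tuple[str, str], ...]  # (variable, term) pairs
    consequent: str  # output term label

    @classmethod
    def of(cls, antecedents: Mapping[str, str] | Sequence, consequent: str):
        if isinstance(antecedents, Mapping):
            antecedents = tuple(antecedents.items())
        return cls(tuple(antecedents), consequent)

    def to_dict(self) -> dict:
        return {"if": dict(self.antecedents), "then": self.consequent}


class FISModel:
    """A complete Mamdani model: inputs, output, rule base, defuzz settings.

    Parameters
    ----------
    inputs, output
        Linguistic variables. Crisp inputs outside an input universe are
        clipped to its edge (measured angles can exceed nominal ranges).
    rules
        The rule base; every referenced variable/term must exist.
    resolution
        Grid-point count for centroid defuzzification (default 1001).
    fallback
        What to do when no rule fires with positive strength: ``"error"``
        (strict) or ``"midpoint"`` of the output universe.
    """

    def __init__(
        self,
        inputs: Sequence[LinguisticVariable],
        output: LinguisticVariable,
        rules: Sequence[FuzzyRule],
        resolution: int = DEFAULT_RESOLUTION,
        fallback: str = "error",
    ) -> None:
        if not rules:
            raise ModelValidationError("a model needs at least one rule")
        if resolution < 2:
            raise ModelValidationError("resolution must be at least 2")
        if fallback not in ("error", "midpoint"):
            raise ModelValidationError("fallback must be 'error' or 'midpoint'")
        self.inputs = {v.name: v for v in inputs}
        self.output = output
        self.rules = list(rules)
        self.resolution = int(resolution)
        self.fallback = fallback
        # the grid must span the full support of every output term: truncating
        # an edge term at the universe boundary would skew its centroid
        lo, hi = output.universe
        if output.terms:
            lo = min(lo, min(mf.a for mf in output.terms.values()))
            hi = max(hi, max(mf.d for mf in output.terms.values()))
        self._grid = np.linspace(lo, hi, self.resolution)
        self._validate()

    def _validate(self) -> None:
        for rule in self.rules:
            for var, term in rule.antecedents:
                if var not in self.inputs:
                    raise ModelValidationError(f"rule references unknown input {var!r}")
                if term not in self.inputs[var].terms:
                    raise ModelValidationError(
                        f"rule references unknown term {var}.{term!r}"
                    )
            if rule.consequent not in self.output.terms:
                raise ModelValidationError(
                    f"rule references unknown output term {rule.consequent!r}"
                )

    def validate_coverage(self) -> None:
        """Require a rule for every combination of input terms."""
        from itertools import product

        names = list(self.inputs)
        have = {tuple(dict(r.antecedents).get(n) for n in names) for r in self.rules}
        for combo in product(*(self.inputs[n].terms for n in names)):
            if combo not in have:
                raise ModelValidationError(
                    f"no rule covers input-term combination {dict(zip(names, combo))}"
                )

    def firing_strengths(self, crisp: Mapping[str, np.ndarray]) -> np.ndarray:
        """(n_rules, N) minimum-AND strengths for clipped crisp inputs."""
        missing = set(self.inputs) - set(crisp)
        if missing:
            raise InferenceError(f"missing crisp input(s): {sorted(missing)}")
        clipped = {name: self.inputs[name].clip(crisp[name]) for name in self.inputs}
        cache: dict[tuple[str, str], np.ndarray] = {}
        strengths = []
        for rule in self.rules:
            mus = []
            for var, term in rule.antecedents:
                key = (var, term)
                if key not in cache:
                    cache[key] = self.inputs[var].terms[term](clipped[var])
                mus.append(cache[key])
            strengths.append(np.minimum.reduce(mus))
        return np.stack(strengths)

    def infer_many(self, crisp: Mapping[str, "np.ndarray"]) -> np.ndarray:
        """Crisp outputs for N simultaneous input tuples (1-D arrays)."""
        arrays = {k: np.atleast_1d(np.asarray(v, float)) for k, v in crisp.items()}
        lengths = {a.size for a in arrays.values()}
        if len(lengths) != 1:
            raise InferenceError(f"input lengths disagree: {sorted(lengths)}")
        n = lengths.pop()
        strengths = self.firing_strengths(arrays)  # (R, N)
        grid = self._grid
        cons = np.stack([self.output.terms[r.consequent](grid) for r in self.rules])
        out = np.empty(n)
        chunk = max(1, int(4e6) // self.resolution)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            agg = np.zeros((sl.stop - sl.start, self.resolution))
            for r in range(len(self.rules)):
                np.maximum(
                    agg,
                    np.minimum(strengths[r, sl, None], cons[r][None, :]),
                    out=agg,
                )
            den = np.trapezoid(agg, grid, axis=1)
            num = np.trapezoid(agg * grid, grid, axis=1)
            dead = den <= 0.0
            if np.any(dead):
                if self.fallback == "error":
                    raise InferenceError(
                        "no rule fired with positive strength for some inputs"
                    )
                mid = 0.5 * (self.output.universe[0] + self.output.universe[1])
                num[dead], den[dead] = mid, 1.0
            out[sl] = num / den
        return out

    def infer(self, crisp: Mapping[str, float]) -> float:
        """Crisp output for a single input tuple."""
        return float(self.infer_many({k: [v] for k, v in crisp.items()})[0])

    def to_dict(self) -> dict:
        return {
            "inputs": [v.to_dict() for v in self.inputs.values()],
            "output": self.output.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
            "resolution": self.resolution,
            "fallback": self.fallback,
        }

    @classmethod
    def from_dict(cls, spec: Mapping) -> "FISModel":
        return cls(
            inputs=[LinguisticVariable.from_dict(v) for v in spec["inputs"]],
            output=LinguisticVariable.from_dict(spec["output"]),
            rules=[FuzzyRule.of(r["if"], r["then"]) for r in spec["rules"]],
            resolution=spec.get("resolution", DEFAULT_RESOLUTION),
            fallback=spec.get("fallback", "error"),
        )
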