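"""The six second-round response models as structured objects.

Each model is a centered second-order polynomial in the environmental
factors (e.g. dark respiration CR as a linear function of acetate,
light and ammonium plus an acetate-ammonium interaction).  The module
evaluates the polynomials, draws single-factor profiles with the other
factors held at their fit-sample means, solves quadratic profile optima
in closed form, and produces interaction slices at the extremes of a
conditioning factor's working range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .factors import EffectTerm, FactorSpec, factors_by_name, table1_factors

__all__ = [
    "QuadraticTerm",
    "InteractionTerm",
    "Vertex",
    "ProfileCurve",
    "PublishedModel",
    "load_published_models",
]


@dataclass(frozen=True)
class QuadraticTerm:
    factor: str
    coef: float
    center: float


@dataclass(frozen=True)
class InteractionTerm:
    factor_a: str
    factor_b: str
    coef: float
    center_a: float
    center_b: float

    def involves(self, factor: str) -> bool:
        return factor in (self.factor_a, self.factor_b)

    def other(self, factor: str) -> tuple[str, float]:
        """The partner factor and its centering constant."""
        if factor == self.factor_a:
            return self.factor_b, self.center_b
        if factor == self.factor_b:
            return self.factor_a, self.center_a
        raise ValueError(f"{factor!r} not in interaction")


@dataclass(frozen=True)
class Vertex:
    location: float
    value: float
    curvature: str  # "concave" (maximum) or "convex" (minimum)


@dataclass
class ProfileCurve:
    response: str
    factor: str
    grid: np.ndarray
    values: np.ndarray
    fixed: dict[str, float]
    vertex: Vertex | None = None


@dataclass
class PublishedModel:
    """A centered polynomial response model with printed coefficients."""

    response: str
    intercept: float
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: list[QuadraticTerm] = field(default_factory=list)
    interaction: list[InteractionTerm] = field(default_factory=list)
    factor_means: dict[str, float] = field(default_factory=dict)
    unit: str = ""

    @property
    def factor_names(self) -> list[str]:
        seen: list[str] = list(self.linear)
        for q in self.quadratic:
            if q.factor not in seen:
                seen.append(q.factor)
        for it in self.interaction:
            for f in (it.factor_a, it.factor_b):
                if f not in seen:
                    seen.append(f)
        return seen

    # ---- evaluation --------------------------------------------------

    def predict(
        self,
        combination: Mapping[str, float],
        factors: Sequence[FactorSpec] | None = None,
    ):
        """Evaluate the polynomial; warns (not errors) outside the working range."""
        missing = [f for f in self.factor_names if f not in combination]
        if missing:
            raise KeyError(f"missing factor values: {missing}")
        fmap = factors_by_name(factors if factors is not None else table1_factors())
        for name in self.factor_names:
            spec = fmap.get(name)
            vals = np.atleast_1d(np.asarray(combination[name], dtype=float))
            if spec is not None and spec.is_continuous:
                if (vals < spec.low).any() or (vals > spec.high).any():
                    warnings.warn(
                        f"{name} outside working range [{spec.low}, {spec.high}]",
                        stacklevel=2,
                    )
        out = np.asarray(self.intercept, dtype=float)
        for f, b in self.linear.items():
            out = out + b * np.asarray(combination[f], dtype=float)
        for q in self.quadratic:
            out = out + q.coef * (np.asarray(combination[q.factor], dtype=float) - q.center) ** 2
        for it in self.interaction:
            xa = np.asarray(combination[it.factor_a], dtype=float) - it.center_a
            xb = np.asarray(combination[it.factor_b], dtype=float) - it.center_b
            out = out + it.coef * xa * xb
        return out if out.ndim else float(out)

    # ---- profiles & optima ------------------------------------------

    def _fixed_values(self, factor: str, overrides: Mapping[str, float] | None = None) -> dict:
        fixed = {f: self.factor_means[f] for f in self.factor_names if f != factor}
        if overrides:
            fixed.update({k: float(v) for k, v in overrides.items() if k != factor})
        return fixed

    def effective_linear(self, factor: str, fixed: Mapping[str, float]) -> float:
        """Slope of the profile in ``factor`` after substituting fixed values.

        d(y)/d(factor) at the quadratic center: the printed linear
        coefficient plus each interaction coefficient times the fixed
        partner's centered value.
        """
        b = self.linear.get(factor, 0.0)
        for it in self.interaction:
            if it.involves(factor):
                other, c_other = it.other(factor)
                b += it.coef * (float(fixed[other]) - c_other)
        return b

    def vertex(
        self, factor: str, fixed: Mapping[str, float] | None = None
    ) -> Vertex | None:
        """Closed-form optimum of the quadratic profile in ``factor``.

        Returns None when the model has no quadratic term in the factor.
        The location is ``c - b_eff / (2 a)`` for the quadratic
        ``a (x - c)^2`` and effective slope ``b_eff``.
        """
        quad = next((q for q in self.quadratic if q.factor == factor), None)
        if quad is None or quad.coef == 0.0:
            return None
        fixed = self._fixed_values(factor, fixed)
        b_eff = self.effective_linear(factor, fixed)
        loc = quad.center - b_eff / (2.0 * quad.coef)
        value = float(self.predict({**fixed, factor: loc}))
        return Vertex(loc, value, "concave" if quad.coef < 0 else "convex")

    def profile(
        self,
        factor: str,
        grid_size: int = 101,
        fixed: Mapping[str, float] | None = None,
        factors: Sequence[FactorSpec] | None = None,
    ) -> ProfileCurve:
        """Response curve along one factor, the others held fixed.

        By default the other factors sit at the model's fit-sample means
        and the grid spans the factor's working range.
        """
        if factor not in self.factor_names:
            raise ValueError(f"{factor!r} is not a factor of model {self.response}")
        fmap = factors_by_name(factors if factors is not None else table1_factors())
        spec = fmap[factor]
        grid = np.linspace(spec.range_min, spec.range_max, grid_size)
        fixed_vals = self._fixed_values(factor, fixed)
        values = np.asarray(self.predict({**fixed_vals, factor: grid}))
        return ProfileCurve(
            self.response, factor, grid, values, fixed_vals, self.vertex(factor, fixed_vals)
        )

    def interaction_slice(
        self,
        factor: str,
        conditioning_factor: str,
        at: tuple[float, float] | None = None,
        grid_size: int = 101,
        factors: Sequence[FactorSpec] | None = None,
    ) -> tuple[ProfileCurve, ProfileCurve]:
        """Two profiles of ``factor`` at low/high values of a partner factor.

        The pair must share an interaction term; remaining factors stay
        at the fit-sample means.  ``at`` defaults to the conditioning
        factor's working-range extremes.
        """
        if not any(
            it.involves(factor) and it.involves(conditioning_factor)
            for it in self.interaction
        ):
            raise ValueError(
                f"model {self.response} has no {factor} x {conditioning_factor} interaction"
            )
        fmap = factors_by_name(factors if factors is not None else table1_factors())
        if at is None:
            cspec = fmap[conditioning_factor]
            at = (cspec.range_min, cspec.range_max)
        lo = self.profile(factor, grid_size, {conditioning_factor: at[0]}, factors)
        hi = self.profile(factor, grid_size, {conditioning_factor: at[1]}, factors)
        return lo, hi

    # ---- bridges to the fitting layer -------------------------------

    def terms(self) -> list[EffectTerm]:
        out = [EffectTerm("linear", (f,)) for f in self.linear]
        out += [EffectTerm("quadratic", (q.factor,)) for q in self.quadratic]
        out += [EffectTerm("interaction", tuple(sorted((it.factor_a, it.factor_b))))
                for it in self.interaction]
        return out

    def centers(self) -> dict[str, float]:
        """Centering constants for re-fitting in the printed parameterization."""
        c: dict[str, float] = {}
        for q in self.quadratic:
            c[q.factor] = q.center
        for it in self.interaction:
            c.setdefault(it.factor_a, it.center_a)
            c.setdefault(it.factor_b, it.center_b)
        for f, v in self.factor_means.items():
            c.setdefault(f, v)
        return c

    def coefficients(self) -> dict[str, float]:
        """Coefficient per term name, plus ``intercept``."""
        out = {"intercept": self.intercept}
        for f, b in self.linear.items():
            out[f] = b
        for q in self.quadratic:
            out[f"{q.factor}^2"] = q.coef
        for it in self.interaction:
            a, b = sorted((it.factor_a, it.factor_b))
            out[f"{a}:{b}"] = it.coef
        return out


def _model_from_dict(d: dict) -> PublishedModel:
    return PublishedModel(
        response=d["response"],
        intercept=float(d["intercept"]),
        linear={k: float(v) for k, v in d.get("linear", {}).items()},
        quadratic=[QuadraticTerm(q["factor"], float(q["coef"]), float(q["center"]))
                   for q in d.get("quadratic", [])],
        interaction=[
            InteractionTerm(i["factor_a"], i["factor_b"], float(i["coef"]),
                            float(i["center_a"]), float(i["center_b"]))
            for i in d.get("interaction", [])
        ],
        factor_means={k: float(v) for k, v in d.get("factor_means", {}).items()},
        unit=d.get("unit", ""),
    )


def load_published_models(path=None) -> dict[str, PublishedModel]:
    """Load the packaged model registry (or a user-supplied JSON file)."""
    if path is None:
        text = resources.files("chlamydoe.data").joinpath("published_models.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {name: _model_from_dict(d) for name, d in raw["models"].items()}
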