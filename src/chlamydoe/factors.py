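"""Environmental factor specifications and candidate effect enumeration.

The study space is spanned by five culture-condition factors: light
irradiance, acetate, CO2 (a two-level ordinal factor: ambient air vs.
1.5 % enrichment), nitrate and ammonium.  Response-surface models may
contain each factor linearly, quadratically (continuous factors only)
and through pairwise interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "FactorSpec",
    "EffectTerm",
    "table1_factors",
    "enumerate_candidate_effects",
]


@dataclass(frozen=True)
class FactorSpec:
    """One environmental factor of the design space.

    Parameters
    ----------
    name : str
        Column name used in design tables (e.g. ``"acetate"``).
    kind : {"continuous", "ordinal"}
        Continuous factors take any value in ``[low, high]``; ordinal
        factors take exactly two numeric levels.
    unit : str
        Physical unit, for reporting only.
    low, high : float
        Working-range bounds (continuous factors).
    levels : tuple of float
        The two ordered numeric levels (ordinal factors).
    """

    name: str
    kind: str = "continuous"
    unit: str = ""
    low: float = 0.0
    high: float = 1.0
    levels: tuple[float, float] = field(default=())  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "continuous":
            if not self.low < self.high:
                raise ValueError(
                    f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
                )
        else:
            if len(self.levels) != 2:
                raise ValueError(
                    f"ordinal factor {self.name!r} must have exactly 2 levels"
                )
            if not self.levels[0] < self.levels[1]:
                raise ValueError(f"ordinal factor {self.name!r}: levels must increase")

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"

    @property
    def midpoint(self) -> float:
        """Centre of the working range (continuous factors only)."""
        if not self.is_continuous:
            raise ValueError(f"{self.name!r} is ordinal; no midpoint")
        return 0.5 * (self.low + self.high)

    @property
    def range_min(self) -> float:
        return self.low if self.is_continuous else self.levels[0]

    @property
    def range_max(self) -> float:
        return self.high if self.is_continuous else self.levels[1]

    def contains(self, value: float) -> bool:
        if self.is_continuous:
            return self.low <= value <= self.high
        return value in self.levels


def table1_factors() -> list[FactorSpec]:
    """The five default factors with their working ranges.

    Light 0–200 µmol photons m⁻² s⁻¹, acetate 0–1 g L⁻¹, CO2 ordinal
    {0.035 %, 1.5 %}, nitrate 0–20 mM, ammonium 0–15 mM.
    """
    return [
        FactorSpec("light", "continuous", "umol_photons.m-2.s-1", 0.0, 200.0),
        FactorSpec("acetate", "continuous", "g.L-1", 0.0, 1.0),
        FactorSpec("co2", "ordinal", "%", levels=(0.035, 1.5)),
        FactorSpec("nitrate", "continuous", "mM", 0.0, 20.0),
        FactorSpec("ammonium", "continuous", "mM", 0.0, 15.0),
    ]


@dataclass(frozen=True)
class EffectTerm:
    """A first- or second-order model effect.

    ``form`` is one of ``"linear"``, ``"quadratic"``, ``"interaction"``;
    ``factors`` holds one factor name (linear, quadratic) or two distinct
    names (interaction).
    """

    form: str
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic", "interaction"):
            raise ValueError(f"unknown effect form {self.form!r}")
        if self.form == "interaction":
            if len(self.factors) != 2 or self.factors[0] == self.factors[1]:
                raise ValueError("interaction needs 2 distinct factors")
        elif len(self.factors) != 1:
            raise ValueError(f"{self.form} effect needs exactly 1 factor")

    @property
    def order(self) -> int:
        return 1 if self.form == "linear" else 2

    @property
    def name(self) -> str:
        if self.form == "linear":
            return self.factors[0]
        if self.form == "quadratic":
            return f"{self.factors[0]}^2"
        return ":".join(self.factors)

    def parents(self) -> tuple["EffectTerm", ...]:
        """Linear effects implied by this term under effect heredity."""
        if self.form == "linear":
            return ()
        return tuple(EffectTerm("linear", (f,)) for f in self.factors)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def enumerate_candidate_effects(factors: Sequence[FactorSpec]) -> list[EffectTerm]:
    """All candidate effects for a response-surface model.

    Returns every linear term (input order), every quadratic of a
    continuous factor, and every unordered pairwise interaction in
    lexicographic order.  For the default five factors (four continuous
    plus the two-level CO2 factor) this yields 5 + 4 + 10 = 19 effects.
    """
    if not factors:
        raise ValueError("need at least one factor")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names")
    terms = [EffectTerm("linear", (f.name,)) for f in factors]
    terms += [EffectTerm("quadratic", (f.name,)) for f in factors if f.is_continuous]
    pairs = sorted(
        {tuple(sorted((a, b))) for i, a in enumerate(names) for b in names[i + 1 :]}
    )
    terms += [EffectTerm("interaction", p) for p in pairs]
    return terms


def factors_by_name(factors: Iterable[FactorSpec]) -> dict[str, FactorSpec]:
    return {f.name: f for f in factors}
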