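"""Experimental-design construction and effect-correlation diagnostics.

The default design mirrors the structure of the 42-run study layout:
a two-level (fractional) factorial backbone on the factor extremes,
replicated center points (all continuous factors at their range
midpoints, the ordinal CO2 factor alternating between its two levels),
and extra axial/edge points of the central-composite / Box-Behnken kind
chosen by a seeded search that minimizes the largest pairwise Pearson
correlation among the encoded effect columns.  Correlations between a
continuous factor and its own CO2 interaction are structural (about
0.7 for a balanced indicator) and are excluded from the search score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import EffectTerm, FactorSpec, enumerate_candidate_effects
from .regression import build_model_matrix_noconst, compute_centers

__all__ = [
    "DesignTable",
    "EffectCorrelations",
    "build_design",
    "effect_correlations",
    "read_design",
    "write_design",
]


@dataclass
class DesignTable:
    """A runs-by-factors table with replicate-group labels.

    ``frame`` holds ``run_id``, one numeric column per factor,
    ``replicate_group`` (runs with identical factor values share a
    label) and ``is_center``.
    """

    frame: pd.DataFrame
    factors: list[FactorSpec]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        missing = [c for c in ["run_id", *names] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design frame lacks columns {missing}")
        if "replicate_group" not in self.frame.columns:
            self.frame = self.frame.assign(replicate_group=_replicate_labels(self.frame, names))
        if "is_center" not in self.frame.columns:
            self.frame = self.frame.assign(is_center=_center_mask(self.frame, self.factors))
        for f in self.factors:
            bad = ~self.frame[f.name].map(f.contains)
            if bad.any():
                raise ValueError(f"factor {f.name!r} has out-of-range values")

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def n_center(self) -> int:
        return int(self.frame["is_center"].sum())

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def factor_data(self) -> pd.DataFrame:
        return self.frame[self.factor_names]


def _replicate_labels(frame: pd.DataFrame, names: list[str]) -> np.ndarray:
    key = frame[names].apply(tuple, axis=1)
    labels: dict[tuple, int] = {}
    out = np.empty(len(frame), dtype=int)
    for i, k in enumerate(key):
        out[i] = labels.setdefault(k, len(labels))
    return out


def _center_mask(frame: pd.DataFrame, factors: list[FactorSpec]) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for f in factors:
        if f.is_continuous:
            mask &= np.isclose(frame[f.name].to_numpy(float), f.midpoint)
    return mask


def _fraction_signs(n_factors: int, size: int) -> np.ndarray:
    """A regular two-level fraction of the requested power-of-two size.

    Halving is by successive defining relations: keep rows whose sign
    product over a shrinking suffix of columns is +1.
    """
    signs = np.array(list(itertools.product((-1, 1), repeat=n_factors)), dtype=int)
    subset = n_factors
    while len(signs) > size:
        keep = signs[:, :subset].prod(axis=1) == 1
        signs = signs[keep]
        subset -= 1
        if subset < 2:
            raise ValueError("cannot fraction the factorial down to the requested size")
    return signs


def _signs_to_values(signs: np.ndarray, factors: list[FactorSpec]) -> pd.DataFrame:
    cols = {}
    for j, f in enumerate(factors):
        lo, hi = f.range_min, f.range_max
        cols[f.name] = np.where(signs[:, j] < 0, lo, hi).astype(float)
    return pd.DataFrame(cols)


def _center_rows(factors: list[FactorSpec], n_center: int) -> pd.DataFrame:
    rows = []
    for i in range(n_center):
        row = {}
        for f in factors:
            if f.is_continuous:
                row[f.name] = f.midpoint
            else:
                row[f.name] = f.levels[i % 2]
        rows.append(row)
    return pd.DataFrame(rows)


def _extra_candidate_pool(factors: list[FactorSpec]) -> pd.DataFrame:
    """Axial (face-centred) and edge (Box-Behnken style) candidate points."""
    cont = [f for f in factors if f.is_continuous]
    ords = [f for f in factors if not f.is_continuous]
    ord_levels = [f.levels for f in ords]
    rows = []

    def base() -> dict:
        return {f.name: f.midpoint for f in cont}

    for f in cont:  # axial: one factor at an extreme, the rest at centre
        for v in (f.low, f.high):
            for combo in itertools.product(*ord_levels) if ords else [()]:
                row = base()
                row[f.name] = v
                for of, lv in zip(ords, combo):
                    row[of.name] = lv
                rows.append(row)
    for fa, fb in itertools.combinations(cont, 2):  # edges: two at extremes
        for va in (fa.low, fa.high):
            for vb in (fb.low, fb.high):
                for combo in itertools.product(*ord_levels) if ords else [()]:
                    row = base()
                    row[fa.name] = va
                    row[fb.name] = vb
                    for of, lv in zip(ords, combo):
                        row[of.name] = lv
                    rows.append(row)
    return pd.DataFrame(rows)


def _correlation_score(
    data: pd.DataFrame,
    effects: list[EffectTerm],
    factors: list[FactorSpec],
    exclude: set[frozenset[str]],
) -> tuple[float, float]:
    """Two-tier design score: (max main-effect |r|, max other |r|).

    Main-effect orthogonality is the first-class objective (screening
    designs keep it near zero); correlations among second-order columns
    are the tie-breaker.  Structural ordinal-interaction pairs are
    excluded.  Compared lexicographically; lower is better.
    """
    centers = compute_centers(data, factors)
    X, names, _ = build_model_matrix_noconst(data, effects, factors, centers)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        return (np.inf, np.inf)
    r = np.corrcoef(X, rowvar=False)
    main = {t.name for t in effects if t.form == "linear"}
    worst_main = 0.0
    worst_other = 0.0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if frozenset((names[i], names[j])) in exclude:
                continue
            v = abs(r[i, j])
            if names[i] in main and names[j] in main:
                worst_main = max(worst_main, v)
            else:
                worst_other = max(worst_other, v)
    return (round(worst_main, 3), worst_other)


def _structural_pairs(effects: list[EffectTerm], factors: list[FactorSpec]) -> set[frozenset[str]]:
    """Pairs whose correlation is an encoding artifact, not a design flaw.

    The interaction of a continuous factor with the two-level ordinal
    factor is ``indicator*(x - c)``, which necessarily correlates with
    ``x`` itself (about 0.71 for a balanced indicator).
    """
    ordinal = {f.name for f in factors if not f.is_continuous}
    out: set[frozenset[str]] = set()
    for t in effects:
        if t.form == "interaction" and (set(t.factors) & ordinal):
            cont = [f for f in t.factors if f not in ordinal]
            if cont:
                out.add(frozenset((t.name, cont[0])))
    return out


def build_design(
    factors: list[FactorSpec],
    n_runs: int = 42,
    n_center: int = 7,
    extra_points: int | None = None,
    seed: int = 0,
    n_search: int = 150,
) -> DesignTable:
    """Generate a factorial-backbone design with centers and extra points.

    Parameters
    ----------
    n_runs, n_center : int
        Total runs and number of replicated center points (defaults 42/7).
    extra_points : int, optional
        Number of axial/edge augmentation points; by default whatever is
        left after the largest regular factorial backbone that still
        leaves room for one axial pair per continuous factor.
    seed : int
        Seed for the augmentation-point search; identical seeds give
        identical tables.
    n_search : int
        Number of random candidate subsets scored during augmentation.
    """
    effects = enumerate_candidate_effects(factors)
    min_runs = len(effects) + 1 + n_center
    if n_runs < min_runs:
        raise ValueError(
            f"n_runs={n_runs} too small for {len(effects)} candidate effects; "
            f"minimum is {min_runs}"
        )
    n_cont = sum(f.is_continuous for f in factors)
    avail = n_runs - n_center
    full = 2 ** len(factors)

    if extra_points is None:
        if avail == full or avail >= full + 2 * n_cont:
            backbone_size = min(full, avail)
        else:
            backbone_size = full
            while backbone_size > avail - 2 * n_cont and backbone_size > 4:
                backbone_size //= 2
        n_extra = avail - backbone_size
    else:
        n_extra = extra_points
        backbone_size = avail - n_extra
        if backbone_size < 4 or backbone_size & (backbone_size - 1):
            raise ValueError(
                f"n_runs - n_center - extra_points = {backbone_size} is not a "
                "power-of-two factorial backbone size"
            )

    backbone = _signs_to_values(_fraction_signs(len(factors), backbone_size), factors)
    centers = _center_rows(factors, n_center)

    if n_extra > 0:
        pool = _extra_candidate_pool(factors)
        # drop pool rows already present in the backbone
        key = backbone.apply(tuple, axis=1)
        pool = pool[~pool[backbone.columns].apply(tuple, axis=1).isin(set(key))]
        pool = pool.reset_index(drop=True)
        if len(pool) < n_extra:
            raise ValueError(
                f"candidate pool ({len(pool)} points) smaller than requested "
                f"extra_points={n_extra}"
            )
        exclude = _structural_pairs(effects, factors)
        rng = np.random.default_rng(seed)
        best_score, best_idx = (np.inf, np.inf), None
        for _ in range(n_search):
            idx = rng.choice(len(pool), size=n_extra, replace=False)
            cand = pd.concat(
                [backbone, pool.iloc[np.sort(idx)], centers], ignore_index=True
            )
            score = _correlation_score(cand, effects, factors, exclude)
            if score < best_score:
                best_score, best_idx = score, np.sort(idx)
        extras = pool.iloc[best_idx].reset_index(drop=True)
        frame = pd.concat([backbone, extras, centers], ignore_index=True)
    else:
        frame = pd.concat([backbone, centers], ignore_index=True)

    frame.insert(0, "run_id", np.arange(1, len(frame) + 1))
    return DesignTable(frame, list(factors))


@dataclass
class EffectCorrelations:
    """Pairwise Pearson correlations between encoded effect columns."""

    table: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    undefined: list[str] = field(default_factory=list)
    threshold: float = 0.50

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"flagged pairs (|r| > {self.threshold}):"]
        for a, b, r in self.flagged:
            lines.append(f"  {a:<22} {b:<22} {r: .4f}")
        return "\n".join(lines)


def effect_correlations(
    design: DesignTable,
    effects: list[EffectTerm] | None = None,
    threshold: float = 0.50,
) -> EffectCorrelations:
    """Correlations between every pair of encoded effect columns.

    Constant columns are reported as ``undefined`` and their rows and
    columns left blank (NaN) rather than propagated.
    """
    if effects is None:
        effects = enumerate_candidate_effects(design.factors)
    data = design.factor_data()
    centers = compute_centers(data, design.factors)
    X, names, _ = build_model_matrix_noconst(data, effects, design.factors, centers)
    sd = X.std(axis=0)
    undefined = [names[j] for j in range(len(names)) if sd[j] == 0]
    r = np.full((len(names), len(names)), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        r[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isfinite(r[i, j]) and abs(r[i, j]) > threshold:
                flagged.append((names[i], names[j], float(r[i, j])))
    flagged.sort(key=lambda t: -abs(t[2]))
    table = pd.DataFrame(r, index=names, columns=names)
    return EffectCorrelations(table, flagged, undefined, threshold)


def write_design(design: DesignTable, path) -> None:
    """Write as CSV with ``run_id`` and one column per factor."""
    design.frame[["run_id", *design.factor_names]].to_csv(path, index=False)


def read_design(path, factors: list[FactorSpec]) -> DesignTable:
    """Read a design CSV; replicate groups and center flags are recomputed."""
    frame = pd.read_csv(path)
    return DesignTable(frame, list(factors))
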