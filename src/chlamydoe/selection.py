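"""Two-round effect selection for response-surface models.

Round 1 is a forward stepwise search minimizing the small-sample AICc
with an effect-heredity ("combine") rule: adding a quadratic or
interaction implicitly brings any absent parent linear terms, and the
AICc of the combined addition is what competes.  Round 2 prunes the
round-1 model by repeatedly removing the effect with the highest
individual-ANOVA p-value until a removal would make the lack-of-fit
test significant (p <= alpha) or drop R2 below a floor (0.60 by
default; for responses whose round-1 R2 is already below the floor, the
round-1 R2 minus a small slack).  Parents of retained second-order
terms are re-added at the end so the final model honours heredity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable
from .factors import EffectTerm, FactorSpec, enumerate_candidate_effects
from .regression import (
    ModelSpec,
    ResponseSurfaceModel,
    ResponseSurfaceResults,
    aicc_from_sse,
    build_model_matrix_noconst,
    compute_centers,
)

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "SelectionConfig",
    "stepwise_forward",
    "backward_prune",
    "run_two_round",
]


@dataclass
class SelectionStep:
    action: str  # "add" | "remove" | "stop"
    term: str | None
    aicc: float
    r2: float
    lack_of_fit_p: float | None
    reason: str = ""


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_spec: ModelSpec
    round: int


@dataclass
class SelectionConfig:
    """Tuning knobs of the two-round procedure."""

    alpha: float = 0.05
    r2_floor: float = 0.60
    slack: float = 0.05
    min_rows: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


class _Workspace:
    """Pre-encoded effect columns and fast SSE evaluations for one response."""

    def __init__(
        self,
        y: np.ndarray,
        data: pd.DataFrame,
        terms: Sequence[EffectTerm],
        factors: Sequence[FactorSpec],
    ):
        self.y = np.asarray(y, dtype=float)
        self.data = data.reset_index(drop=True)
        self.factors = list(factors)
        self.centers = compute_centers(self.data, factors)
        self.terms = list(terms)
        X, names, _ = build_model_matrix_noconst(self.data, self.terms, factors, self.centers)
        self.X = X
        self.names = names
        self.index = {t.name: j for j, t in enumerate(self.terms)}
        self.n = len(self.y)
        self.sst = float(((self.y - self.y.mean()) ** 2).sum())
        # replicate-group pure error is model independent
        groups = self.data.groupby(list(self.data.columns), sort=False).indices
        self.n_groups = len(groups)
        ss_pure = 0.0
        for idx in groups.values():
            yi = self.y[list(idx)]
            ss_pure += float(((yi - yi.mean()) ** 2).sum())
        self.ss_pure = ss_pure
        self.df_pure = self.n - self.n_groups

    def sse(self, idx: Sequence[int]) -> float | None:
        """Residual SS of the model with the given columns; None if singular."""
        k = len(idx)
        if self.n <= k + 1:
            return None
        X1 = np.column_stack([np.ones(self.n), self.X[:, list(idx)]])
        beta, _, rank, _ = np.linalg.lstsq(X1, self.y, rcond=None)
        if rank < X1.shape[1]:
            return None
        resid = self.y - X1 @ beta
        return float(resid @ resid)

    def r2(self, sse: float) -> float:
        return 1.0 - sse / self.sst if self.sst > 0 else float("nan")

    def lof_p(self, sse: float, k: int) -> float | None:
        df_lof = self.n_groups - 1 - k
        if self.df_pure <= 0 or df_lof <= 0 or self.ss_pure <= 0:
            return None
        ss_lof = max(sse - self.ss_pure, 0.0)
        f = (ss_lof / df_lof) / (self.ss_pure / self.df_pure)
        return float(stats.f.sf(f, df_lof, self.df_pure))

    def effect_pvalues(self, idx: list[int]) -> np.ndarray:
        """Deprivation-ANOVA p for every column of the model with columns idx."""
        sse_full = self.sse(idx)
        k = len(idx)
        df_err = self.n - k - 1
        out = np.full(k, np.nan)
        if sse_full is None or df_err <= 0:
            return out
        ms_err = sse_full / df_err
        for j in range(k):
            sse_r = self.sse(idx[:j] + idx[j + 1 :])
            if sse_r is None:
                continue
            f = max(sse_r - sse_full, 0.0) / ms_err if ms_err > 0 else np.inf
            out[j] = float(stats.f.sf(f, 1, df_err))
        return out


def _closure(term: EffectTerm, have: set[str]) -> list[EffectTerm]:
    """The term plus any absent linear parents (heredity / combine rule)."""
    add = [term]
    for parent in term.parents():
        if parent.name not in have and parent.name not in {t.name for t in add}:
            add.append(parent)
    return add


def _align(design: DesignTable, y) -> tuple[np.ndarray, pd.DataFrame]:
    yv = np.asarray(y, dtype=float)
    if len(yv) != design.n_runs:
        raise ValueError("y must align with the design rows")
    keep = ~np.isnan(yv)
    return yv[keep], design.factor_data().loc[keep].reset_index(drop=True)


def stepwise_forward(
    design: DesignTable,
    y,
    candidates: Sequence[EffectTerm] | None = None,
    config: SelectionConfig | None = None,
    response: str = "y",
) -> SelectionTrace:
    """Round 1: greedy forward AICc selection with effect heredity.

    Missing values in ``y`` are dropped (the centering constants are
    therefore those of the surviving rows).  Stops when no addition
    lowers the AICc; ties prefer the lower-order term, then enumeration
    order.
    """
    if candidates is None:
        candidates = enumerate_candidate_effects(design.factors)
    if not candidates:
        raise ValueError("no candidate effects")
    config = config or SelectionConfig()
    yv, data = _align(design, y)

    # workspace over candidates plus every possible linear parent
    all_terms = list(candidates)
    names = {t.name for t in all_terms}
    for t in candidates:
        for p in t.parents():
            if p.name not in names:
                all_terms.append(p)
                names.add(p.name)
    ws = _Workspace(yv, data, all_terms, design.factors)

    selected: list[EffectTerm] = []
    sse0 = ws.sse([])
    current = aicc_from_sse(sse0, ws.n, 0) if sse0 is not None else math.inf
    steps: list[SelectionStep] = []
    any_fit_possible = False
    while True:
        best: tuple[float, int, int] | None = None  # (aicc, order, enum index)
        best_add: list[EffectTerm] | None = None
        have = {t.name for t in selected}
        for i, cand in enumerate(candidates):
            if cand.name in have:
                continue
            addition = _closure(cand, have)
            idx = [ws.index[t.name] for t in selected + addition]
            sse = ws.sse(idx)
            if sse is None:
                continue
            any_fit_possible = True
            a = aicc_from_sse(sse, ws.n, len(idx))
            key = (a, cand.order, i)
            if best is None or key < best:
                best, best_add = key, addition
        if best is None or best[0] >= current:
            break
        selected += best_add
        current = best[0]
        idx = [ws.index[t.name] for t in selected]
        sse = ws.sse(idx)
        extra = [t.name for t in best_add[1:]]
        steps.append(
            SelectionStep(
                "add",
                best_add[0].name,
                current,
                ws.r2(sse),
                ws.lof_p(sse, len(idx)),
                reason="with parents " + ", ".join(extra) if extra else "lowest AICc",
            )
        )
    if not selected and not any_fit_possible:
        warnings.warn("every single-effect fit was singular; returning empty model")
        steps.append(SelectionStep("stop", None, current, 0.0, None, "all additions singular"))
    else:
        idx = [ws.index[t.name] for t in selected]
        sse = ws.sse(idx)
        steps.append(
            SelectionStep("stop", None, current,
                          ws.r2(sse) if sse is not None else float("nan"),
                          ws.lof_p(sse, len(idx)) if sse is not None else None,
                          "no addition lowers AICc")
        )
    spec = ModelSpec(response, selected, dict(ws.centers))
    return SelectionTrace(steps, spec, round=1)


def backward_prune(
    design: DesignTable,
    y,
    round1_spec: ModelSpec,
    r2_floor_default: float = 0.60,
    config: SelectionConfig | None = None,
) -> SelectionTrace:
    """Round 2: p-ordered pruning with the lack-of-fit / R2 stopping rule.

    The highest-p effect is tentatively removed; the removal is rejected
    (and pruning stops) if the reduced fit shows significant lack of fit
    or an R2 below the floor.  The floor is ``r2_floor_default`` unless
    the round-1 R2 is already lower, in which case it is the round-1 R2
    minus the configured slack.  When lack of fit is unavailable only
    the R2 criterion applies.
    """
    config = config or SelectionConfig(r2_floor=r2_floor_default)
    yv, data = _align(design, y)
    terms = list(round1_spec.terms)
    ws = _Workspace(yv, data, terms, design.factors)

    idx = [ws.index[t.name] for t in terms]
    sse1 = ws.sse(idx)
    if sse1 is None:
        raise ValueError("round-1 model does not fit (singular)")
    r2_1 = ws.r2(sse1)
    floor = r2_floor_default if r2_1 >= r2_floor_default else r2_1 - config.slack

    steps: list[SelectionStep] = []
    current = list(terms)
    while current:
        idx = [ws.index[t.name] for t in current]
        pvals = ws.effect_pvalues(idx)
        if np.isnan(pvals).all():
            steps.append(SelectionStep("stop", None, math.nan, ws.r2(ws.sse(idx)),
                                       None, "effect p-values unavailable"))
            break
        # highest p first; ties remove the higher-order term first
        order = sorted(
            range(len(current)),
            key=lambda j: (-(pvals[j] if np.isfinite(pvals[j]) else -1.0),
                           -current[j].order),
        )
        j = order[0]
        trial = current[:j] + current[j + 1 :]
        t_idx = [ws.index[t.name] for t in trial]
        sse_t = ws.sse(t_idx)
        if sse_t is None:
            steps.append(SelectionStep("stop", current[j].name, math.nan,
                                       ws.r2(ws.sse(idx)), None, "removal fit singular"))
            break
        r2_t = ws.r2(sse_t)
        lof_t = ws.lof_p(sse_t, len(t_idx))
        bad_lof = lof_t is not None and lof_t <= config.alpha
        if bad_lof or r2_t < floor:
            reason = []
            if bad_lof:
                reason.append(f"lack-of-fit p = {lof_t:.4f} <= {config.alpha}")
            if r2_t < floor:
                reason.append(f"R2 = {r2_t:.3f} < floor {floor:.3f}")
            steps.append(SelectionStep("stop", current[j].name,
                                       aicc_from_sse(ws.sse(idx), ws.n, len(idx)),
                                       ws.r2(ws.sse(idx)),
                                       ws.lof_p(ws.sse(idx), len(idx)),
                                       "removal rejected: " + " and ".join(reason)))
            break
        removed = current[j]
        current = trial
        steps.append(SelectionStep(
            "remove", removed.name,
            aicc_from_sse(sse_t, ws.n, len(t_idx)), r2_t, lof_t,
            f"highest p ({pvals[j]:.4f}) removed"))

    # heredity repair: parents of retained second-order terms
    have = {t.name for t in current}
    for t in list(current):
        for parent in t.parents():
            if parent.name not in have:
                current.append(parent)
                have.add(parent.name)
                idx = [ws.index.get(p.name) for p in current]
                if None in idx:
                    # parent column not encoded in workspace; extend lazily
                    ws2 = _Workspace(yv, data, current, design.factors)
                    sse_h = ws2.sse(list(range(len(current))))
                    kh = len(current)
                else:
                    sse_h = ws.sse(idx)
                    kh = len(idx)
                steps.append(SelectionStep(
                    "add", parent.name,
                    aicc_from_sse(sse_h, ws.n, kh) if sse_h is not None else math.nan,
                    ws.r2(sse_h) if sse_h is not None else math.nan,
                    ws.lof_p(sse_h, kh) if sse_h is not None else None,
                    f"heredity repair for {t.name}"))
    spec = ModelSpec(round1_spec.response, current, dict(ws.centers))
    return SelectionTrace(steps, spec, round=2)


@dataclass
class ResponseSelection:
    """Per-response outcome of the two-round procedure."""

    response: str
    round1: ResponseSurfaceResults | None
    round2: ResponseSurfaceResults | None
    trace1: SelectionTrace | None
    trace2: SelectionTrace | None
    factors_retained: list[str] = field(default_factory=list)
    skipped: str = ""


def run_two_round(
    design: DesignTable,
    responses: pd.DataFrame,
    config: SelectionConfig | None = None,
    candidates: Sequence[EffectTerm] | None = None,
) -> dict[str, ResponseSelection]:
    """Run both selection rounds for every response column.

    Missing rows are dropped per response (centering recomputed), then
    round 1 (forward AICc) and round 2 (p-ordered pruning) are applied.
    Returns a mapping response -> :class:`ResponseSelection` with fitted
    results, traces and the distinct environmental factors retained.
    """
    config = config or SelectionConfig()
    response_cols = [c for c in responses.columns if c != "run_id"]
    if not response_cols:
        raise ValueError("response table has no response columns")
    merged = design.frame[["run_id"]].merge(responses, on="run_id", how="left")
    out: dict[str, ResponseSelection] = {}
    for name in response_cols:
        yv = merged[name].to_numpy(float)
        n_obs = int(np.isfinite(yv).sum())
        if n_obs < config.min_rows:
            warnings.warn(f"{name}: only {n_obs} rows; skipped")
            out[name] = ResponseSelection(name, None, None, None, None,
                                          skipped=f"only {n_obs} rows")
            continue
        finite = yv[np.isfinite(yv)]
        if np.ptp(finite) == 0.0:
            warnings.warn(f"{name}: constant response; empty model")
            empty = SelectionTrace(
                [SelectionStep("stop", None, math.nan, 0.0, None, "constant response")],
                ModelSpec(name, [], {}), round=1)
            out[name] = ResponseSelection(name, None, None, empty, None,
                                          skipped="constant response")
            continue
        t1 = stepwise_forward(design, yv, candidates, config, response=name)
        t2 = backward_prune(design, yv, t1.final_spec, config.r2_floor, config)
        keep = ~np.isnan(yv)
        data = design.factor_data().loc[keep].reset_index(drop=True)
        res1 = _fit_spec(yv[keep], data, t1.final_spec, design.factors) if t1.final_spec.terms else None
        res2 = _fit_spec(yv[keep], data, t2.final_spec, design.factors) if t2.final_spec.terms else None
        out[name] = ResponseSelection(
            name, res1, res2, t1, t2,
            factors_retained=t2.final_spec.factor_names,
        )
    return out


def _fit_spec(y, data, spec: ModelSpec, factors) -> ResponseSurfaceResults:
    model = ResponseSurfaceModel(y, data, spec.terms, factors, response=spec.response)
    return model.fit()
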