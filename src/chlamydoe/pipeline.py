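"""End-to-end orchestration: design -> responses -> selection -> validation.

A :class:`PipelineConfig` (validated, JSON round-trippable) drives the
whole study replica; all randomness flows from a single top-level seed
expanded per stage (design construction, response noise, fold
assignment) so any stage can be re-run reproducibly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .design import build_design, effect_correlations, read_design
from .factors import FactorSpec, table1_factors
from .published import load_published_models
from .regression import _fmt_p
from .selection import SelectionConfig, run_two_round
from .simulate import (
    DEFAULT_MISSING_RUNS,
    DEFAULT_SIGMA,
    NoiseModel,
    generate_responses,
    read_responses,
)
from .validation import experimental_validation, kfold_cv, load_validation_points

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


class PipelineConfig(BaseModel):
    """Configuration of the full pipeline (defaults mirror the study)."""

    n_runs: int = 42
    n_center: int = 7
    seed: int = 0
    sigma: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_SIGMA))
    missing_runs: dict[str, list[int]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MISSING_RUNS.items()}
    )
    alpha: float = 0.05
    r2_floor: float = 0.60
    slack: float = 0.05
    cv_k: int = 5
    experimental_validation: bool = True
    design_path: str | None = None
    responses_path: str | None = None

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        return v

    @field_validator("sigma")
    @classmethod
    def _sigma_nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: s for k, s in v.items() if s < 0}
        if bad:
            raise ValueError(f"negative sigma: {bad}")
        return v

    @field_validator("cv_k")
    @classmethod
    def _k_min(cls, v: int) -> int:
        if v < 2:
            raise ValueError("cv_k must be >= 2")
        return v


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(3)
    names = ("design", "noise", "folds")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def run_pipeline(config: PipelineConfig, factors: list[FactorSpec] | None = None) -> dict:
    """Run the study replica and return the report bundle (JSON-able dict).

    Stages: design (generated or loaded) -> responses (simulated from
    the published models or loaded) -> effect-correlation diagnostics ->
    two-round selection per response -> vertex table of the final
    models -> k-fold cross-validation of the final specs -> optional
    experimental validation of the published models against the packaged
    measured combinations.
    """
    factors = factors or table1_factors()
    seeds = _stage_seeds(config.seed)

    if config.design_path:
        design = read_design(config.design_path, factors)
    else:
        design = build_design(factors, config.n_runs, config.n_center, seed=seeds["design"])

    models = load_published_models()
    if config.responses_path:
        responses = read_responses(config.responses_path)
    else:
        noise = NoiseModel(sigma=dict(config.sigma), seed=seeds["noise"],
                           missing_runs={k: list(v) for k, v in config.missing_runs.items()})
        responses = generate_responses(design, models, noise)

    corr = effect_correlations(design)
    sel_config = SelectionConfig(alpha=config.alpha, r2_floor=config.r2_floor,
                                 slack=config.slack)
    selection = run_two_round(design, responses, sel_config)

    vertex_table: dict[str, dict] = {}
    cv: dict[str, Any] = {}
    for name, sel in selection.items():
        if sel.round2 is None:
            continue
        vx = sel.round2.vertices()
        if vx:
            vertex_table[name] = vx
        rep = kfold_cv(design, responses[name].to_numpy(float),
                       sel.round2.model.spec, k=config.cv_k, seed=seeds["folds"])
        cv[name] = rep.to_dict()

    ev: dict[str, Any] = {}
    if config.experimental_validation:
        points = load_validation_points()
        for name, model in models.items():
            if name in points.columns:
                ev[name] = experimental_validation(model, points).to_dict()

    bundle = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stage_seeds": seeds,
        "design": {
            "n_runs": design.n_runs,
            "n_center": design.n_center,
            "correlation_flags": [
                {"a": a, "b": b, "r": r} for a, b, r in corr.flagged
            ],
        },
        "selection": {
            name: {
                "skipped": sel.skipped,
                "factors_retained": sel.factors_retained,
                "round1": None if sel.round1 is None else sel.round1.to_dict(),
                "round2": None if sel.round2 is None else sel.round2.to_dict(),
                "trace1": None if sel.trace1 is None else _trace_dict(sel.trace1),
                "trace2": None if sel.trace2 is None else _trace_dict(sel.trace2),
            }
            for name, sel in selection.items()
        },
        "vertices": vertex_table,
        "cross_validation": cv,
        "experimental_validation": ev,
    }
    return bundle


def _trace_dict(trace) -> dict:
    return {
        "round": trace.round,
        "final_terms": trace.final_spec.term_names,
        "steps": [
            {
                "action": s.action, "term": s.term, "aicc": s.aicc,
                "r2": s.r2, "lack_of_fit_p": s.lack_of_fit_p, "reason": s.reason,
            }
            for s in trace.steps
        ],
    }


def _sig3(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "-"
    return f"{v:.3g}"


def render_report(bundle: dict) -> str:
    """Render the bundle as Markdown (effects by ascending p, stars at 0.05)."""
    lines = ["# Bioenergetic response-surface report", ""]
    lines += [f"Runs: {bundle['design']['n_runs']}  "
              f"center points: {bundle['design']['n_center']}", ""]
    flags = bundle["design"]["correlation_flags"]
    if flags:
        lines += ["## Correlated effects", "", "| effect A | effect B | r |", "|---|---|---|"]
        lines += [f"| {f['a']} | {f['b']} | {f['r']:.4f} |" for f in flags]
        lines.append("")
    lines.append("## Final models (round 2)")
    for name, sel in bundle["selection"].items():
        lines += ["", f"### {name}"]
        if sel["skipped"]:
            lines.append(f"skipped: {sel['skipped']}")
            continue
        r2 = sel["round2"]
        if r2 is None or not r2["effects"]:
            lines.append("no effects retained")
            continue
        lof = r2["lack_of_fit"]
        lof_txt = _fmt_p(lof["p"]) if lof["available"] else f"unavailable ({lof['reason']})"
        lines += [
            f"R2 = {r2['r2']:.2f}, R2adj = {r2['r2_adj']:.2f}, "
            f"RMSE_F = {_sig3(r2['rmse_f'])} ({r2['rmse_pct_scale']:.0f}% of average scale), "
            f"AICc = {r2['aicc']:.2f}",
            f"whole-model p = {_fmt_p(r2['whole_model']['p'])}, lack-of-fit p = {lof_txt}",
            "",
            "| effect | coef | beta | p |",
            "|---|---|---|---|",
        ]
        effects = sorted(r2["effects"].items(), key=lambda kv: kv[1]["p"])
        for ename, e in effects:
            star = "*" if e["p"] <= 0.05 else ""
            lines.append(
                f"| {ename} | {_sig3(e['coef'])} | {e['beta']:.3f} | {_fmt_p(e['p'])}{star} |"
            )
    if bundle["vertices"]:
        lines += ["", "## Quadratic optima", "",
                  "| response | factor | location | value | curvature |",
                  "|---|---|---|---|---|"]
        for resp, per in bundle["vertices"].items():
            for fac, v in per.items():
                lines.append(
                    f"| {resp} | {fac} | {_sig3(v['location'])} | "
                    f"{_sig3(v['value'])} | {v['curvature']} |"
                )
    if bundle["cross_validation"]:
        lines += ["", "## Cross-validation", "",
                  "| response | k | MAE_CV | RMSE_CV |", "|---|---|---|---|"]
        for resp, r in bundle["cross_validation"].items():
            lines.append(f"| {resp} | {r['k']} | {_sig3(r['mae_fold_avg'])} | "
                         f"{_sig3(r['rmse_fold_avg'])} |")
    if bundle["experimental_validation"]:
        lines += ["", "## Experimental validation", "",
                  "| response | n | MAE_EV | RMSE_EV |", "|---|---|---|---|"]
        for resp, r in bundle["experimental_validation"].items():
            lines.append(f"| {resp} | {r['n_points']} | {_sig3(r['mae'])} | "
                         f"{_sig3(r['rmse'])} |")
    lines.append("")
    return "\n".join(lines)


def write_bundle(bundle: dict, out_dir) -> None:
    """Write report.json and report.md into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    (out / "report.md").write_text(render_report(bundle))
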