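"""Synthetic response generation from ground-truth models plus noise.

Stands in for the study's raw measurement spreadsheet: responses are
drawn from the published (or user-supplied) response models with
additive homoscedastic Gaussian noise at each response's fitted RMSE,
the two fluorescence indices truncated at zero, and the observed
missing-value pattern reproduced (dark respiration absent for two runs,
the cytochromial maximal activity for one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable
from .factors import FactorSpec
from .published import PublishedModel, load_published_models

__all__ = [
    "NoiseModel",
    "DEFAULT_SIGMA",
    "DEFAULT_MISSING_RUNS",
    "DEFAULT_REPLICATE_RSD",
    "NONNEGATIVE_RESPONSES",
    "generate_responses",
    "generate_validation_set",
    "read_responses",
    "write_responses",
]

#: Fitted root-mean-square error of each second-round model (response units).
DEFAULT_SIGMA: dict[str, float] = {
    "CR": 2.9,
    "MA_CYT": 3.5,
    "MA_ALT": 3.0,
    "PHIPSII800": 0.068,
    "NPQ800": 0.084,
    "P800": 19.6,
}

#: Runs for which a response could not be measured in the study.
DEFAULT_MISSING_RUNS: dict[str, list[int]] = {"CR": [14, 28], "MA_CYT": [26]}

#: Average relative SD of experimental replicates per response.
DEFAULT_REPLICATE_RSD: dict[str, float] = {
    "CR": 0.09,
    "MA_CYT": 0.09,
    "MA_ALT": 0.09,
    "PHIPSII800": 0.09,
    "NPQ800": 0.197,
    "P800": 0.09,
}

#: Fluorescence indices that cannot be negative; generated values are clipped.
NONNEGATIVE_RESPONSES = ("PHIPSII800", "NPQ800")


@dataclass
class NoiseModel:
    """Per-response Gaussian noise scales, seed, and missing-run pattern."""

    sigma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    seed: int = 0
    missing_runs: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MISSING_RUNS.items()}
    )

    def __post_init__(self) -> None:
        for name, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma for {name!r} must be >= 0")


def _check_model_factors(model: PublishedModel, design: DesignTable) -> None:
    unknown = [f for f in model.factor_names if f not in design.factor_names]
    if unknown:
        raise KeyError(
            f"model {model.response!r} references unknown factors {unknown}"
        )


def generate_responses(
    design: DesignTable,
    models: Mapping[str, PublishedModel] | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Simulate a response table on a design.

    ``y = model(x) + N(0, sigma^2)`` independently per run; runs listed
    in the noise model's missing pattern are blanked; reproducible for a
    fixed seed.  Returns a frame keyed by ``run_id`` with one column per
    response (NaN = missing).
    """
    if models is None:
        models = load_published_models()
    if noise is None:
        noise = NoiseModel()
    for m in models.values():
        _check_model_factors(m, design)
    for name, runs in noise.missing_runs.items():
        bad = set(runs) - set(design.frame["run_id"])
        if name in models and bad:
            raise ValueError(f"missing_runs for {name!r} not in design: {sorted(bad)}")

    rng = np.random.default_rng(noise.seed)
    data = design.factor_data()
    out = pd.DataFrame({"run_id": design.frame["run_id"].to_numpy()})
    for name in sorted(models):
        model = models[name]
        mu = np.asarray(model.predict({f: data[f].to_numpy(float) for f in model.factor_names}))
        sigma = noise.sigma.get(name, 0.0)
        y = mu + rng.normal(0.0, sigma, size=len(mu)) if sigma > 0 else mu.copy()
        if name in NONNEGATIVE_RESPONSES:
            n_trunc = int((y < 0).sum())
            if n_trunc:
                warnings.warn(f"{name}: truncated {n_trunc} negative values at 0",
                              stacklevel=2)
                y = np.clip(y, 0.0, None)
        miss = noise.missing_runs.get(name, [])
        if miss:
            y = np.where(out["run_id"].isin(miss), np.nan, y)
        out[name] = y
    return out


def generate_validation_set(
    n_points: int,
    factors: Sequence[FactorSpec],
    models: Mapping[str, PublishedModel] | None = None,
    replicate_sd: Mapping[str, float] | float | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Random factor combinations with replicate mean +/- SD responses.

    Continuous factors are drawn uniformly over their working ranges;
    ordinal factors are pinned to their high level (all validation
    cultures used 1.5 % CO2).  Replicate noise is proportional:
    ``N(0, (rsd * |mu|)^2)`` around the model prediction ``mu``.
    """
    if n_points < 1 or n_replicates < 1:
        raise ValueError("n_points and n_replicates must be >= 1")
    if models is None:
        models = load_published_models()
    if replicate_sd is None:
        rsd_map: dict[str, float] = dict(DEFAULT_REPLICATE_RSD)
    elif isinstance(replicate_sd, Mapping):
        rsd_map = dict(replicate_sd)
    else:
        rsd_map = {name: float(replicate_sd) for name in models}

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for f in factors:
        if f.is_continuous:
            cols[f.name] = rng.uniform(f.low, f.high, size=n_points)
        else:
            cols[f.name] = np.full(n_points, f.levels[1])
    out = pd.DataFrame(cols)
    out.insert(0, "point", np.arange(1, n_points + 1))
    for name in sorted(models):
        model = models[name]
        mu = np.asarray(
            model.predict({f: out[f].to_numpy(float) for f in model.factor_names})
        )
        rsd = rsd_map.get(name, 0.0)
        reps = mu[:, None] + rng.normal(0.0, 1.0, size=(n_points, n_replicates)) * (
            rsd * np.abs(mu)[:, None]
        )
        if name in NONNEGATIVE_RESPONSES:
            reps = np.clip(reps, 0.0, None)
        out[name] = reps.mean(axis=1)
        out[f"{name}_sd"] = reps.std(axis=1, ddof=1) if n_replicates > 1 else 0.0
    return out


def write_responses(responses: pd.DataFrame, path) -> None:
    """Write a response table as CSV (blank = missing)."""
    responses.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    return pd.read_csv(path)
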