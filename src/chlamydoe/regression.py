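"""Response-surface least squares with full ANOVA diagnostics.

The model for one response is the second-order polynomial

    y = b0 + sum_i b_i x_i + sum_ii b_ii (x_i - c_i)^2
           + sum_ij b_ij (x_i - c_i)(x_j - c_j) + e

where second-order columns are centred at the arithmetic mean ``c`` of
each factor over the rows actually fitted (so responses with missing
runs get their own centering constants).  The two-level ordinal CO2
factor enters linearly as an indicator of its high level and interacts
with a continuous factor as ``indicator * (x - c_x)`` (an "extension"
term switched on at the high CO2 level).

Fitting is ordinary least squares; diagnostics follow the classical
response-surface toolkit: the SS decomposition SS_total = SS_model +
SS_error, whole-model and per-effect ANOVA F-tests (the effect SS being
the increase in error SS when the model is deprived of the effect),
a replicate-group lack-of-fit test splitting SS_error into pure error
and lack-of-fit, standardized beta-weights, the small-sample AICc, and
RMSE/MAE both in response units and as a percentage of the response's
average scale (mean minus minimum of the fitted values of y).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .factors import EffectTerm, FactorSpec, factors_by_name

__all__ = [
    "ModelSpec",
    "RankDeficientError",
    "LackOfFit",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "compute_centers",
    "encode_effect",
    "build_model_matrix",
    "aicc_from_sse",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when the model matrix is singular; names the aliased columns."""

    def __init__(self, aliased: Sequence[str]):
        self.aliased = list(aliased)
        super().__init__(f"model matrix is rank deficient; aliased columns: {self.aliased}")


@dataclass
class ModelSpec:
    """A response name, its effect terms and the realized centering constants."""

    response: str
    terms: list[EffectTerm]
    centering: dict[str, float] = field(default_factory=dict)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def factor_names(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for f in t.factors:
                if f not in seen:
                    seen.append(f)
        return seen


def compute_centers(data: pd.DataFrame, factors: Sequence[FactorSpec]) -> dict[str, float]:
    """Arithmetic mean of every continuous factor over the given rows."""
    return {f.name: float(data[f.name].mean()) for f in factors if f.is_continuous}


def encode_effect(
    term: EffectTerm,
    data: pd.DataFrame,
    centers: Mapping[str, float],
    factors: Mapping[str, FactorSpec],
) -> np.ndarray:
    """Encode one effect as a numeric column.

    Linear continuous terms enter uncentered; the ordinal factor's linear
    term is an indicator of its high level; all second-order columns use
    the supplied centering constants.
    """

    def col(name: str) -> np.ndarray:
        spec = factors[name]
        x = np.asarray(data[name], dtype=float)
        if spec.is_continuous:
            return x
        return (x == spec.levels[1]).astype(float)

    def centered(name: str) -> np.ndarray:
        return np.asarray(data[name], dtype=float) - centers[name]

    if term.form == "linear":
        return col(term.factors[0])
    if term.form == "quadratic":
        f = term.factors[0]
        if not factors[f].is_continuous:
            raise ValueError(f"quadratic term on ordinal factor {f!r}")
        return centered(f) ** 2
    a, b = term.factors
    fa, fb = factors[a], factors[b]
    if fa.is_continuous and fb.is_continuous:
        return centered(a) * centered(b)
    if not fa.is_continuous and not fb.is_continuous:
        raise ValueError("interaction of two ordinal factors is not supported")
    ordinal, cont = (a, b) if not fa.is_continuous else (b, a)
    return col(ordinal) * centered(cont)


def build_model_matrix(
    data: pd.DataFrame,
    terms: Sequence[EffectTerm],
    factors: Sequence[FactorSpec],
    centers: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Encode the effect columns for the given rows.

    Returns ``(X, names, centers)`` where ``X`` has one column per term
    (no intercept) and ``centers`` are the realized centering constants
    (recomputed from ``data`` when not supplied).
    """
    fmap = factors_by_name(factors)
    if centers is None:
        centers = compute_centers(data, factors)
    cols = [encode_effect(t, data, centers, fmap) for t in terms]
    names = [t.name for t in terms]
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    for j, name in enumerate(names):
        if X.shape[0] > 1 and np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"effect column {name!r} is constant on the fit rows")
    return X, names, dict(centers)


def aicc_from_sse(sse: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for a Gaussian OLS fit.

    ``k`` counts the effect columns; the parameter count used in the
    penalty is ``k + 2`` (intercept and error variance).  Returns +inf
    (with a warning) when the correction denominator is not positive.
    """
    kp = k + 2
    if n - kp - 1 <= 0:
        warnings.warn("AICc penalty denominator <= 0; returning +inf", stacklevel=2)
        return math.inf
    ll_term = n * math.log(2.0 * math.pi * sse / n) + n
    return ll_term + 2 * kp + 2 * kp * (kp + 1) / (n - kp - 1)


def _solve_ols(X1: np.ndarray, y: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Least squares with an explicit rank check (no silent pseudo-inverse)."""
    beta, _, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    if rank < X1.shape[1]:
        # identify aliased columns by pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X1, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        tol = d.max() * max(X1.shape) * np.finfo(float).eps if d.size else 0.0
        bad = [piv[i] for i in range(len(d)) if d[i] <= tol] + list(piv[len(d):])
        labels = ["intercept"] + list(names)
        raise RankDeficientError([labels[j] for j in sorted(bad)])
    return beta


@dataclass
class LackOfFit:
    """Replicate-group lack-of-fit decomposition of the error SS."""

    available: bool
    reason: str = ""
    ss_pure: float = float("nan")
    ss_lof: float = float("nan")
    df_pure: int = 0
    df_lof: int = 0
    fvalue: float = float("nan")
    pvalue: float = float("nan")


class ResponseSurfaceModel:
    """OLS response-surface model for one response on a set of design rows.

    Parameters
    ----------
    y : array-like
        Response values for the fit rows (no missing values).
    data : DataFrame
        Factor values for the same rows (one column per factor).
    terms : sequence of EffectTerm
        Effects to include (the intercept is implicit).
    factors : sequence of FactorSpec
        Factor definitions covering every factor used by ``terms``.
    response : str
        Response name, used in reports.
    """

    def __init__(
        self,
        y,
        data: pd.DataFrame,
        terms: Sequence[EffectTerm],
        factors: Sequence[FactorSpec],
        response: str = "y",
        centers: Mapping[str, float] | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != len(self.data):
            raise ValueError("y and data must have the same number of rows")
        if np.isnan(self.y).any():
            raise ValueError("y contains missing values; drop them before fitting")
        self.terms = list(terms)
        self.factors = list(factors)
        self.response = response
        X, names, centers = build_model_matrix(self.data, self.terms, self.factors, centers)
        self.exog = X
        self.exog_names = names
        self.centers = centers
        n, k = X.shape
        if n <= k + 1:
            raise ValueError(f"need n > k+1 rows to fit ({n} rows, {k} effects)")

    @classmethod
    def from_tables(
        cls,
        design,
        responses: pd.DataFrame,
        response: str,
        terms: Sequence[EffectTerm],
    ) -> "ResponseSurfaceModel":
        """Build from a :class:`~chlamydoe.design.DesignTable` and a response table.

        Rows where the response is missing are dropped, and the centering
        constants are therefore recomputed on the remaining rows.
        """
        merged = design.frame.merge(responses[["run_id", response]], on="run_id")
        keep = merged[response].notna()
        sub = merged.loc[keep]
        return cls(
            sub[response].to_numpy(float),
            sub[[f.name for f in design.factors]],
            terms,
            design.factors,
            response=response,
        )

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.response, list(self.terms), dict(self.centers))

    def fit(self) -> "ResponseSurfaceResults":
        return ResponseSurfaceResults(self)


class ResponseSurfaceResults:
    """Estimates and diagnostics of a fitted :class:`ResponseSurfaceModel`."""

    def __init__(self, model: ResponseSurfaceModel):
        self.model = model
        y = model.y
        X = model.exog
        n, k = X.shape
        X1 = np.column_stack([np.ones(n), X])
        beta = _solve_ols(X1, y, model.exog_names)
        self.nobs = n
        self.k_effects = k
        self.params = pd.Series(beta, index=["intercept"] + model.exog_names)
        self.fittedvalues = X1 @ beta
        self.resid = y - self.fittedvalues

        ybar = y.mean()
        self.ss_total = float(((y - ybar) ** 2).sum())
        self.ss_error = float((self.resid**2).sum())
        self.ss_model = float(((self.fittedvalues - ybar) ** 2).sum())
        self.df_total = n - 1
        self.df_model = k
        self.df_error = n - k - 1
        self.ms_error = self.ss_error / self.df_error
        self.ms_model = self.ss_model / self.df_model if k else 0.0
        ms_total = self.ss_total / self.df_total

        self.rsquared = self.ss_model / self.ss_total if self.ss_total > 0 else float("nan")
        self.rsquared_adj = 1.0 - self.ms_error / ms_total if ms_total > 0 else float("nan")
        self.rmse = math.sqrt(self.ms_error)
        self.mae = float(np.abs(self.resid).mean())
        self.average_scale = float(ybar - y.min())
        if self.average_scale > 0:
            self.rmse_pct_scale = 100.0 * self.rmse / self.average_scale
        else:
            self.rmse_pct_scale = float("nan")
        self.aicc = aicc_from_sse(self.ss_error, n, k)

        # whole-model ANOVA
        if k and self.ms_error > 0:
            self.fvalue = self.ms_model / self.ms_error
            self.f_pvalue = float(stats.f.sf(self.fvalue, k, self.df_error))
        else:
            self.fvalue = float("nan")
            self.f_pvalue = float("nan")

        self._X1 = X1
        self.effect_ss, self.effect_fvalues, self.effect_pvalues = self._effect_anova()
        self.beta_weights = self._beta_weights()
        self.lack_of_fit = self._lack_of_fit()

    # ---- diagnostics -------------------------------------------------

    def _effect_anova(self) -> tuple[pd.Series, pd.Series, pd.Series]:
        """Deprivation ANOVA: effect SS = SSE(without term) - SSE(full).

        Columns are held fixed (no recentering) and the full model's
        MS_error is the denominator, with 1 DF per effect.
        """
        names = self.model.exog_names
        ss = np.full(len(names), np.nan)
        y = self.model.y
        X1 = self._X1
        for j in range(len(names)):
            Xr = np.delete(X1, j + 1, axis=1)
            try:
                br = _solve_ols(Xr, y, [n for i, n in enumerate(names) if i != j])
            except RankDeficientError:
                continue
            sse_r = float(((y - Xr @ br) ** 2).sum())
            ss[j] = max(sse_r - self.ss_error, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = ss / self.ms_error if self.ms_error > 0 else np.full_like(ss, np.nan)
        p = np.array([float(stats.f.sf(v, 1, self.df_error)) if np.isfinite(v) else np.nan for v in f])
        idx = pd.Index(names)
        return pd.Series(ss, idx), pd.Series(f, idx), pd.Series(p, idx)

    def _beta_weights(self) -> pd.Series:
        """Coefficients after standardizing columns and y to mean 0, SD 1.

        The constructed second-order columns are standardized as columns
        (not rebuilt from standardized factors); sample SD (n-1).
        """
        X = self.model.exog
        y = self.model.y
        if X.shape[1] == 0:
            return pd.Series(dtype=float)
        sx = X.std(axis=0, ddof=1)
        sy = y.std(ddof=1)
        if np.any(sx == 0) or sy == 0:
            raise ValueError("cannot standardize a constant column")
        Z = (X - X.mean(axis=0)) / sx
        z = (y - y.mean()) / sy
        b, _, rank, _ = np.linalg.lstsq(Z, z, rcond=None)
        if rank < Z.shape[1]:
            raise RankDeficientError(self.model.exog_names)
        return pd.Series(b, index=self.model.exog_names)

    def _lack_of_fit(self) -> LackOfFit:
        """Pure error from replicate groups; SS_lof = SS_error - SS_pure."""
        data = self.model.data
        y = self.model.y
        key = list(data.columns)
        groups = data.groupby(key, sort=False).indices
        n_groups = len(groups)
        if n_groups == len(y):
            return LackOfFit(False, "no replicated runs")
        ss_pure = 0.0
        for idx in groups.values():
            yi = y[list(idx)]
            ss_pure += float(((yi - yi.mean()) ** 2).sum())
        df_pure = len(y) - n_groups
        df_lof = n_groups - 1 - self.k_effects
        ss_lof = max(self.ss_error - ss_pure, 0.0)
        if df_lof <= 0:
            return LackOfFit(False, "no lack-of-fit degrees of freedom",
                             ss_pure=ss_pure, ss_lof=ss_lof, df_pure=df_pure, df_lof=df_lof)
        if df_pure == 0 or ss_pure == 0:
            return LackOfFit(False, "zero pure error",
                             ss_pure=ss_pure, ss_lof=ss_lof, df_pure=df_pure, df_lof=df_lof)
        f = (ss_lof / df_lof) / (ss_pure / df_pure)
        p = float(stats.f.sf(f, df_lof, df_pure))
        return LackOfFit(True, "", ss_pure, ss_lof, df_pure, df_lof, f, p)

    # ---- prediction & reporting -------------------------------------

    def predict(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Predict at new factor combinations using the stored centering."""
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame({k: [v] for k, v in data.items()})
        X, _, _ = build_model_matrix_noconst(
            data, self.model.terms, self.model.factors, self.model.centers
        )
        return float(self.params.iloc[0]) + X @ self.params.iloc[1:].to_numpy()

    def vertices(self) -> dict[str, dict]:
        """Closed-form optimum of each quadratic factor profile.

        Other factors are held at their fit-sample means, so a
        continuous interaction partner contributes nothing (its centered
        mean is zero) while an ordinal partner contributes through the
        mean of its indicator column.  Returns per-factor
        ``{"location", "value", "curvature"}``.
        """
        out: dict[str, dict] = {}
        fmap = factors_by_name(self.model.factors)
        data = self.model.data
        centers = self.model.centers
        for term in self.model.terms:
            if term.form != "quadratic":
                continue
            x = term.factors[0]
            a = float(self.params[term.name])
            if a == 0.0:
                continue
            b = float(self.params.get(x, 0.0))
            for t2 in self.model.terms:
                if t2.form == "interaction" and x in t2.factors:
                    other = t2.factors[0] if t2.factors[1] == x else t2.factors[1]
                    if fmap[other].is_continuous:
                        partner_mean = float((data[other] - centers[other]).mean())
                    else:
                        partner_mean = float(
                            (data[other] == fmap[other].levels[1]).mean()
                        )
                    b += float(self.params[t2.name]) * partner_mean
            loc = centers[x] - b / (2.0 * a)
            comb: dict[str, float] = {}
            for f in self.model.factors:
                if f.name == x:
                    comb[f.name] = loc
                elif f.is_continuous:
                    comb[f.name] = centers.get(f.name, float(data[f.name].mean()))
                else:
                    comb[f.name] = f.levels[0]
            value = float(self.predict(comb)[0])
            out[x] = {
                "location": loc,
                "value": value,
                "curvature": "concave" if a < 0 else "convex",
            }
        return out

    def equation(self, digits: int = 3) -> str:
        """Render the fitted model in its centered printed form."""
        parts = [_fmt_sig(self.params["intercept"], digits)]
        fmap = factors_by_name(self.model.factors)
        for term in self.model.terms:
            c = self.params[term.name]
            piece = _term_repr(term, self.model.centers, fmap, digits)
            parts.append(f"{'+' if c >= 0 else '-'} {_fmt_sig(abs(c), digits)}*{piece}")
        return f"{self.model.response} = " + " ".join(parts)

    def summary(self) -> str:
        """Plain-text summary table (whole model, then effects by ascending p)."""
        lof = self.lack_of_fit
        lof_txt = f"p = {lof.pvalue:.4f}" if lof.available else f"unavailable ({lof.reason})"
        lines = [
            f"Response: {self.model.response}    n = {self.nobs}   effects = {self.k_effects}",
            f"R2 = {self.rsquared:.4f}   R2adj = {self.rsquared_adj:.4f}   "
            f"RMSE_F = {self.rmse:.4g} ({self.rmse_pct_scale:.0f}% of average scale)   "
            f"MAE_F = {self.mae:.4g}",
            f"AICc = {self.aicc:.2f}   whole-model F({self.df_model},{self.df_error}) = "
            f"{self.fvalue:.3f}, p = {_fmt_p(self.f_pvalue)}   lack-of-fit: {lof_txt}",
            "-" * 72,
            f"{'effect':<24}{'coef':>12}{'beta':>10}{'p':>12}",
        ]
        order = self.effect_pvalues.sort_values(kind="stable").index
        for name in order:
            star = "*" if self.effect_pvalues[name] <= 0.05 else " "
            lines.append(
                f"{name:<24}{self.params[name]:>12.4g}{self.beta_weights[name]:>10.3f}"
                f"{_fmt_p(self.effect_pvalues[name]):>11}{star}"
            )
        lines.append("-" * 72)
        lines.append(self.equation())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        lof = self.lack_of_fit
        return {
            "response": self.model.response,
            "n": self.nobs,
            "k": self.k_effects,
            "params": {k: float(v) for k, v in self.params.items()},
            "centering": {k: float(v) for k, v in self.model.centers.items()},
            "terms": [t.name for t in self.model.terms],
            "r2": self.rsquared,
            "r2_adj": self.rsquared_adj,
            "rmse_f": self.rmse,
            "mae_f": self.mae,
            "rmse_pct_scale": self.rmse_pct_scale,
            "average_scale": self.average_scale,
            "aicc": self.aicc,
            "whole_model": {"F": self.fvalue, "p": self.f_pvalue},
            "lack_of_fit": {
                "available": lof.available,
                "reason": lof.reason,
                "F": None if not lof.available else lof.fvalue,
                "p": None if not lof.available else lof.pvalue,
            },
            "effects": {
                name: {
                    "coef": float(self.params[name]),
                    "beta": float(self.beta_weights[name]),
                    "ss": float(self.effect_ss[name]),
                    "p": float(self.effect_pvalues[name]),
                }
                for name in self.model.exog_names
            },
        }


def build_model_matrix_noconst(data, terms, factors, centers):
    """Encode columns with *fixed* centers (no constant-column check)."""
    fmap = factors_by_name(factors)
    cols = [encode_effect(t, data, centers, fmap) for t in terms]
    names = [t.name for t in terms]
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names, dict(centers)


def _fmt_sig(v: float, digits: int = 3) -> str:
    if v == 0:
        return "0"
    return f"{v:.{digits}g}"


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "nan"
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def _term_repr(term: EffectTerm, centers, fmap, digits=3) -> str:
    def cf(name: str) -> str:
        return f"({name}-{_fmt_sig(centers[name], digits)})"

    if term.form == "linear":
        f = term.factors[0]
        return f if fmap[f].is_continuous else f"[{f}=high]"
    if term.form == "quadratic":
        return f"{cf(term.factors[0])}^2"
    a, b = term.factors
    pieces = []
    for f in (a, b):
        pieces.append(f"[{f}=high]" if not fmap[f].is_continuous else cf(f))
    return "*".join(pieces)
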