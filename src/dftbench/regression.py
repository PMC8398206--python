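"""Ordinary-least-squares models of property errors on method features.

Each scored property's signed error over the functional x basis grid is
modelled as a linear function of the six descriptors (SR, MR, LR exchange
percentages, basis size NBF, double-zeta indicator, diffuse indicator), on
raw scales and with an intercept.  Models are then reduced by backward
elimination: the non-intercept term with the largest p-value above alpha is
dropped and the model refit, one term per step; the intercept becomes
eligible for removal only once every remaining slope is significant.

Fitting is delegated to :mod:`statsmodels` OLS; this module adds the feature
bookkeeping, the reduction trail, prediction from a coefficient table, and a
star-annotated text report (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .descriptors import FEATURE_NAMES

__all__ = [
    "RegressionModel",
    "CollinearityError",
    "fit_full",
    "reduce",
    "fit_reduced",
    "predict",
    "significance_stars",
    "model_report",
]

INTERCEPT = "intercept"


class CollinearityError(ValueError):
    """The design matrix is rank deficient; names the offending columns."""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class RegressionModel:
    """A fitted linear model with classical inference statistics.

    ``terms`` lists the included regressors (possibly with ``intercept``);
    ``reduction_trail`` records each dropped term with its p-value at removal.
    The training design and response are retained so reduction can refit.
    """

    response: str
    terms: tuple[str, ...]
    coef: Mapping[str, float]
    stderr: Mapping[str, float]
    tstat: Mapping[str, float]
    pvalue: Mapping[str, float]
    r_squared: float
    residual_std_error: float
    f_statistic: float | None
    f_pvalue: float | None
    n_observations: int
    reduction_trail: tuple[tuple[str, float], ...] = ()
    _design: pd.DataFrame | None = field(default=None, repr=False, compare=False)
    _y: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def intercept(self) -> float:
        return float(self.coef.get(INTERCEPT, 0.0))

    def as_dict(self) -> dict:
        """JSON-ready summary (coefficients, inference, trail)."""
        return {
            "response": self.response,
            "terms": list(self.terms),
            "coef": {t: float(self.coef[t]) for t in self.terms},
            "stderr": {t: float(self.stderr[t]) for t in self.terms},
            "tstat": {t: float(self.tstat[t]) for t in self.terms},
            "pvalue": {t: float(self.pvalue[t]) for t in self.terms},
            "stars": {t: significance_stars(float(self.pvalue[t])) for t in self.terms},
            "r_squared": self.r_squared,
            "residual_std_error": self.residual_std_error,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "n_observations": self.n_observations,
            "reduction_trail": [[t, float(p)] for t, p in self.reduction_trail],
        }


def _as_design(features: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features.drop(columns=[c for c in ("functional", "basis") if c in features.columns])
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected a (n, {len(FEATURE_NAMES)}) feature matrix, got shape {arr.shape}")
    return pd.DataFrame(arr, columns=list(FEATURE_NAMES))


def _diagnose_collinear(X: pd.DataFrame) -> list[str]:
    """Columns that are (near-)exact linear combinations of the others."""
    bad = []
    arr = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        if others.shape[1] == 0:
            continue
        proj, *_ = np.linalg.lstsq(np.column_stack([others, np.ones(len(arr))]), arr[:, j], rcond=None)
        resid = arr[:, j] - np.column_stack([others, np.ones(len(arr))]) @ proj
        scale = np.linalg.norm(arr[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(str(col))
    return bad


def _fit(X: pd.DataFrame, y: np.ndarray, response: str, with_intercept: bool, trail=()) -> RegressionModel:
    if with_intercept and np.ptp(y) == 0.0:
        # constant response: slopes are exactly zero and carry no evidence
        names = [INTERCEPT, *X.columns]
        return RegressionModel(
            response=response,
            terms=tuple(names),
            coef={INTERCEPT: float(y[0]), **{c: 0.0 for c in X.columns}},
            stderr={n: 0.0 for n in names},
            tstat={n: 0.0 for n in names},
            pvalue={INTERCEPT: 0.0, **{c: 1.0 for c in X.columns}},
            r_squared=0.0,
            residual_std_error=0.0,
            f_statistic=None,
            f_pvalue=None,
            n_observations=len(y),
            reduction_trail=tuple(trail),
            _design=X,
            _y=np.asarray(y, dtype=float),
        )
    design = sm.add_constant(X, prepend=True, has_constant="add") if with_intercept else X
    if design.shape[1] == 0:
        raise ValueError("no terms to fit")
    res = sm.OLS(y, design).fit()
    names = ["intercept" if n == "const" else n for n in design.columns]
    coef = dict(zip(names, res.params))
    stderr = dict(zip(names, res.bse))
    tstat = dict(zip(names, res.tvalues))
    pval = dict(zip(names, res.pvalues))
    rse = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
    rsq = float(res.rsquared)
    if not np.isfinite(rsq):
        rsq = 0.0  # constant response: no variance to explain
    fstat = float(res.fvalue) if res.df_model > 0 and np.isfinite(res.fvalue) else None
    fp = float(res.f_pvalue) if fstat is not None and np.isfinite(res.f_pvalue) else None
    return RegressionModel(
        response=response,
        terms=tuple(names),
        coef=coef,
        stderr=stderr,
        tstat=tstat,
        pvalue=pval,
        r_squared=rsq,
        residual_std_error=rse,
        f_statistic=fstat,
        f_pvalue=fp,
        n_observations=int(res.nobs),
        reduction_trail=tuple(trail),
        _design=X,
        _y=np.asarray(y, dtype=float),
    )


def fit_full(features: pd.DataFrame | np.ndarray, response: Sequence[float], response_name: str = "y") -> RegressionModel:
    """OLS of the response on all six features plus an intercept.

    Zero-variance columns are dropped with a warning (they are
    indistinguishable from the intercept); any remaining rank deficiency
    raises :class:`CollinearityError` naming the dependent columns.
    """
    X = _as_design(features).astype(float)
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"{len(X)} rows of features but {len(y)} responses")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need more than {X.shape[1] + 1} observations, got {len(y)}")

    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance feature column(s): {', '.join(constant)}", stacklevel=2)
        X = X.drop(columns=constant)

    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(f"rank-deficient design; collinear columns: {', '.join(_diagnose_collinear(X)) or 'unidentified'}")
    return _fit(X, y, response_name, with_intercept=True)


def reduce(model: RegressionModel, alpha: float = 0.05) -> RegressionModel:
    """Backward elimination at significance level ``alpha``.

    Repeatedly drops the slope with the largest p-value above alpha and
    refits; once all slopes are significant, a non-significant intercept is
    dropped too (an intercept-free form is legitimate).  Terminates when
    every remaining term has p <= alpha, possibly with no terms left.
    """
    if model._design is None or model._y is None:
        raise ValueError("model does not retain its training data; refit with fit_full")
    X = model._design
    y = model._y
    with_intercept = INTERCEPT in model.terms
    current = model
    trail = list(model.reduction_trail)

    while True:
        slopes = [(t, current.pvalue[t]) for t in current.terms if t != INTERCEPT]
        weak = [(t, p) for t, p in slopes if p > alpha]
        if weak:
            drop, p = max(weak, key=lambda tp: tp[1])
            trail.append((drop, float(p)))
            X = X.drop(columns=[drop])
            if X.shape[1] == 0 and not with_intercept:
                return replace(current, terms=(), coef={}, stderr={}, tstat={}, pvalue={}, reduction_trail=tuple(trail))
            current = _fit(X, y, model.response, with_intercept, trail)
            continue
        if with_intercept and current.pvalue.get(INTERCEPT, 0.0) > alpha:
            trail.append((INTERCEPT, float(current.pvalue[INTERCEPT])))
            with_intercept = False
            if X.shape[1] == 0:
                return replace(current, terms=(), coef={}, stderr={}, tstat={}, pvalue={}, reduction_trail=tuple(trail))
            current = _fit(X, y, model.response, with_intercept, trail)
            continue
        return current


def fit_reduced(
    features: pd.DataFrame | np.ndarray,
    response: Sequence[float],
    response_name: str = "y",
    alpha: float = 0.05,
) -> RegressionModel:
    """Convenience: full fit followed by backward reduction."""
    return reduce(fit_full(features, response, response_name), alpha=alpha)


def predict(model: RegressionModel | Mapping[str, float], features: Mapping[str, float]) -> float:
    """Linear predictor for one feature vector.

    Accepts a fitted model or a bare term -> coefficient mapping (the
    published coefficient tables can be applied directly).  Every
    non-intercept term must be supplied in ``features``.
    """
    coef = model.coef if isinstance(model, RegressionModel) else model
    total = 0.0
    missing = []
    for term, c in coef.items():
        if term == INTERCEPT:
            total += c
        elif term in features:
            total += c * float(features[term])
        else:
            missing.append(term)
    if missing:
        raise KeyError(f"feature vector is missing required term(s): {', '.join(missing)}")
    return total


def model_report(models: Sequence[RegressionModel]) -> str:
    """Star-annotated text table of one or more fitted models."""
    lines = []
    for m in models:
        lines.append(f"response: {m.response}   n={m.n_observations}")
        lines.append(f"  R^2={m.r_squared:.4f}  resid SE={m.residual_std_error:.4f}  " +
                     (f"F={m.f_statistic:.2f} (p={m.f_pvalue:.3g})" if m.f_statistic is not None else "F=--"))
        for t in m.terms:
            lines.append(
                f"  {t:>10s}  {m.coef[t]: .6g}{significance_stars(m.pvalue[t]):<3s} "
                f"(se={m.stderr[t]:.3g}, p={m.pvalue[t]:.3g})"
            )
        if m.reduction_trail:
            dropped = ", ".join(f"{t} (p={p:.3g})" for t, p in m.reduction_trail)
            lines.append(f"  dropped: {dropped}")
        lines.append("")
    lines.append("significance: * p<0.05, ** p<0.01, *** p<0.001")
    return "\n".join(lines)
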