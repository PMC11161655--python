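"""Grey-matter trajectory breakpoints, the residual reserve method, and
feature-set model comparison for predicting processing speed.

Brain-reserve analyses relate volumetric measures to cognition only after
(i) locating the age at which atrophy begins, via continuous piecewise-linear
("breakpoint") regression, and (ii) adjusting regional volumes for total
intracranial volume by the residual method.  Complementarity of grey matter,
network controllability and path redundancy as predictors of processing
speed is then quantified by fitting one Gaussian GLM per feature block
combination and comparing R^2, log-likelihood, AIC and BIC on the identical
complete-case sample.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

from .errors import (
    DegenerateBreakpointWarning,
    ParameterError,
    ValidationError,
)
from .stats import residualize_on


@dataclass
class BreakpointFit:
    """Continuous piecewise-linear fit of a volume-vs-age trajectory."""

    breakpoints: tuple[float, ...]
    segment_slopes: tuple[float, ...]
    intercept: float
    sse: float
    n_segments: int
    #: per-segment (pearson_r, p, n) computed on the raw data inside each segment
    segment_stats: tuple[tuple[float, float, int], ...]

    @property
    def breakpoint_age(self) -> float:
        return self.breakpoints[0]

    def predict(self, age) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        y = self.intercept + self.segment_slopes[0] * a
        for bp, (s0, s1) in zip(self.breakpoints,
                                itertools.pairwise(self.segment_slopes)):
            y = y + (s1 - s0) * np.maximum(a - bp, 0.0)
        return y


def _piecewise_sse(age: np.ndarray, y: np.ndarray, breaks: np.ndarray):
    D = np.column_stack(
        [np.ones_like(age), age] + [np.maximum(age - b, 0.0) for b in breaks]
    )
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return float(resid @ resid), beta


def fit_breakpoint(age, volume, n_segments: int = 2) -> BreakpointFit:
    """Fit a continuous piecewise-linear trajectory with data-driven breakpoints.

    The breakpoint location is profiled: for each candidate the slopes are the
    least-squares solution of the hinge design ``[1, age, (age - b)_+ ...]``,
    and the candidate minimizing the total squared error is refined by bounded
    scalar optimization (single breakpoint) or Nelder-Mead (several).

    Emits :class:`~ctrlred.errors.DegenerateBreakpointWarning` when the
    segment slopes are indistinguishable, i.e. the data are effectively
    linear.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(volume, dtype=float)
    if age.shape != y.shape:
        raise ValidationError("age and volume must have equal length")
    mask = np.isfinite(age) & np.isfinite(y)
    age, y = age[mask], y[mask]
    if age.size < 20:
        raise ValidationError(f"need >= 20 points, got {age.size}")
    if np.ptp(age) < 10.0:
        raise ValidationError("age span must cover >= 10 years")
    if n_segments < 2:
        raise ParameterError("n_segments must be >= 2")

    lo, hi = np.quantile(age, [0.02, 0.98])
    n_breaks = n_segments - 1
    if n_breaks == 1:
        grid = np.linspace(lo, hi, 201)
        sses = [
            _piecewise_sse(age, y, np.array([b]))[0] for b in grid
        ]
        i = int(np.argmin(sses))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda b: _piecewise_sse(age, y, np.array([b]))[0],
            bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-4},
        )
        breaks = np.array([float(res.x)])
    else:
        init = np.quantile(age, np.linspace(0, 1, n_breaks + 2)[1:-1])

        def obj(b):
            b = np.sort(b)
            if b[0] < lo or b[-1] > hi:
                return np.inf
            return _piecewise_sse(age, y, b)[0]

        res = optimize.minimize(obj, init, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-10})
        breaks = np.sort(res.x)
    sse, beta = _piecewise_sse(age, y, breaks)
    slopes = [float(beta[1])]
    for j in range(n_breaks):
        slopes.append(slopes[-1] + float(beta[2 + j]))

    scale = max(np.abs(slopes).max(), np.ptp(y) / max(np.ptp(age), 1.0), 1e-12)
    if max(abs(slopes[j + 1] - slopes[j]) for j in range(n_breaks)) < 1e-6 * scale:
        warnings.warn(
            "segment slopes are indistinguishable: no genuine breakpoint",
            DegenerateBreakpointWarning,
        )

    edges = np.concatenate([[age.min()], breaks, [age.max()]])
    seg_stats = []
    for j in range(n_segments):
        m = (age >= edges[j]) & (age <= edges[j + 1])
        if m.sum() >= 3 and np.ptp(age[m]) > 0 and np.ptp(y[m]) > 0:
            r, p = sps.pearsonr(age[m], y[m])
        else:
            r, p = np.nan, np.nan
        seg_stats.append((float(r), float(p), int(m.sum())))

    return BreakpointFit(
        tuple(float(b) for b in breaks), tuple(slopes), float(beta[0]),
        sse, n_segments, tuple(seg_stats),
    )


def residual_adjust(volume, icv) -> np.ndarray:
    """Residual-method adjustment of a volume for total intracranial volume.

    Returns the residuals of the intercept-included regression of ``volume``
    on ``icv``; the output is exactly uncorrelated with ``icv``.
    """
    v = np.asarray(volume, dtype=float)
    c = np.asarray(icv, dtype=float)
    if np.any(v <= 0) or np.any(c <= 0):
        raise ValidationError("volumes must be strictly positive")
    return residualize_on(v, c)


# ---------------------------------------------------------------------------
# Feature-set model comparison


@dataclass
class ModelComparison:
    """Goodness-of-fit table for a family of feature-set GLMs."""

    table: pd.DataFrame  # label, r_squared, log_likelihood, aic, bic, n, k
    coefficients: dict[str, pd.Series] = field(default_factory=dict)


def default_feature_sets(
    gm: Sequence[str], control: Sequence[str], redundancy: Sequence[str]
) -> dict[str, list[str]]:
    """The seven nonempty combinations of the GM/Control/Redundancy blocks."""
    blocks = {"GM": list(gm), "Control": list(control), "Redundancy": list(redundancy)}
    sets: dict[str, list[str]] = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(blocks, r):
            sets[" + ".join(combo)] = sum((blocks[b] for b in combo), [])
    return sets


def compare_feature_models(
    table: pd.DataFrame,
    outcome: str,
    feature_sets: Mapping[str, Sequence[str]],
    age_min: float | None = None,
    age_col: str = "age",
    zscore: bool = True,
) -> ModelComparison:
    """Fit one Gaussian-identity GLM per feature set on the identical sample.

    Subjects may first be restricted to ``age > age_min`` (the data-driven
    hippocampal breakpoint in the standard analysis).  The outcome and all
    predictors are z-scored on the analysis sample; this affects coefficients
    but not R^2, log-likelihood, AIC or BIC.
    """
    all_cols = sorted({outcome, *itertools.chain.from_iterable(feature_sets.values())})
    df = table
    if age_min is not None:
        df = df[df[age_col] > age_min]
    df = df[all_cols].dropna().astype(float)
    n = len(df)
    max_k = max(len(v) for v in feature_sets.values())
    if max_k + 1 >= n:
        raise ParameterError(
            f"feature count {max_k} (+ intercept) must be below sample size {n}"
        )
    if zscore:
        df = (df - df.mean()) / df.std(ddof=0)
    rows = []
    coefs: dict[str, pd.Series] = {}
    for label, feats in feature_sets.items():
        Xd = sm.add_constant(df[list(feats)], has_constant="add")
        # OLS == Gaussian-identity GLM; its MLE-scale likelihood keeps the
        # nested-model log-likelihood ordering exact.
        fit = sm.OLS(df[outcome], Xd).fit()
        r2 = float(fit.rsquared)
        k = len(feats) + 1
        ll = float(fit.llf)
        rows.append({
            "label": label, "r_squared": r2, "log_likelihood": ll,
            "aic": 2 * k - 2 * ll, "bic": k * np.log(n) - 2 * ll,
            "n": n, "k": k,
        })
        coefs[label] = fit.params
    return ModelComparison(pd.DataFrame(rows), coefs)
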