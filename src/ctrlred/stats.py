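"""Covariate-adjusted rank correlations, group contrasts and bootstrap mediation.

The inferential toolkit mirrors a cross-sectional aging analysis: Spearman
correlations with education as a covariate (partial correlation on ranks),
ANCOVA / Welch ANOVA group comparisons between middle-aged and old-aged
subjects, Fisher z contrasts of sex-specific correlations, degree-residualized
associations, and parallel mediation with percentile bootstrap confidence
intervals, all Bonferroni-corrected within their test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    DiagnosticsError,
    DivergenceError,
    ParameterError,
    ValidationError,
)


def bonferroni(p_values, m: int):
    """Bonferroni adjustment ``min(1, p * m)``, element-wise."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ParameterError(f"family size must be >= 1, got {m}")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, p * m)
    return float(adj) if np.isscalar(p_values) else adj


def assign_age_group(ages, cut: float = 65.0) -> np.ndarray:
    """Label subjects 'middle' (age < cut) or 'old' (age >= cut)."""
    ages = np.asarray(ages, dtype=float)
    return np.where(ages < cut, "middle", "old")


@dataclass
class CorrelationResult:
    rho: float
    p_raw: float
    p_adjusted: float
    n: int
    covariates: tuple[str, ...] = ()
    family_size: int = 1


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def partial_spearman(
    x,
    y,
    covariates: np.ndarray | Sequence | None = None,
    family_size: int = 1,
    covariate_names: Sequence[str] = (),
) -> CorrelationResult:
    """Spearman correlation of x and y, partialling out covariates on ranks.

    All variables are rank-transformed (average ranks for ties); the partial
    Pearson correlation of the ranked x and y given the ranked covariates is
    the covariate-adjusted rank correlation.  With no covariates this reduces
    exactly to the plain Spearman coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = None
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    mask = np.isfinite(x) & np.isfinite(y)
    if Z is not None:
        mask &= np.all(np.isfinite(Z), axis=1)
    x, y = x[mask], y[mask]
    n = x.size
    k = 0 if Z is None else Z.shape[1]
    if n < k + 4:
        raise ValidationError(f"too few complete cases (n={n})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    if Z is None:
        rho, p = sps.spearmanr(x, y)
    else:
        Z = Z[mask]
        rx, ry = _rank(x), _rank(y)
        rz = np.column_stack([_rank(Z[:, j]) for j in range(k)])
        D = np.column_stack([np.ones(n), rz])
        ex = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
        ey = ry - D @ np.linalg.lstsq(D, ry, rcond=None)[0]
        denom = np.sqrt((ex @ ex) * (ey @ ey))
        if denom == 0:
            raise DegenerateInputError("residual variance is zero")
        rho = float((ex @ ey) / denom)
        df = n - 2 - k
        rho_c = np.clip(rho, -0.9999999999, 0.9999999999)
        t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(float(rho), float(p), bonferroni(p, family_size),
                             n, tuple(covariate_names), family_size)


@dataclass
class GroupComparison:
    F: float
    p_raw: float
    p_adjusted: float
    method: str
    n_groups: int
    family_size: int = 1


def group_compare(
    values,
    group_labels,
    covariates: pd.DataFrame | None = None,
    method: str = "ancova",
    family_size: int = 1,
) -> GroupComparison:
    """Compare a metric between groups by ANCOVA or Welch's ANOVA.

    ANCOVA adjusts for the supplied covariates (e.g. education); Welch's
    ANOVA ignores covariates and drops the equal-variance assumption, the
    combination used for hub-level contrasts.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or np.any(counts < 3):
        raise ValidationError("need >= 2 groups with >= 3 members each")
    df = pd.DataFrame({"y": values, "group": labels})
    if method == "ancova":
        covs: list[str] = []
        if covariates is not None:
            for col in covariates.columns:
                df[col] = np.asarray(covariates[col], dtype=float)
                covs.append(col)
        if covs:
            res = pg.ancova(data=df, dv="y", between="group", covar=covs)
        else:  # ANCOVA without covariates reduces to a one-way ANOVA
            res = pg.anova(data=df, dv="y", between="group")
        row = res.loc[res["Source"] == "group"].iloc[0]
    elif method == "welch_anova":
        res = pg.welch_anova(data=df, dv="y", between="group")
        row = res.iloc[0]
    else:
        raise ParameterError(f"unknown method {method!r}")
    pcol = "p_unc" if "p_unc" in row.index else "p-unc"
    F, p = float(row["F"]), float(row[pcol])
    return GroupComparison(F, p, bonferroni(p, family_size), method,
                           int(uniq.size), family_size)


def sex_correlation_contrast(rho_f: float, n_f: int, rho_m: float, n_m: int):
    """Fisher z contrast of two independent correlations.

    ``z = (atanh(rho_f) - atanh(rho_m)) / sqrt(1/(n_f-3) + 1/(n_m-3))`` with a
    two-sided normal p-value.
    """
    for rho in (rho_f, rho_m):
        if abs(rho) >= 1.0:
            raise DivergenceError("|rho| = 1: Fisher transform diverges")
    if n_f < 4 or n_m < 4:
        raise ValidationError("need n >= 4 in both groups")
    z = (np.arctanh(rho_f) - np.arctanh(rho_m)) / np.sqrt(
        1.0 / (n_f - 3) + 1.0 / (n_m - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def residualize_on(values, regressor) -> np.ndarray:
    """Residuals of an intercept-included least-squares fit of values on regressor."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(regressor, dtype=float)
    if y.shape != x.shape:
        raise ValidationError("values and regressor must have equal length")
    if np.ptp(x) == 0:
        raise ValidationError("constant regressor")
    D = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


# ---------------------------------------------------------------------------
# Mediation


@dataclass
class MediationResult:
    """Linear path mediation X -> M -> Y with bootstrap inference.

    ``indirect = a * b`` with paths estimated by OLS including the covariates
    in every equation; the confidence interval is a percentile bootstrap over
    subjects at level ``1 - alpha / family_size`` and the mediation is
    significant iff the interval excludes zero.
    """

    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    ci_lower: float
    ci_upper: float
    conf_level: float
    n_boot: int
    significant: bool
    n: int
    covariates: tuple[str, ...] = ()
    seed: int | None = None


def _boot_coef(design: np.ndarray, y: np.ndarray, idx: np.ndarray,
               col: int) -> np.ndarray:
    """Coefficient ``col`` of OLS fits over bootstrap index matrix (B, n)."""
    D = design[idx]                      # (B, n, p)
    G = np.einsum("bnp,bnq->bpq", D, D)
    h = np.einsum("bnp,bn->bp", D, y[idx])
    try:
        beta = np.linalg.solve(G, h[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.einsum("bpq,bq->bp", np.linalg.pinv(G), h)
    return beta[:, col]


def mediate(
    X,
    M,
    Y,
    covariates: np.ndarray | None = None,
    n_boot: int = 10000,
    alpha: float = 0.05,
    family_size: int = 1,
    seed: int | None = None,
    covariate_names: Sequence[str] = (),
    _chunk: int = 2000,
) -> MediationResult:
    """Single-mediator linear mediation with a seeded percentile bootstrap."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Z = None
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    mask = np.isfinite(X) & np.isfinite(M) & np.isfinite(Y)
    if Z is not None:
        mask &= np.all(np.isfinite(Z), axis=1)
    X, M, Y = X[mask], M[mask], Y[mask]
    if Z is not None:
        Z = Z[mask]
    n = X.size
    if n < 30:
        raise ValidationError(f"mediation needs >= 30 complete cases, got {n}")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    if not (0 < alpha < 1) or family_size < 1:
        raise ParameterError("need 0 < alpha < 1 and family_size >= 1")

    ones = np.ones(n)
    zcols = [] if Z is None else [Z]
    Da = np.column_stack([ones, X, *zcols])          # M ~ X (+ covs); a at col 1
    Db = np.column_stack([ones, X, M, *zcols])       # Y ~ X + M (+ covs)
    Dc = Da                                          # Y ~ X (+ covs); c at col 1
    cond = np.linalg.cond(Db)
    if cond > 1e10:
        raise DiagnosticsError(
            f"collinear design (condition number {cond:.3g})"
        )
    beta_a = np.linalg.lstsq(Da, M, rcond=None)[0]
    beta_b = np.linalg.lstsq(Db, Y, rcond=None)[0]
    beta_c = np.linalg.lstsq(Dc, Y, rcond=None)[0]
    a, b = float(beta_a[1]), float(beta_b[2])
    c_prime, c_total = float(beta_b[1]), float(beta_c[1])

    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    done = 0
    while done < n_boot:
        B = min(_chunk, n_boot - done)
        idx = rng.integers(0, n, size=(B, n))
        draws[done:done + B] = (
            _boot_coef(Da, M, idx, 1) * _boot_coef(Db, Y, idx, 2)
        )
        done += B
    q = alpha / family_size
    lo, hi = np.percentile(draws, [100 * q / 2, 100 * (1 - q / 2)])
    return MediationResult(
        a=a, b=b, c_total=c_total, c_prime=c_prime, indirect=a * b,
        ci_lower=float(lo), ci_upper=float(hi), conf_level=1.0 - q,
        n_boot=n_boot, significant=bool(lo > 0 or hi < 0), n=n,
        covariates=tuple(covariate_names), seed=seed,
    )
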