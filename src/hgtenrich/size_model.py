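"""Genome-size correction of shared-gene counts.

The number of genes a bacterium shares with any given archaeon rises with the
bacterium's gene count and saturates. Per archaeon we fit a four-parameter
log-logistic curve

    f(x) = c + (d - c) / (1 + (x / e)^b)

with x the bacterial gene count, c/d the lower/upper asymptote, e the
inflection point and b the shape (b < 0 yields an increasing curve; the form
is identical to c + (d-c)/(1 + 10^{b (log10 x - log10 e)})). "Residual RBHs"
are observed counts minus this fit; they are the size-corrected sharing
measure everything downstream consumes. A symmetric alternative, the Korbel
weighted average sqrt(2)AB/(A^2+B^2) over both partners' gene counts, is
provided for model comparison.

A secondary adjustment regresses the primary residuals on bacterial %GC and
gene count (ordinary least squares, with intercept) to verify that GC content
is not confounding phenotype effects.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .errors import DegenerateDataError, DomainError, InputError, InsufficientDataError
from .models import LogLogisticFit, ResidualMatrix

__all__ = [
    "log_logistic",
    "fit_log_logistic",
    "korbel_weight",
    "fit_korbel_scale",
    "residual_matrix",
    "decorrelation_check",
    "secondary_residuals",
]


def log_logistic(x, b: float, c: float, d: float, e: float):
    """Evaluate the four-parameter log-logistic curve at gene count(s) x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("log_logistic requires x > 0")
    if e <= 0:
        raise DomainError("log_logistic requires e > 0")
    out = c + (d - c) / (1.0 + (x / e) ** b)
    return float(out) if out.ndim == 0 else out


def _loglogistic_residuals(theta, x, y):
    b, c, delta, e = theta
    return (c + delta / (1.0 + (x / e) ** b)) - y


def fit_log_logistic(
    sizes,
    counts,
    *,
    max_restarts: int = 20,
    seed: int = 0,
    archaeon: str = "",
) -> LogLogisticFit:
    """Nonlinear least-squares fit of counts ~ log_logistic(sizes).

    Internally parameterized as (b, c, d-c, e) with d-c >= 0 and c >= 0 so the
    asymptote ordering and non-negativity are enforced by bounds.
    Initialization: c0=min(counts), d0=max(counts), e0=median(sizes), b0=-1;
    on failure up to ``max_restarts`` jittered restarts. ``converged`` is
    False if no restart succeeded (best-effort parameters are still returned).
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("sizes and counts must be 1-D and of equal length")
    if len(x) < 5:
        raise InsufficientDataError(f"need >= 5 points to fit, got {len(x)}")
    if np.any(x <= 0):
        raise DomainError("sizes must be positive")

    if np.ptp(y) == 0:
        # constant response: flat curve, nothing to estimate
        const = float(y[0])
        return LogLogisticFit(
            archaeon=archaeon, b=-1.0, c=const, d=const, e=float(np.median(x)),
            residual_sd=0.0, converged=True, n_points=len(x), degenerate=True,
        )

    c0 = max(float(np.min(y)), 0.0)
    d0 = float(np.max(y))
    theta0 = np.array([-1.0, c0, max(d0 - c0, 1e-6), float(np.median(x))])
    lower = np.array([-10.0, 0.0, 0.0, 1.0])
    upper = np.array([10.0, np.inf, np.inf, 1e7])

    rng = np.random.default_rng(seed)
    best = None
    best_cost = np.inf
    start = theta0
    for attempt in range(max_restarts + 1):
        try:
            res = least_squares(
                _loglogistic_residuals, np.clip(start, lower, upper),
                bounds=(lower, upper), args=(x, y),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            res = None
        if res is not None and np.isfinite(res.cost) and res.cost < best_cost:
            best, best_cost = res, res.cost
        if best is not None and best.success and attempt >= 1:
            break
        if best is not None and best.success and attempt == 0:
            break
        # jittered restart
        jitter = rng.uniform(0.5, 2.0, size=4)
        start = theta0 * jitter
        start[0] = -rng.uniform(0.3, 3.0)

    if best is None:
        raise InsufficientDataError("log-logistic fit failed on all restarts")
    b, c, delta, e = best.x
    d = c + delta
    resid = y - log_logistic(x, b, c, d, e)
    residual_sd = float(np.std(resid, ddof=1))
    return LogLogisticFit(
        archaeon=archaeon, b=float(b), c=float(c), d=float(d), e=float(e),
        residual_sd=residual_sd, converged=bool(best.success), n_points=len(x),
    )


def korbel_weight(A, B):
    """Symmetric genome-size weight sqrt(2)*A*B / (A^2 + B^2), in (0, sqrt(2)/2]."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(A <= 0) or np.any(B <= 0):
        raise DomainError("korbel_weight requires positive gene counts")
    w = np.sqrt(2.0) * A * B / (A**2 + B**2)
    return float(w) if w.ndim == 0 else w


def fit_korbel_scale(size_pairs, counts) -> float:
    """Least-squares scale s for counts ~ s * korbel_weight(A, B).

    Closed form: s = sum(count * w) / sum(w^2).
    """
    pairs = np.asarray(size_pairs, dtype=float)
    y = np.asarray(counts, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) != len(y):
        raise InputError("size_pairs must be an (n, 2) array matching counts")
    if len(y) < 2:
        raise InsufficientDataError("need >= 2 pairs to estimate the Korbel scale")
    w = korbel_weight(pairs[:, 0], pairs[:, 1])
    denom = float(np.sum(w * w))
    if denom == 0.0:
        raise DegenerateDataError("all Korbel weights are zero")
    return float(np.sum(y * w) / denom)


def residual_matrix(rbh: pd.DataFrame, fits: dict, sizes: pd.Series) -> ResidualMatrix:
    """Observed minus fitted counts per (bacterium, archaeon).

    ``rbh``: counts indexed by bacterium, columns archaea. ``fits``: one
    :class:`LogLogisticFit` per archaeon column. ``sizes``: bacterial gene
    counts indexed by bacterium id.
    """
    missing = [a for a in rbh.columns if a not in fits]
    if missing:
        raise InputError(f"missing log-logistic fit for archaea: {missing}")
    absent = [b for b in rbh.index if b not in sizes.index]
    if absent:
        raise InputError(f"missing gene counts for bacteria: {absent}")
    x = sizes.loc[rbh.index].to_numpy(dtype=float)
    res = {}
    sd = {}
    for a in rbh.columns:
        f = fits[a]
        res[a] = rbh[a].to_numpy(dtype=float) - log_logistic(x, f.b, f.c, f.d, f.e)
        sd[a] = f.residual_sd
    values = pd.DataFrame(res, index=rbh.index)[list(rbh.columns)]
    return ResidualMatrix(values=values, residual_sd=pd.Series(sd))


def decorrelation_check(residuals, sizes) -> float:
    """Squared Pearson correlation of residuals against bacterial gene counts.

    Returns NaN (with a warning) when either input has zero variance.
    """
    r = np.asarray(residuals, dtype=float)
    x = np.asarray(sizes, dtype=float)
    if len(r) != len(x):
        raise InputError("residuals and sizes must have equal length")
    if len(r) < 3:
        raise InsufficientDataError("need >= 3 bacteria for the decorrelation check")
    if np.std(r) == 0 or np.std(x) == 0:
        warnings.warn("zero-variance input: decorrelation R^2 undefined", stacklevel=2)
        return float("nan")
    rho = pearsonr(r, x).statistic
    return float(rho * rho)


def secondary_residuals(primary: ResidualMatrix, sizes: pd.Series, gc: pd.Series) -> ResidualMatrix:
    """Regress out bacterial %GC and gene count from primary residuals.

    Per archaeon: OLS of the residual column on (gc, size) with intercept;
    the secondary residual is the OLS residual. Residual SDs are recomputed.
    """
    idx = primary.values.index
    for name, s in (("sizes", sizes), ("gc", gc)):
        absent = [b for b in idx if b not in s.index]
        if absent:
            raise InputError(f"{name} missing bacteria: {absent}")
    X = np.column_stack([gc.loc[idx].to_numpy(float), sizes.loc[idx].to_numpy(float)])
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDataError("collinear design: gc and size do not span 2 dimensions")
    out = {}
    sd = {}
    for a in primary.values.columns:
        fitted = sm.OLS(primary.values[a].to_numpy(float), design).fit()
        out[a] = fitted.resid
        sd[a] = float(np.std(fitted.resid, ddof=1))
    values = pd.DataFrame(out, index=idx)[list(primary.values.columns)]
    return ResidualMatrix(values=values, residual_sd=pd.Series(sd))
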