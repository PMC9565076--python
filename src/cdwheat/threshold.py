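"""Single-threshold two-regime linear regression.

The model splits the sample on a threshold variable q at an unknown point
gamma and fits a separate linear equation in the predictor x on each side:

    y_i = a1 + b1 * x_i + e_i   if q_i <= gamma   (regime 1)
    y_i = a2 + b2 * x_i + e_i   if q_i >  gamma   (regime 2)

gamma is estimated by concentrated least squares: for every admissible
candidate (the distinct observed values of q, trimmed so both regimes keep
enough observations) the two regime regressions are fitted and the combined
residual sum of squares S(gamma) recorded; gamma_hat minimises S.  Inference
follows the classical machinery for this estimator:

* LR sequence  LR(gamma) = n * (S(gamma) - S(gamma_hat)) / S(gamma_hat),
  equivalently (S(gamma) - S(gamma_hat)) / sigma2_hat with
  sigma2_hat = S(gamma_hat) / n; LR(gamma_hat) = 0 by construction.
* Confidence set for gamma by inverting the LR sequence at the critical
  value c(alpha) = -2 * ln(1 - sqrt(1 - alpha)) of the non-standard
  asymptotic distribution of LR at the true threshold.
* Existence of a threshold is tested with the sup-F statistic
  n * (SSR_null - S(gamma_hat)) / S(gamma_hat) against a residual-bootstrap
  null distribution (responses resampled under the fitted single-regime
  linear model), since gamma is unidentified under the null and the sup-F
  null law is not pivotal.

The grid scan is computed from cumulative sufficient statistics in O(n)
after sorting, which keeps the bootstrap and Monte-Carlo suites fast; the
plain two-regression route (`ssr_at`) is retained and must agree with the
scan, which the test suite checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import Dataset, complete_cases
from .errors import (
    ConfigurationError,
    DegenerateThresholdError,
    DegenerateVarianceError,
    RegimeSingularityError,
)

logger = logging.getLogger(__name__)

_SINGULAR_REL = 1e-12  # relative floor for a regime's predictor spread
_DEGENERATE_REL = 1e-10  # sigma2 below this (relative to response scale) is 0


@dataclass(frozen=True)
class ThresholdSpec:
    """Declaration of one threshold fit.

    Parameters
    ----------
    response, predictor, threshold_var
        Column names for y, x and q.  predictor and threshold_var may
        coincide (e.g. pH as both regressor and splitting variable).
    trim_fraction
        Fraction of the sample excluded from each tail of the candidate
        grid, so both regimes retain at least ceil(trim_fraction * n)
        observations.  Default 0.15.
    min_regime_size
        Hard floor on regime size regardless of trimming; must allow at
        least one residual degree of freedom per regime.
    include_intercept
        Fit a + b*x per regime (default) or slope-only through the origin.
    """

    response: str
    predictor: str
    threshold_var: str
    trim_fraction: float = 0.15
    min_regime_size: int = 3
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.trim_fraction < 0.5:
            raise ConfigurationError(
                f"trim_fraction must be in (0, 0.5), got {self.trim_fraction}"
            )
        k = 2 if self.include_intercept else 1
        if self.min_regime_size < k + 1:
            raise ConfigurationError(
                f"min_regime_size must be >= {k + 1} for {k} coefficient(s)"
            )


@dataclass(frozen=True)
class LinearBaseline:
    """Single-regime OLS fit of response on predictor (the no-threshold null)."""

    intercept: float
    slope: float
    r2: float
    ssr_null: float
    n: int


@dataclass
class ThresholdFit:
    """A fitted two-regime threshold model."""

    spec: ThresholdSpec
    gamma_hat: float
    beta_low: tuple[float, float]   # (intercept, slope), regime q <= gamma
    beta_high: tuple[float, float]  # (intercept, slope), regime q > gamma
    n_low: int
    n_high: int
    ssr: float                      # S(gamma_hat)
    sigma2_hat: float               # S(gamma_hat) / n
    r2_low: float
    r2_high: float
    baseline: LinearBaseline
    grid: np.ndarray                # admissible candidate thresholds
    ssr_grid: np.ndarray            # S(gamma) over the grid
    q_range: tuple[float, float]
    q_distinct: np.ndarray | None = None  # sorted distinct observed q
    lr_sequence: list[tuple[float, float]] | None = None
    ci_gamma: dict | None = None
    sup_stat: float | None = None
    boot_p: float | None = None
    seed: int | None = None

    @classmethod
    def from_coefficients(
        cls,
        spec: ThresholdSpec,
        gamma: float,
        beta_low: tuple[float, float],
        beta_high: tuple[float, float],
        q_range: tuple[float, float] = (-np.inf, np.inf),
    ) -> "ThresholdFit":
        """Wrap published regime equations so :func:`predict` can evaluate
        them; estimation-side fields are filled with placeholders."""
        baseline = LinearBaseline(np.nan, np.nan, np.nan, np.nan, 0)
        return cls(
            spec=spec, gamma_hat=float(gamma),
            beta_low=tuple(beta_low), beta_high=tuple(beta_high),
            n_low=0, n_high=0, ssr=np.nan, sigma2_hat=np.nan,
            r2_low=np.nan, r2_high=np.nan, baseline=baseline,
            grid=np.array([gamma]), ssr_grid=np.array([np.nan]),
            q_range=q_range,
        )

    @property
    def n(self) -> int:
        return self.n_low + self.n_high

    @property
    def degenerate_variance(self) -> bool:
        return self.lr_sequence is None

    def as_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "predictor": self.spec.predictor,
            "threshold_var": self.spec.threshold_var,
            "gamma_hat": self.gamma_hat,
            "intercept_low": self.beta_low[0],
            "slope_low": self.beta_low[1],
            "intercept_high": self.beta_high[0],
            "slope_high": self.beta_high[1],
            "n_low": self.n_low,
            "n_high": self.n_high,
            "ssr": self.ssr,
            "sigma2_hat": self.sigma2_hat,
            "r2_low": self.r2_low,
            "r2_high": self.r2_high,
            "ssr_null": self.baseline.ssr_null,
            "r2_null": self.baseline.r2,
            "ci_low": None if self.ci_gamma is None else self.ci_gamma["low"],
            "ci_high": None if self.ci_gamma is None else self.ci_gamma["high"],
            "ci_contiguous": (None if self.ci_gamma is None
                              else self.ci_gamma["contiguous"]),
            "sup_stat": self.sup_stat,
            "boot_p": self.boot_p,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# data plumbing

def _frame(data) -> pd.DataFrame:
    if isinstance(data, Dataset):
        return data.frame
    return data


def _arrays(data, spec: ThresholdSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frame = _frame(data)
    cols = list(dict.fromkeys([spec.response, spec.predictor, spec.threshold_var]))
    sub = complete_cases(frame, cols)
    y = sub[spec.response].to_numpy(dtype=float)
    x = sub[spec.predictor].to_numpy(dtype=float)
    q = sub[spec.threshold_var].to_numpy(dtype=float)
    return y, x, q


# ---------------------------------------------------------------------------
# grid

def build_grid(q, spec: ThresholdSpec) -> np.ndarray:
    """Admissible candidate thresholds for the concentrated search.

    Candidates are the sorted distinct observed values of q such that the
    split q <= gamma leaves both regimes with at least
    max(ceil(trim_fraction * n), min_regime_size) observations.  Ties go to
    the lower regime (q <= gamma).
    """
    q = np.asarray(q, dtype=float)
    n = q.size
    distinct = np.unique(q)
    if distinct.size < 2:
        raise DegenerateThresholdError(
            "threshold variable is constant; no admissible split"
        )
    n_min = max(math.ceil(spec.trim_fraction * n), spec.min_regime_size)
    q_sorted = np.sort(q)
    n_low = np.searchsorted(q_sorted, distinct, side="right")
    ok = (n_low >= n_min) & (n - n_low >= n_min)
    grid = distinct[ok]
    if grid.size == 0:
        raise DegenerateThresholdError(
            f"no admissible threshold candidate with both regimes >= {n_min} "
            f"observations (n = {n})"
        )
    return grid


# ---------------------------------------------------------------------------
# OLS primitives

def _ols(x: np.ndarray, y: np.ndarray, intercept: bool) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and SSR via lstsq (the reference route)."""
    if intercept:
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = x[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RegimeSingularityError(
            "singular regression design (constant predictor in a regime)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _regime_r2(x: np.ndarray, y: np.ndarray, ssr: float, intercept: bool) -> float:
    tss = float(((y - y.mean()) ** 2).sum()) if intercept else float(y @ y)
    if tss <= 0:
        return float("nan")
    return 1.0 - ssr / tss


def ssr_at(data, spec: ThresholdSpec, gamma: float) -> dict:
    """Concentrated SSR and regime coefficients at one candidate threshold.

    Two independent OLS fits on the q <= gamma and q > gamma subsets; this
    is the plain (non-vectorised) route and the reference the fast grid
    scan is tested against.
    """
    y, x, q = _arrays(data, spec)
    grid = build_grid(q, spec)
    if not np.any(np.isclose(grid, gamma)):
        raise ValueError(
            f"gamma = {gamma} is not an admissible candidate "
            f"(grid spans [{grid[0]}, {grid[-1]}])"
        )
    low = q <= gamma
    beta_low, ssr_low = _ols(x[low], y[low], spec.include_intercept)
    beta_high, ssr_high = _ols(x[~low], y[~low], spec.include_intercept)

    def _pad(b: np.ndarray) -> tuple[float, float]:
        return (float(b[0]), float(b[1])) if b.size == 2 else (0.0, float(b[0]))

    return {
        "ssr": ssr_low + ssr_high,
        "ssr_low": ssr_low,
        "ssr_high": ssr_high,
        "beta_low": _pad(beta_low),
        "beta_high": _pad(beta_high),
        "n_low": int(low.sum()),
        "n_high": int((~low).sum()),
    }


# ---------------------------------------------------------------------------
# fast scan: SSR over the whole grid from cumulative sufficient statistics

def _scan_ssr(
    x: np.ndarray,
    Y: np.ndarray,
    n_low: np.ndarray,
    intercept: bool,
) -> np.ndarray:
    """SSR of the two-regime split for each response row and each split size.

    Parameters
    ----------
    x : (n,) predictor sorted by the threshold variable.
    Y : (R, n) response rows sorted the same way.
    n_low : (K,) number of observations in the lower regime per candidate.

    Returns an (R, K) matrix; candidates whose split is singular in either
    regime get +inf.
    """
    n = x.size
    Y = np.atleast_2d(Y)
    if intercept:
        # centering changes no subset SSR but tames cancellation
        x = x - x.mean()
        Y = Y - Y.mean(axis=1, keepdims=True)
    cx = np.cumsum(x)
    cxx = np.cumsum(x * x)
    cY = np.cumsum(Y, axis=1)
    cYY = np.cumsum(Y * Y, axis=1)
    cXY = np.cumsum(x * Y, axis=1)
    i = n_low - 1  # prefix end index per candidate
    m1 = n_low.astype(float)
    m2 = (n - n_low).astype(float)
    scale_x = max(float(cxx[-1]), 1.0)

    def _side(sx, sxx, sy, syy, sxy, m):
        if intercept:
            vxx = sxx - sx * sx / m
            vxy = sxy - sx * sy / m
            vyy = syy - sy * sy / m
        else:
            vxx, vxy, vyy = sxx, sxy, syy
        singular = vxx <= _SINGULAR_REL * scale_x
        safe = np.where(singular, 1.0, vxx)
        ssr = vyy - vxy * vxy / safe
        ssr = np.where(singular, np.inf, np.maximum(ssr, 0.0))
        return ssr

    ssr_lo = _side(cx[i], cxx[i], cY[:, i], cYY[:, i], cXY[:, i], m1)
    ssr_hi = _side(cx[-1] - cx[i], cxx[-1] - cxx[i],
                   cY[:, -1:] - cY[:, i], cYY[:, -1:] - cYY[:, i],
                   cXY[:, -1:] - cXY[:, i], m2)
    return ssr_lo + ssr_hi


def _scan(y, x, q, spec: ThresholdSpec) -> tuple[np.ndarray, np.ndarray]:
    """Grid and S(gamma) over the grid for one response vector."""
    grid = build_grid(q, spec)
    order = np.argsort(q, kind="stable")
    xs, ys, qs = x[order], y[order], q[order]
    n_low = np.searchsorted(qs, grid, side="right")
    ssr = _scan_ssr(xs, ys[None, :], n_low, spec.include_intercept)[0]
    if not np.any(np.isfinite(ssr)):
        raise RegimeSingularityError(
            "predictor is constant within every admissible split"
        )
    return grid, ssr


# ---------------------------------------------------------------------------
# headline estimator

def fit_linear_baseline(data, spec: ThresholdSpec) -> LinearBaseline:
    """Single-regime OLS of response on predictor (the no-threshold null)."""
    y, x, _ = _arrays(data, spec)
    beta, ssr = _ols(x, y, spec.include_intercept)
    if spec.include_intercept:
        intercept, slope = float(beta[0]), float(beta[1])
    else:
        intercept, slope = 0.0, float(beta[0])
    return LinearBaseline(
        intercept=intercept, slope=slope,
        r2=_regime_r2(x, y, ssr, spec.include_intercept),
        ssr_null=ssr, n=y.size,
    )


def fit_threshold(data, spec: ThresholdSpec, alpha: float = 0.05) -> ThresholdFit:
    """Concentrated least-squares threshold fit.

    gamma_hat is the grid argmin of S(gamma) (ties broken toward the
    smallest candidate); regime coefficients, per-regime R-squared, the LR
    sequence and the LR-inversion confidence set at ``alpha`` are filled in.
    The bootstrap p-value is left to :func:`bootstrap_test`.  With a perfect
    fit (sigma2 = 0) the LR sequence and confidence set are left as None.
    """
    y, x, q = _arrays(data, spec)
    grid, ssr_grid = _scan(y, x, q, spec)
    k = int(np.argmin(ssr_grid))  # first minimum = smallest candidate
    gamma_hat = float(grid[k])

    at = ssr_at(data, spec, gamma_hat)
    baseline = fit_linear_baseline(data, spec)
    n = y.size
    ssr = at["ssr"]
    sigma2 = ssr / n

    low = q <= gamma_hat
    r2_low = _regime_r2(x[low], y[low], at["ssr_low"], spec.include_intercept)
    r2_high = _regime_r2(x[~low], y[~low], at["ssr_high"], spec.include_intercept)

    fit = ThresholdFit(
        spec=spec, gamma_hat=gamma_hat,
        beta_low=at["beta_low"], beta_high=at["beta_high"],
        n_low=at["n_low"], n_high=at["n_high"],
        ssr=ssr, sigma2_hat=sigma2, r2_low=r2_low, r2_high=r2_high,
        baseline=baseline, grid=grid, ssr_grid=ssr_grid,
        q_range=(float(q.min()), float(q.max())),
        q_distinct=np.unique(q),
    )
    y_scale = max(float(np.var(y)), float(np.mean(y * y)), 1.0)
    if sigma2 > _DEGENERATE_REL * y_scale:
        fit.lr_sequence = lr_sequence(fit)
        fit.ci_gamma = gamma_ci(fit, alpha)
        fit.sup_stat = (baseline.ssr_null - ssr) / sigma2
    return fit


def lr_sequence(fit: ThresholdFit) -> list[tuple[float, float]]:
    """LR(gamma) = n * (S(gamma) - S(gamma_hat)) / S(gamma_hat) over the grid.

    Equivalently (S(gamma) - S(gamma_hat)) / sigma2_hat with
    sigma2_hat = S(gamma_hat) / n.
    """
    n = fit.n
    s_hat = float(np.min(fit.ssr_grid))
    sigma2 = s_hat / n
    y_scale = max(abs(fit.baseline.ssr_null) / n, 1e-300)
    if sigma2 <= _DEGENERATE_REL * y_scale:
        raise DegenerateVarianceError(
            "residual variance is zero; LR sequence undefined"
        )
    lr = (fit.ssr_grid - s_hat) / sigma2
    lr = np.maximum(lr, 0.0)
    return [(float(g), float(v)) for g, v in zip(fit.grid, lr)]


def lr_critical_value(alpha: float) -> float:
    """c(alpha) = -2 ln(1 - sqrt(1 - alpha)) for LR inversion at the threshold."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    return -2.0 * math.log(1.0 - math.sqrt(1.0 - alpha))


def gamma_ci(fit: ThresholdFit, alpha: float = 0.05) -> dict:
    """Confidence set for gamma: candidates with LR(gamma) <= c(alpha).

    S(gamma) is piecewise constant between distinct observed values of the
    threshold variable, so each retained candidate gamma_k stands for the
    whole interval [gamma_k, next distinct q).  The set is reported as the
    hull [low, high] where ``high`` is the right edge of the last member's
    constancy interval, plus a contiguity flag; a disjoint set keeps
    ``contiguous`` False and the hull overstates it.
    """
    seq = fit.lr_sequence if fit.lr_sequence is not None else lr_sequence(fit)
    c = lr_critical_value(alpha)
    lr = np.array([v for _, v in seq])
    idx = np.flatnonzero(lr <= c)
    gammas = fit.grid[idx]
    top = float(gammas.max())
    distinct = fit.q_distinct if fit.q_distinct is not None else fit.grid
    above = distinct[distinct > top]
    high = float(above[0]) if above.size else top
    return {
        "alpha": alpha,
        "critical_value": c,
        "low": float(gammas.min()),
        "high": high,
        "contiguous": bool(idx.size == idx.max() - idx.min() + 1),
        "members": [float(g) for g in gammas],
    }


def bootstrap_test(
    data,
    spec: ThresholdSpec,
    n_boot: int = 499,
    seed: int | None = None,
) -> dict:
    """Residual-bootstrap test for the existence of a threshold.

    Observed statistic: sup-F = n * (SSR_null - S(gamma_hat)) / S(gamma_hat)
    = (SSR_null - S(gamma_hat)) / sigma2_hat.
    Null resamples keep the design (x, q) fixed and draw responses as the
    fitted single-regime values plus residuals resampled with replacement;
    each resample is re-scanned for its own sup-F.  p = (1 + m) / (B + 1)
    where m counts bootstrap statistics >= the observed one.
    """
    if n_boot < 99:
        raise ConfigurationError(f"n_boot must be >= 99, got {n_boot}")
    y, x, q = _arrays(data, spec)
    n = y.size
    grid = build_grid(q, spec)
    order = np.argsort(q, kind="stable")
    xs, ys, qs = x[order], y[order], q[order]
    n_low = np.searchsorted(qs, grid, side="right")

    beta, ssr_null = _ols(xs, ys, spec.include_intercept)
    ssr_grid = _scan_ssr(xs, ys[None, :], n_low, spec.include_intercept)[0]
    s_hat = float(np.min(ssr_grid))
    sigma2 = s_hat / n
    if sigma2 <= 0:
        raise DegenerateVarianceError("perfect fit; sup-F undefined")
    sup_stat = (ssr_null - s_hat) / sigma2

    if spec.include_intercept:
        fitted = beta[0] + beta[1] * xs
    else:
        fitted = beta[0] * xs
    resid = ys - fitted

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Yb = fitted[None, :] + resid[idx]

    ssr_b = _scan_ssr(xs, Yb, n_low, spec.include_intercept)
    s_min = np.min(ssr_b, axis=1)
    # per-replicate null SSR of the single-regime fit
    xc = xs - xs.mean() if spec.include_intercept else xs
    Yc = Yb - Yb.mean(axis=1, keepdims=True) if spec.include_intercept else Yb
    sxx = float(xc @ xc)
    sxy = Yc @ xc
    syy = np.einsum("ij,ij->i", Yc, Yc)
    ssr_null_b = np.maximum(syy - sxy * sxy / sxx, 0.0)
    f_b = (ssr_null_b - s_min) / np.maximum(s_min / n, 1e-300)

    m = int(np.sum(f_b >= sup_stat))
    return {
        "sup_stat": float(sup_stat),
        "boot_p": (1 + m) / (n_boot + 1),
        "n_boot": n_boot,
        "seed": seed,
    }


def predict(fit: ThresholdFit, x, q):
    """Piecewise prediction: regime-1 equation if q <= gamma_hat, else regime 2.

    Extrapolation outside the fitted range of the threshold variable is
    allowed (and logged at debug level), not an error.
    """
    x = np.asarray(x, dtype=float)
    q = np.asarray(q, dtype=float)
    lo, hi = fit.q_range
    if np.any((q < lo) | (q > hi)):
        logger.debug("predict called outside fitted q range [%g, %g]", lo, hi)
    a1, b1 = fit.beta_low
    a2, b2 = fit.beta_high
    out = np.where(q <= fit.gamma_hat, a1 + b1 * x, a2 + b2 * x)
    if out.ndim == 0:
        return float(out)
    return out


def fit_all(
    data,
    predictors: Sequence[str],
    threshold_vars: Sequence[str],
    response: str = "log_bcf",
    *,
    trim_fraction: float = 0.15,
    min_regime_size: int = 3,
    alpha: float = 0.05,
    n_boot: int = 499,
    seed: int | None = None,
) -> list[dict]:
    """One threshold fit per (predictor, threshold variable) combination.

    Combinations that fail (degenerate grid, singular regime, ...) are
    recorded with their error message and the batch continues; fits whose
    existence test is not significant are retained with their boot_p, so
    the caller sees the full cross.
    """
    results: list[dict] = []
    for i, pred in enumerate(predictors):
        for j, tvar in enumerate(threshold_vars):
            spec = ThresholdSpec(
                response=response, predictor=pred, threshold_var=tvar,
                trim_fraction=trim_fraction, min_regime_size=min_regime_size,
            )
            entry: dict = {"spec": spec, "fit": None, "error": None}
            try:
                fit = fit_threshold(data, spec, alpha=alpha)
                if not fit.degenerate_variance:
                    combo_seed = None if seed is None else seed + 1000 * i + j
                    boot = bootstrap_test(data, spec, n_boot=n_boot,
                                          seed=combo_seed)
                    fit.boot_p = boot["boot_p"]
                    fit.sup_stat = boot["sup_stat"]
                    fit.seed = combo_seed
                entry["fit"] = fit
            except Exception as exc:  # noqa: BLE001 - batch keeps going
                entry["error"] = f"{type(exc).__name__}: {exc}"
                logger.warning("fit (%s | %s) failed: %s", pred, tvar, exc)
            results.append(entry)
    return results


def models_frame(results: Iterable[dict], alpha: float = 0.05) -> pd.DataFrame:
    """Flatten fit_all output into one row per attempted combination."""
    rows = []
    for entry in results:
        if entry["fit"] is None:
            spec = entry["spec"]
            rows.append({
                "response": spec.response, "predictor": spec.predictor,
                "threshold_var": spec.threshold_var, "error": entry["error"],
            })
        else:
            row = entry["fit"].as_dict()
            row["error"] = None
            bp = row.get("boot_p")
            row["significant"] = bool(bp is not None and bp <= alpha)
            rows.append(row)
    return pd.DataFrame(rows)
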