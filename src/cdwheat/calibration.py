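"""Monte-Carlo calibration of the threshold estimator and existence test.

Three studies, each returning a tidy per-replicate frame so the analysis
drivers, the test suite and the acceptance script all consume the same
computation:

* :func:`oracle_check` — on small random two-regime datasets, the fast
  cumulative-statistics grid scan must reproduce an exhaustive brute-force
  search (two fresh least-squares fits per candidate) exactly.
* :func:`recovery_simulation` — with a planted threshold, the estimate
  should land within the local spacing of the candidate grid and the
  LR-inversion confidence set should cover the true threshold at least at
  its nominal rate.
* :func:`size_simulation` — under a single-regime null the bootstrap
  existence test should reject at close to its nominal level.

The recovery and size designs use a plain uniform threshold variable so the
grid spacing is homogeneous and the nominal properties are the only thing
being measured; the study-scale generator (:mod:`cdwheat.synthetic`) is
exercised separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .threshold import ThresholdSpec, bootstrap_test, build_grid, \
    fit_threshold, ssr_at

_SPEC = ThresholdSpec(response="y", predictor="x", threshold_var="q")


def _frame(y: np.ndarray, x: np.ndarray, q: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [str(i) for i in range(y.size)], "y": y, "x": x, "q": q,
    })


def brute_force_fit(frame: pd.DataFrame, spec: ThresholdSpec) -> tuple[float, float]:
    """Exhaustive candidate scan via per-candidate least squares.

    Independent oracle for :func:`cdwheat.threshold.fit_threshold`: every
    admissible candidate is refitted from scratch with
    :func:`cdwheat.threshold.ssr_at` and the argmin taken directly (first
    minimum, i.e. smallest candidate on ties).
    """
    q = frame[spec.threshold_var].to_numpy(dtype=float)
    grid = build_grid(q, spec)
    ssrs = np.array([ssr_at(frame, spec, g)["ssr"] for g in grid])
    k = int(np.argmin(ssrs))
    return float(grid[k]), float(ssrs[k])


def oracle_check(
    n_datasets: int = 50,
    seed: int = 0,
    n_range: tuple[int, int] = (12, 30),
) -> pd.DataFrame:
    """Fast scan vs brute force on small random two-regime datasets."""
    rows = []
    for rep in range(n_datasets):
        rng = np.random.default_rng([seed, rep])
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        q = rng.normal(0.0, 1.0, n)
        x = rng.normal(0.0, 1.0, n)
        y = np.where(q <= 0.0, 1.0 + 2.0 * x, -1.0 - x) + rng.normal(0, 0.5, n)
        frame = _frame(y, x, q)
        fit = fit_threshold(frame, _SPEC)
        g_brute, s_brute = brute_force_fit(frame, _SPEC)
        rows.append({
            "rep": rep, "n": n,
            "gamma_scan": fit.gamma_hat, "gamma_brute": g_brute,
            "ssr_scan": fit.ssr, "ssr_brute": s_brute,
            "agree": bool(
                fit.gamma_hat == g_brute
                and np.isclose(fit.ssr, s_brute, rtol=1e-9, atol=1e-12)
            ),
        })
    return pd.DataFrame(rows)


def recovery_simulation(
    n_reps: int = 200,
    n: int = 200,
    gamma_true: float = 5.0,
    slope_low: float = 1.0,
    slope_high: float = -1.0,
    noise_sd: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Threshold recovery and LR confidence-set coverage.

    DGP per replicate: q ~ U(0, 10), x = q, y = slope_low * x below the
    threshold and slope_high * x above (equal intercepts 0, so the slope
    gap is the whole signal), Gaussian noise.  ``local_spacing`` is the gap
    between the two observed q values bracketing the true threshold.
    """
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        q = rng.uniform(0.0, 10.0, n)
        x = q
        y = np.where(q <= gamma_true, slope_low * x, slope_high * x)
        y = y + rng.normal(0.0, noise_sd, n)
        fit = fit_threshold(_frame(y, x, q), _SPEC, alpha=alpha)
        qs = np.sort(q)
        i = int(np.searchsorted(qs, gamma_true))
        lo = qs[i - 1] if i > 0 else qs[0]
        hi = qs[i] if i < n else qs[-1]
        ci = fit.ci_gamma
        rows.append({
            "rep": rep, "gamma_hat": fit.gamma_hat,
            "abs_err": abs(fit.gamma_hat - gamma_true),
            "local_spacing": hi - lo,
            "ci_low": ci["low"], "ci_high": ci["high"],
            "covered": bool(ci["low"] <= gamma_true <= ci["high"]),
        })
    return pd.DataFrame(rows)


def size_simulation(
    n_reps: int = 300,
    n: int = 200,
    n_boot: int = 199,
    alpha: float = 0.05,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical size of the bootstrap existence test under the null.

    DGP per replicate: q ~ U(0, 10), x = q, y = 1 + 0.5 x + noise — one
    regime, no threshold.  Reports the bootstrap p-value per replicate.
    """
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        q = rng.uniform(0.0, 10.0, n)
        x = q
        y = 1.0 + 0.5 * x + rng.normal(0.0, noise_sd, n)
        boot = bootstrap_test(_frame(y, x, q), _SPEC, n_boot=n_boot,
                              seed=int(rng.integers(2**31)))
        rows.append({
            "rep": rep, "sup_stat": boot["sup_stat"],
            "boot_p": boot["boot_p"],
            "reject": bool(boot["boot_p"] <= alpha),
        })
    return pd.DataFrame(rows)
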