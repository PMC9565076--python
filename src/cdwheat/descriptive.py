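"""Descriptive layer: summary statistics, speciation, correlations, exceedance.

Conventions: sample standard deviation (n-1 denominator); CV = SD/mean x 100;
exceedance is strict (value > limit); Pearson significance is two-tailed from
the t distribution with n-2 degrees of freedom, starred at 0.05 / 0.01.
Speciation percentages are taken over the fraction sum rather than total
soil Cd, so sequential-extraction recovery error cannot distort the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import FRACTION_COLUMNS, Dataset, complete_cases
from .errors import (
    InsufficientDataError,
    MissingColumnError,
    UndefinedCorrelationError,
)


@dataclass(frozen=True)
class SummaryStats:
    """Mean/SD/median/min/max/CV summary for one variable."""

    variable: str
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    cv: float  # percent

    def as_dict(self) -> dict:
        return {
            "variable": self.variable, "n": self.n, "mean": self.mean,
            "sd": self.sd, "median": self.median, "min": self.min,
            "max": self.max, "cv_percent": self.cv,
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between two variables with a two-tailed p and star flag."""

    var_x: str
    var_y: str
    r: float
    p_two_tailed: float
    n: int
    significance: str  # "", "*", or "**"

    def as_dict(self) -> dict:
        return {
            "var_x": self.var_x, "var_y": self.var_y, "r": self.r,
            "p_two_tailed": self.p_two_tailed, "n": self.n,
            "significance": self.significance,
        }


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, SD / mean x 100."""
    if mean == 0:
        raise InsufficientDataError("CV undefined for zero mean")
    return sd / mean * 100.0


def summarize(values, variable: str = "") -> SummaryStats:
    """Summary statistics with sample SD and CV in percent.

    Values are used at full precision; rounding is a presentation concern.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 observations to summarize {variable!r}, got {arr.size}"
        )
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return SummaryStats(
        variable=variable,
        n=int(arr.size),
        mean=mean,
        sd=sd,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        cv=cv_percent(mean, sd),
    )


def summary_table(dataset: Dataset, variables: Sequence[str]) -> pd.DataFrame:
    """One SummaryStats row per variable, in the order given."""
    rows = []
    for var in variables:
        if var not in dataset.frame.columns:
            raise MissingColumnError(f"variable {var!r} not in dataset")
        rows.append(summarize(dataset.frame[var].to_numpy(), var).as_dict())
    return pd.DataFrame(rows)


def exceedance(values, limit: float) -> dict:
    """Count and percent of values strictly above a regulatory limit."""
    if limit <= 0:
        raise ValueError(f"limit must be > 0, got {limit}")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError("exceedance of an empty vector is undefined")
    count = int((arr > limit).sum())
    return {"count": count, "n": int(arr.size),
            "percent": count / arr.size * 100.0}


def fraction_percentages(record: Mapping[str, float]) -> dict:
    """Tessier fraction percentages of the fraction sum, plus non-residual.

    The five operational fractions (exchangeable, carbonate-bound,
    Fe-Mn-oxide-bound, organic-bound, residual) are normalised by their own
    sum; non-residual percent = 100 - residual percent and proxies the
    mobile, plant-available pool.
    """
    missing = [c for c in FRACTION_COLUMNS
               if c not in record or pd.isna(record[c])]
    if missing:
        raise MissingColumnError(f"missing Tessier fraction(s): {missing}")
    vals = np.array([float(record[c]) for c in FRACTION_COLUMNS])
    total = vals.sum()
    if total <= 0:
        raise ValueError("fraction sum must be > 0")
    pct = vals / total * 100.0
    out = {f"{c}_percent": float(p) for c, p in zip(FRACTION_COLUMNS, pct)}
    out["nonresidual_percent"] = 100.0 - out["re_cd_percent"]
    return out


def fraction_table(dataset: Dataset) -> pd.DataFrame:
    """Per-sample speciation percentages for every record with fractions."""
    if not dataset.has_fractions:
        raise MissingColumnError(
            f"dataset lacks Tessier fraction columns {FRACTION_COLUMNS}"
        )
    rows = []
    for rec in dataset.frame.to_dict("records"):
        row = {"sample_id": rec["sample_id"], "soil_cd": rec["soil_cd"]}
        row.update(fraction_percentages(rec))
        rows.append(row)
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with two-tailed p (t distribution, n-2 df) on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        name = "x" if np.ptp(x) == 0 else "y"
        raise UndefinedCorrelationError(
            f"variable {name!r} has zero variance; correlation undefined"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    dataset: Dataset,
    pairs: Iterable[tuple[str, str]],
) -> list[CorrelationResult]:
    """Pearson correlations for the requested (x, y) pairs.

    Each pair is computed on its own complete cases (rows missing either
    variable are dropped for that pair only).
    """
    results = []
    for var_x, var_y in pairs:
        sub = complete_cases(dataset.frame, [var_x, var_y])
        try:
            r, p, n = pearson(sub[var_x].to_numpy(), sub[var_y].to_numpy())
        except UndefinedCorrelationError as exc:
            raise UndefinedCorrelationError(
                f"pair ({var_x}, {var_y}): {exc}"
            ) from exc
        results.append(CorrelationResult(
            var_x=var_x, var_y=var_y, r=r, p_two_tailed=p, n=n,
            significance=_stars(p),
        ))
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
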