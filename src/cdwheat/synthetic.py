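"""Synthetic soil-wheat datasets with the structure the analysis assumes.

The generator emulates a small topsoil/wheat-grain survey on carbonate-rich
alluvial soil: right-skewed total soil Cd and Zn (lognormal), near-normal pH
and organic matter within narrow ranges, a clay/silt/sand split summing to
100, Tessier Cd fractions drawn on the simplex around the typical ordering
residual > carbonate > Fe-Mn oxide > exchangeable > organic, and a log10
bioconcentration-factor response that is piecewise linear in a chosen
predictor with the regime split on a threshold variable (two_regime mode) or
a single line (null_linear mode, the no-threshold null used for size
checks).  Grain Cd is back-computed as soil_cd * 10**log_bcf so the derived
columns of :mod:`cdwheat.data_io` reproduce the planted response exactly.

Default parameter values are the study-scale conditions: n = 22, marginal
moments and ranges of a 22-sample survey, and a pH-threshold response at
gamma = 7.98 with regime slopes +0.292 / -0.615.

Every draw is reproducible from one integer seed; each variable has its own
deterministic substream, so adding a variable to the schema does not shift
the draws of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .data_io import Dataset, add_derived_columns
from .errors import ConfigurationError

import pandas as pd


@dataclass(frozen=True)
class Marginal:
    """One variable's marginal law: (truncated) normal or lognormal.

    ``mean`` and ``sd`` are the arithmetic moments being targeted (for the
    lognormal they parameterise the untruncated law; truncation shifts the
    realised moments slightly).
    """

    family: str  # "normal" | "lognormal"
    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        if (self.lower is not None and self.upper is not None
                and not self.lower < self.upper):
            raise ConfigurationError(
                f"truncation bounds must be ordered, got [{self.lower}, {self.upper}]"
            )

    def _normal_params(self) -> tuple[float, float]:
        if self.family == "normal":
            return self.mean, self.sd
        if self.mean <= 0:
            raise ConfigurationError("lognormal needs a positive mean")
        s2 = np.log1p((self.sd / self.mean) ** 2)
        return float(np.log(self.mean) - s2 / 2.0), float(np.sqrt(s2))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF of the truncated law, evaluated by mapping the
        uniform draw into the untruncated CDF mass between the bounds."""
        mu, sigma = self._normal_params()
        log_space = self.family == "lognormal"
        lo, hi = self.lower, self.upper
        a = 0.0 if lo is None else stats.norm.cdf(
            (np.log(lo) if log_space else lo), mu, sigma)
        b = 1.0 if hi is None else stats.norm.cdf(
            (np.log(hi) if log_space else hi), mu, sigma)
        if not b > a:
            raise ConfigurationError(
                f"truncation [{lo}, {hi}] leaves no probability mass"
            )
        z = stats.norm.ppf(a + u * (b - a), mu, sigma)
        return np.exp(z) if log_space else z

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))


def default_marginals() -> dict[str, Marginal]:
    """Study-scale marginals (soil Cd and Zn right-skewed; the rest normal)."""
    return {
        "soil_cd": Marginal("lognormal", 2.99, 2.67, 0.42, 11.21),
        "ph": Marginal("normal", 7.88, 0.38, 6.82, 8.78),
        "om": Marginal("normal", 3.02, 0.56, 2.26, 4.08),
        "caco3": Marginal("normal", 67.86, 18.79, 43.32, 106.07),
        "clay": Marginal("normal", 1.20, 0.39, 0.50, 2.50),
        "silt": Marginal("normal", 67.80, 7.14, 50.0, 80.0),
        "ca": Marginal("normal", 31.78, 6.10, 22.52, 42.93),
        "fe": Marginal("normal", 30.11, 2.87, 26.17, 38.14),
        "mn": Marginal("normal", 0.57, 0.05, 0.50, 0.72),
        "p": Marginal("normal", 1.23, 0.26, 0.93, 1.77),
        "zn": Marginal("lognormal", 488.44, 836.58, 110.64, 4057.14),
    }


#: Fixed substream index per draw; append-only so seeds stay stable.
_STREAMS: dict[str, int] = {
    "soil_cd": 0, "ph": 1, "om": 2, "caco3": 3, "clay": 4, "silt": 5,
    "ca": 6, "fe": 7, "mn": 8, "p": 9, "zn": 10,
    "fractions": 11, "recovery": 12, "noise": 13,
}

#: Mean Tessier fraction shares (ex, ca, fm, or, re) of extractable Cd.
_FRACTION_SHARES = np.array([0.13, 0.30, 0.15, 0.04, 0.38])
_FRACTION_NAMES = ("ex_cd", "ca_cd", "fm_cd", "or_cd", "re_cd")


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating parameters.

    ``regime_mode``: ``two_regime`` plants a threshold at ``gamma_true`` in
    ``threshold_var`` with regime coefficients ``beta_low`` / ``beta_high``
    (each (intercept, slope) on the predictor); ``null_linear`` applies
    ``beta_low`` everywhere (beta_high is ignored).  ``predictor`` defaults
    to the threshold variable itself.
    """

    n: int = 22
    seed: int = 0
    threshold_var: str = "ph"
    predictor: str | None = None
    gamma_true: float = 7.98
    beta_low: tuple[float, float] = (-3.337, 0.292)
    beta_high: tuple[float, float] = (4.186, -0.615)
    noise_sd: float = 0.15
    regime_mode: str = "two_regime"
    marginals: Mapping[str, Marginal] = field(default_factory=default_marginals)
    dirichlet_concentration: float = 200.0
    recovery_mean: float = 0.95
    recovery_sd: float = 0.04
    recovery_bounds: tuple[float, float] = (0.90, 1.05)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.regime_mode not in ("two_regime", "null_linear"):
            raise ConfigurationError(
                f"regime_mode must be two_regime|null_linear, got {self.regime_mode!r}"
            )
        if self.regime_mode == "two_regime":
            m = self.marginals.get(self.threshold_var)
            if m is not None and m.lower is not None and m.upper is not None:
                if not m.lower < self.gamma_true < m.upper:
                    raise ConfigurationError(
                        f"gamma_true {self.gamma_true} outside the support "
                        f"[{m.lower}, {m.upper}] of {self.threshold_var!r}"
                    )

    @property
    def predictor_name(self) -> str:
        return self.predictor or self.threshold_var

    def describe(self) -> str:
        d = asdict(self)
        d["marginals"] = {k: asdict(v) for k, v in self.marginals.items()}
        return json.dumps(d, sort_keys=True, default=str)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def generate(config: SyntheticConfig) -> Dataset:
    """Draw one synthetic dataset; fully reproducible from ``config.seed``."""
    n = config.n
    cols: dict[str, np.ndarray] = {}
    for name in ("soil_cd", "ph", "om", "caco3", "clay", "silt",
                 "ca", "fe", "mn", "p", "zn"):
        marg = config.marginals.get(name)
        if marg is None:
            raise ConfigurationError(f"no marginal configured for {name!r}")
        cols[name] = marg.sample(n, _rng(config.seed, name))
    # sand closes the texture composition to exactly 100
    cols["sand"] = 100.0 - cols["clay"] - cols["silt"]
    if np.any(cols["sand"] <= 0):
        raise ConfigurationError("clay + silt draws exceed 100%; narrow bounds")

    # Tessier fractions: simplex draw around the mean shares, scaled by an
    # imperfect sequential-extraction recovery of total soil Cd
    alpha = config.dirichlet_concentration * _FRACTION_SHARES
    shares = _rng(config.seed, "fractions").dirichlet(alpha, size=n)
    lo, hi = config.recovery_bounds
    rec_marg = Marginal("normal", config.recovery_mean, config.recovery_sd, lo, hi)
    recovery = rec_marg.sample(n, _rng(config.seed, "recovery"))
    extractable = cols["soil_cd"] * recovery
    for j, fname in enumerate(_FRACTION_NAMES):
        cols[fname] = extractable * shares[:, j]

    # response: log10(BCF) piecewise (or single) linear in the predictor
    pred_name = config.predictor_name
    if pred_name == "log_om":
        pred = np.log10(cols["om"])
    elif pred_name in cols:
        pred = cols[pred_name]
    else:
        raise ConfigurationError(f"unknown predictor {pred_name!r}")
    qvar = cols.get(config.threshold_var)
    if qvar is None:
        raise ConfigurationError(f"unknown threshold_var {config.threshold_var!r}")
    a1, b1 = config.beta_low
    if config.regime_mode == "two_regime":
        a2, b2 = config.beta_high
        log_bcf = np.where(qvar <= config.gamma_true,
                           a1 + b1 * pred, a2 + b2 * pred)
    else:
        log_bcf = a1 + b1 * pred
    if config.noise_sd > 0:
        log_bcf = log_bcf + _rng(config.seed, "noise").normal(
            0.0, config.noise_sd, size=n)
    cols["grain_cd"] = cols["soil_cd"] * 10.0 ** log_bcf

    frame = pd.DataFrame({"sample_id": [f"S{i + 1:02d}" for i in range(n)],
                          **cols})
    order = ["sample_id", "soil_cd", "grain_cd", "ph", "om", "caco3",
             "clay", "silt", "sand", "ca", "fe", "mn", "p", "zn",
             *_FRACTION_NAMES]
    ds = Dataset(frame=frame[order], provenance=config.describe())
    return add_derived_columns(ds)


def generate_null(config: SyntheticConfig) -> Dataset:
    """Single-regime dataset (beta_low everywhere): the no-threshold null."""
    return generate(replace(config, regime_mode="null_linear"))
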