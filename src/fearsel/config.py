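"""Simulation configuration and phenotype marginal distributions.

Phenotypes live on a percent-freezing scale (0-100).  The generator draws
latent Gaussian liabilities and maps them to the phenotype scale through a
configurable marginal distribution (Gaussian copula).  Marginals are specified
as plain dicts with a ``kind`` key so configurations round-trip through
YAML/JSON unchanged:

``{"kind": "identity"}``
    Phenotype equals the latent standard-normal liability (the "Gaussian
    scale" used for heritability-recovery experiments, where the generating
    h-squared is exactly the expected regression slope).

``{"kind": "beta", "a": ..., "b": ...}``
    Beta(a, b) stretched to [0, 100].  With a > b the mass concentrates near
    100 %, giving the negatively skewed post-acquisition freezing shape.

``{"kind": "normal_mixture", "means": [...], "sds": [...], "weights": [...]}``
    Mixture of normals truncated to [0, 100] and renormalized; two components
    reproduce the bimodal post-extinction shape seen in males, a dominant
    component plus a wide right component the right-tailed female shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from scipy import optimize, stats

import yaml


class ConfigError(ValueError):
    """Raised for invalid simulation or analysis configuration."""


# ---------------------------------------------------------------------------
# Marginal distributions
# ---------------------------------------------------------------------------


class Marginal:
    """A phenotype marginal exposing ``cdf`` and ``ppf`` on the percent scale."""

    def cdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def ppf(self, q):  # pragma: no cover - interface
        raise NotImplementedError


class IdentityMarginal(Marginal):
    """Phenotype equals the latent N(0,1) liability (no transform)."""

    def cdf(self, x):
        return stats.norm.cdf(x)

    def ppf(self, q):
        return stats.norm.ppf(q)


class BetaMarginal(Marginal):
    """Beta(a, b) scaled to [0, 100] percent."""

    def __init__(self, a: float, b: float):
        if a <= 0 or b <= 0:
            raise ConfigError(f"beta shape parameters must be positive, got a={a}, b={b}")
        self.a, self.b = float(a), float(b)
        self._dist = stats.beta(a, b, loc=0.0, scale=100.0)

    def cdf(self, x):
        return self._dist.cdf(x)

    def ppf(self, q):
        return self._dist.ppf(q)


class TruncatedNormalMixture(Marginal):
    """Mixture of normals truncated to [lo, hi] and renormalized.

    The quantile function is obtained by bisection on the monotone truncated
    CDF; vectorized over the input.
    """

    def __init__(self, means, sds, weights, lo: float = 0.0, hi: float = 100.0):
        means = np.asarray(means, float)
        sds = np.asarray(sds, float)
        weights = np.asarray(weights, float)
        if not (means.shape == sds.shape == weights.shape) or means.ndim != 1:
            raise ConfigError("means, sds, weights must be 1-D and of equal length")
        if np.any(sds <= 0):
            raise ConfigError("mixture component SDs must be positive")
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ConfigError("mixture weights must be non-negative and sum to 1")
        if not hi > lo:
            raise ConfigError("truncation bounds require hi > lo")
        self.means, self.sds, self.weights = means, sds, weights
        self.lo, self.hi = float(lo), float(hi)
        self._flo = self._raw_cdf(self.lo)
        self._fhi = self._raw_cdf(self.hi)
        if self._fhi - self._flo <= 0:
            raise ConfigError("mixture has no mass inside the truncation bounds")

    def _raw_cdf(self, x):
        x = np.asarray(x, float)[..., None]
        return np.sum(self.weights * stats.norm.cdf((x - self.means) / self.sds), axis=-1)

    def cdf(self, x):
        x = np.asarray(x, float)
        out = (self._raw_cdf(x) - self._flo) / (self._fhi - self._flo)
        return np.clip(out, 0.0, 1.0)

    def ppf(self, q):
        q = np.atleast_1d(np.asarray(q, float))
        target = self._flo + q * (self._fhi - self._flo)
        out = np.empty_like(q)
        for i, t in enumerate(target.ravel()):
            if t <= self._flo:
                out.ravel()[i] = self.lo
            elif t >= self._fhi:
                out.ravel()[i] = self.hi
            else:
                out.ravel()[i] = optimize.brentq(
                    lambda x, t=t: self._raw_cdf(x) - t, self.lo, self.hi, xtol=1e-10
                )
        return out if out.size > 1 else float(out[0])


def make_marginal(params: Mapping[str, Any]) -> Marginal:
    """Build a :class:`Marginal` from its dict specification."""
    kind = params.get("kind")
    if kind == "identity":
        return IdentityMarginal()
    if kind == "beta":
        return BetaMarginal(params["a"], params["b"])
    if kind == "normal_mixture":
        return TruncatedNormalMixture(
            params["means"], params["sds"], params["weights"],
            lo=params.get("lo", 0.0), hi=params.get("hi", 100.0),
        )
    raise ConfigError(f"unknown marginal kind: {kind!r}")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


def _default_acq_marginal() -> dict:
    # negatively skewed, mass piled toward maximal freezing
    return {"kind": "beta", "a": 6.0, "b": 1.5}


def _default_ext_marginal() -> dict:
    # per-sex: bimodal for males (modes near 22 % and near ceiling),
    # right-tailed unimodal for females centered near 35 %
    return {
        "M": {
            "kind": "normal_mixture",
            "means": [22.0, 100.0],
            "sds": [13.0, 12.0],
            "weights": [0.6, 0.4],
        },
        "F": {
            "kind": "normal_mixture",
            "means": [35.0, 80.0],
            "sds": [12.0, 18.0],
            "weights": [0.85, 0.15],
        },
    }


def _default_vocalizer_rates() -> dict:
    # incidence of 18-32 kHz (negative) and 32-96 kHz (positive) vocalizers
    # by line and sex, close to the observed first-generation incidences
    return {
        "negative_18_32": {
            "LE/M": 0.23, "LE/F": 0.08,
            "RB/M": 0.30, "RB/F": 0.11,
            "HE/M": 0.05, "HE/F": 0.04,
            "founder/M": 0.18, "founder/F": 0.08,
        },
        "positive_32_96": {
            "LE/M": 0.23, "LE/F": 0.32,
            "RB/M": 0.50, "RB/F": 0.42,
            "HE/M": 0.38, "HE/F": 0.22,
            "founder/M": 0.35, "founder/F": 0.30,
        },
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic selective-breeding experiment.

    Defaults emulate the study conditions: 50 founders per sex, moderate
    heritability of the post-extinction phenotype, litters culled to 12
    pups, 3 conditioning trials / 18 extinction trials / 3 recall trials,
    and a right-skewed shock-reactivity distribution with median 10 dB.
    """

    n_founder_males: int = 50
    n_founder_females: int = 50
    true_h2: float = 0.36
    #: latent correlation between acquisition and extinction liabilities;
    #: the magnitude is not an empirically anchored value
    acq_ext_latent_correlation: float = 0.5
    acq_marginal_params: dict = field(default_factory=_default_acq_marginal)
    ext_marginal_params: dict = field(default_factory=_default_ext_marginal)
    litter_size_distribution: dict = field(
        default_factory=lambda: {"kind": "truncated_poisson", "mean": 12.0, "min": 1}
    )
    cull_max: int = 12
    offspring_tested_per_litter: int = 8
    n_acquisition_trials: int = 3
    n_extinction_trials: int = 18
    n_recall_trials: int = 3
    trial_noise_sd: float = 8.0
    vocalizer_rates: dict = field(default_factory=_default_vocalizer_rates)
    calls_per_vocalizer_mean: float = 6.0
    shock_db_params: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median": 10.0, "sigma": 0.8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founder_males < 1 or self.n_founder_females < 1:
            raise ConfigError("founder counts must be >= 1")
        if not 0.0 <= self.true_h2 <= 1.0:
            raise ConfigError("true_h2 must lie in [0, 1]")
        if not -1.0 <= self.acq_ext_latent_correlation <= 1.0:
            raise ConfigError("acq_ext_latent_correlation must lie in [-1, 1]")
        if self.cull_max < 1:
            raise ConfigError("cull_max must be >= 1")
        if self.offspring_tested_per_litter < 0:
            raise ConfigError("offspring_tested_per_litter must be >= 0")
        if self.trial_noise_sd < 0:
            raise ConfigError("trial_noise_sd must be >= 0")
        for band, rates in self.vocalizer_rates.items():
            for cell, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"vocalizer rate {band}[{cell}] = {p} outside [0, 1]")
        # fail fast on malformed marginals
        make_marginal(self.acq_marginal_params)
        for m in self._ext_marginal_dicts().values():
            make_marginal(m)

    def _ext_marginal_dicts(self) -> dict:
        p = self.ext_marginal_params
        if "kind" in p:  # single marginal for both sexes
            return {"M": p, "F": p}
        if set(p) >= {"M", "F"}:
            return {"M": p["M"], "F": p["F"]}
        raise ConfigError("ext_marginal_params must be a marginal dict or {'M':..., 'F':...}")

    def acq_marginal(self) -> Marginal:
        return make_marginal(self.acq_marginal_params)

    def ext_marginal(self, sex: str) -> Marginal:
        return make_marginal(self._ext_marginal_dicts()[sex])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown SimConfig fields: {sorted(extra)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
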