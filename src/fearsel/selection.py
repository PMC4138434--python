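"""Cost-optimized choice of founder breeders for the selected lines.

Selecting for divergent extinction recall while holding acquisition constant
is a loss-gain tradeoff: the tighter the acquisition matching, the smaller
the available extinction divergence.  The tradeoff is formalized by a cost
over an acquisition cutoff theta (percent freezing after acquisition).
Subjects freezing below theta are filtered out; the remainder are ranked by
post-extinction freezing; the provisional low-extinguisher (LE) group is the
top k and the high-extinguisher (HE) group the bottom k; and the cost is

    J(theta) = (1 + (LE_acq - HE_acq)^2) / (LE_ext - HE_ext)^2

with group means in percent.  The +1 in the numerator keeps the cost
sensitive to the extinction-mean difference even when the acquisition means
match exactly.  ``sweep_theta`` evaluates J over an integer grid (default
1-85 %), per sex when stratified, and the final cutoff interval is the
intersection of the per-stratum optimal intervals (when one stratum's
interval encompasses the other's, the narrower interval wins).

The cutoff filter is inclusive (keep >= theta) during the sweep and strict
(keep > theta) for final founder selection; both sit behind the
``inclusive`` switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    theta_grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 86.0))
    k_per_sex: int = 10
    stratify_by_sex: bool = True
    rank_key: str = "post_ext_pct"
    acq_key: str = "post_acq_pct"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.theta_grid = np.asarray(self.theta_grid, float)
        if len(self.theta_grid) == 0:
            raise SelectionError("theta_grid must be non-empty")
        if np.any(np.diff(self.theta_grid) <= 0):
            raise SelectionError("theta_grid must be strictly increasing")
        if np.any((self.theta_grid <= 0) | (self.theta_grid >= 100)):
            raise SelectionError("theta_grid values must lie in (0, 100)")
        if self.k_per_sex < 1:
            raise SelectionError("k_per_sex must be >= 1")


@dataclass
class CostEvaluation:
    theta: float
    stratum: str
    feasible: bool
    le_acq_mean: float = np.nan
    he_acq_mean: float = np.nan
    le_ext_mean: float = np.nan
    he_ext_mean: float = np.nan
    cost: float = np.inf


@dataclass
class CostCurve:
    """J(theta) over the grid, with per-stratum and final optimal intervals."""

    evaluations: pd.DataFrame
    optimal_intervals: dict[str, list[float]]
    optimal_interval: list[float]

    @property
    def chosen_theta(self) -> float:
        return float(min(self.optimal_interval))


def _ranked_eligible(
    phenotypes: pd.DataFrame,
    theta: float,
    config: SelectionConfig,
    inclusive: bool,
    rng: np.random.Generator,
) -> pd.DataFrame:
    acq = phenotypes[config.acq_key]
    eligible = phenotypes[acq >= theta] if inclusive else phenotypes[acq > theta]
    # seeded random key breaks rank ties reproducibly
    tie = rng.random(len(eligible))
    order = np.lexsort((tie, -eligible[config.rank_key].to_numpy(float)))
    return eligible.iloc[order]


def selection_cost(
    theta: float,
    phenotypes: pd.DataFrame,
    config: SelectionConfig | None = None,
    inclusive: bool = True,
    stratum: str = "pooled",
) -> CostEvaluation:
    """Evaluate J(theta) on one stratum of scored subjects.

    Infeasible (infinite cost) when fewer than 2k subjects pass the filter or
    the provisional groups' extinction means coincide.
    """
    config = config or SelectionConfig()
    if len(phenotypes) == 0:
        raise SelectionError("empty phenotype set")
    rng = np.random.default_rng(config.rng_seed)
    ranked = _ranked_eligible(phenotypes, theta, config, inclusive, rng)
    k = config.k_per_sex
    if len(ranked) < 2 * k:
        return CostEvaluation(theta=theta, stratum=stratum, feasible=False)
    le, he = ranked.iloc[:k], ranked.iloc[-k:]
    le_acq = float(le[config.acq_key].mean())
    he_acq = float(he[config.acq_key].mean())
    le_ext = float(le[config.rank_key].mean())
    he_ext = float(he[config.rank_key].mean())
    denom = (le_ext - he_ext) ** 2
    if denom == 0.0:
        return CostEvaluation(theta=theta, stratum=stratum, feasible=False,
                              le_acq_mean=le_acq, he_acq_mean=he_acq,
                              le_ext_mean=le_ext, he_ext_mean=he_ext)
    cost = (1.0 + (le_acq - he_acq) ** 2) / denom
    return CostEvaluation(theta=theta, stratum=stratum, feasible=True,
                          le_acq_mean=le_acq, he_acq_mean=he_acq,
                          le_ext_mean=le_ext, he_ext_mean=he_ext, cost=cost)


def sweep_theta(
    phenotypes: pd.DataFrame,
    config: SelectionConfig | None = None,
    inclusive: bool = True,
) -> CostCurve:
    """Evaluate J over the cutoff grid and locate the optimal interval.

    With sex stratification (default), each sex gets its own curve and
    optimal interval (all feasible grid points attaining that stratum's
    minimum cost); the final interval is their intersection.  If the
    intersection is empty — a configuration the encompassing rule does not
    cover — the narrowest stratum's interval is used, with a warning.
    """
    config = config or SelectionConfig()
    if config.stratify_by_sex and "sex" in phenotypes.columns:
        strata = {str(s): g for s, g in phenotypes.groupby("sex", sort=True)}
    else:
        strata = {"pooled": phenotypes}
    evals: list[CostEvaluation] = []
    optimal: dict[str, list[float]] = {}
    for name, group in strata.items():
        stratum_evals = [
            selection_cost(theta, group, config, inclusive=inclusive, stratum=name)
            for theta in config.theta_grid
        ]
        evals.extend(stratum_evals)
        costs = np.array([e.cost if e.feasible else np.inf for e in stratum_evals])
        if not np.isfinite(costs).any():
            raise SelectionError(f"no feasible cutoff in stratum {name!r}")
        best = costs.min()
        optimal[name] = [float(t) for t, c in zip(config.theta_grid, costs)
                         if np.isfinite(c) and np.isclose(c, best, rtol=1e-12, atol=0.0)]
    final = set(optimal[next(iter(optimal))])
    for interval in optimal.values():
        final &= set(interval)
    if not final:
        narrowest = min(optimal.values(), key=len)
        warnings.warn(
            "per-stratum optimal intervals are disjoint; "
            "falling back to the narrowest stratum's interval",
            stacklevel=2,
        )
        final = set(narrowest)
    table = pd.DataFrame([vars(e) for e in evals])
    return CostCurve(evaluations=table, optimal_intervals=optimal,
                     optimal_interval=sorted(final))


@dataclass
class BreederSet:
    """Founder assignments: LE/HE selected lines plus the random-bred line."""

    le: pd.DataFrame
    he: pd.DataFrame
    rb: pd.DataFrame | None = None

    def assignments(self) -> pd.DataFrame:
        parts = [self.le.assign(role="LE"), self.he.assign(role="HE")]
        if self.rb is not None:
            parts.append(self.rb.assign(role="RB"))
        return pd.concat(parts, ignore_index=True)[["id", "sex", "role"]]

    def selected_ids(self) -> set[str]:
        ids = set(self.le["id"]) | set(self.he["id"])
        if self.rb is not None:
            ids |= set(self.rb["id"])
        return ids


def select_breeders(
    phenotypes: pd.DataFrame,
    theta: float,
    config: SelectionConfig | None = None,
    inclusive: bool = False,
) -> BreederSet:
    """Choose the LE and HE founders at the chosen cutoff.

    Within each sex, subjects with post-acquisition freezing above theta
    (strictly, by default) are ranked by post-extinction freezing; the top k
    become LE founders, the bottom k HE founders.  Rank ties are broken by a
    seeded random draw (noted via a warning).
    """
    config = config or SelectionConfig()
    if config.stratify_by_sex and "sex" in phenotypes.columns:
        strata = {str(s): g for s, g in phenotypes.groupby("sex", sort=True)}
    else:
        strata = {"pooled": phenotypes}
    k = config.k_per_sex
    le_parts, he_parts = [], []
    for name, group in strata.items():
        rng = np.random.default_rng(config.rng_seed)
        ranked = _ranked_eligible(group, theta, config, inclusive, rng)
        if len(ranked) < 2 * k:
            raise SelectionError(
                f"stratum {name!r}: only {len(ranked)} subjects pass the "
                f"cutoff {theta}; need at least {2 * k}"
            )
        if ranked[config.rank_key].duplicated().any():
            warnings.warn(
                f"stratum {name!r}: rank ties broken by seeded random draw",
                stacklevel=2,
            )
        le_parts.append(ranked.iloc[:k])
        he_parts.append(ranked.iloc[-k:])
    return BreederSet(le=pd.concat(le_parts, ignore_index=True),
                      he=pd.concat(he_parts, ignore_index=True))


def select_random_line(
    phenotypes: pd.DataFrame,
    excluded: BreederSet,
    k_per_sex: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded uniform sample of k males and k females not already selected."""
    taken = excluded.selected_ids()
    pool = phenotypes[~phenotypes["id"].isin(taken)]
    rng = np.random.default_rng(seed)
    parts = []
    for sex, group in pool.groupby("sex", sort=True):
        if len(group) < k_per_sex:
            raise SelectionError(
                f"stratum {sex!r}: only {len(group)} unselected subjects; "
                f"need {k_per_sex}"
            )
        idx = rng.choice(len(group), size=k_per_sex, replace=False)
        parts.append(group.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)
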