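"""Narrow-sense heritability from weighted midparent-offspring regression.

The estimator is the classical quantitative-genetics chain: regress family
offspring means on midparent values, weighting each family to account for
unequal litter sizes and within-litter resemblance.  For family i with n_i
tested offspring,

    W_i = (n_i + n_i T) / (1 + n_i T),       T = (t - b^2 / 2) / (1 - t),

where b is the unweighted regression slope and t the intraclass correlation
of litter-mates from a one-way ANOVA of offspring values grouped by litter:

    t = (MSA - MSW) / (MSA + (n0 - 1) MSW),

with MSA/MSW the among/within-litter mean squares and the effective family
size

    n0 = n_bar - sum_i (n_i - n_bar)^2 / ((k - 1) N)

for k families totalling N offspring of average family size n_bar.  The
heritability estimate h2 is the slope of the weighted regression; because
the regressor is the midparent value (mean of both parents), the slope
estimates h2 directly rather than half of it.  The reported standard error
is the conventional weighted-least-squares slope SE and the p-value a slope
t-test on k - 2 degrees of freedom.

The weight formula's b is computed once from the unweighted fit — a single
pass, no iteration.  A negative T is accepted so long as every weight stays
positive; otherwise the computation fails loudly rather than clamping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class HeritabilityError(ValueError):
    pass


FAMILY_COLUMNS = ["family_id", "sire_value", "dam_value", "midparent",
                  "n_i", "offspring_mean", "offspring_values"]


def build_family_table(
    subjects: pd.DataFrame,
    phenotype_field: str = "post_ext_pct",
    tested_only: bool = True,
) -> pd.DataFrame:
    """One row per breeding pair with at least one scored, tested offspring.

    ``subjects`` must carry ``id``, ``sire``, ``dam`` (NA for founders) and
    the phenotype column for parents and offspring alike.  Offspring without
    a score are excluded with a warning stating the count; the family is
    kept with reduced n_i.
    """
    if phenotype_field not in subjects.columns:
        raise HeritabilityError(f"subjects table lacks column {phenotype_field!r}")
    values = subjects.set_index("id")[phenotype_field]
    offspring = subjects[subjects["sire"].notna() & subjects["dam"].notna()]
    if tested_only and "tested" in offspring.columns:
        offspring = offspring[offspring["tested"]]
    n_missing = int(offspring[phenotype_field].isna().sum())
    if n_missing:
        warnings.warn(
            f"excluding {n_missing} offspring without a {phenotype_field} score",
            stacklevel=2,
        )
        offspring = offspring[offspring[phenotype_field].notna()]
    rows = []
    for (sire, dam), group in offspring.groupby(["sire", "dam"], sort=True):
        for pid in (sire, dam):
            if pid not in values.index or pd.isna(values[pid]):
                raise HeritabilityError(f"parent {pid!r} lacks a {phenotype_field} score")
        vals = group[phenotype_field].to_numpy(float)
        litters = group["litter"].dropna().unique() if "litter" in group else []
        fam_id = str(litters[0]) if len(litters) == 1 else f"{sire}x{dam}"
        sv, dv = float(values[sire]), float(values[dam])
        rows.append({
            "family_id": fam_id, "sire_value": sv, "dam_value": dv,
            "midparent": (sv + dv) / 2.0, "n_i": len(vals),
            "offspring_mean": float(vals.mean()), "offspring_values": list(vals),
        })
    if not rows:
        raise HeritabilityError("no breeding pair with scored tested offspring")
    return pd.DataFrame(rows)[FAMILY_COLUMNS]


def effective_family_size(families: pd.DataFrame) -> float:
    """n0 = n_bar - sum (n_i - n_bar)^2 / ((k - 1) N)."""
    n = families["n_i"].to_numpy(float)
    k = len(n)
    if k < 2:
        raise HeritabilityError("effective family size requires at least 2 families")
    nbar, N = n.mean(), n.sum()
    return float(nbar - np.sum((n - nbar) ** 2) / ((k - 1) * N))


def intraclass_correlation(families: pd.DataFrame) -> tuple[float, float, float]:
    """(t, MSA, MSW) from the one-way ANOVA of offspring values by family."""
    groups = [np.asarray(v, float) for v in families["offspring_values"]]
    k = len(groups)
    if k < 2:
        raise HeritabilityError("intraclass correlation requires at least 2 families")
    n = np.array([len(g) for g in groups], float)
    N = n.sum()
    if N - k <= 0:
        raise HeritabilityError("all families are singletons; within-litter mean square undefined")
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    msa = float(np.sum(n * (means - grand) ** 2) / (k - 1))
    msw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups) / (N - k))
    if msa == 0.0 and msw == 0.0:
        raise HeritabilityError("offspring values are constant; intraclass correlation undefined")
    n0 = effective_family_size(families)
    t = (msa - msw) / (msa + (n0 - 1.0) * msw)
    return float(t), msa, msw


def family_weights(families: pd.DataFrame, b: float, t_icc: float) -> tuple[float, np.ndarray]:
    """(T, W_i) from the unweighted slope b and intraclass correlation t.

    A negative T means the within-family resemblance beyond the parental
    regression is estimated below zero; like a negative variance component
    it is set to zero (every weight then equals the family size) with a
    warning, so the estimate degrades to size-weighted regression rather
    than failing on noisy data.
    """
    if t_icc >= 1.0:
        raise HeritabilityError("intraclass correlation of 1 makes T infinite")
    T = (t_icc - 0.5 * b**2) / (1.0 - t_icc)
    if T < 0.0:
        warnings.warn(
            f"T = {T:.4g} < 0 (no residual family resemblance); "
            "clamping to 0 so weights equal family sizes"
        )
        T = 0.0
    n = families["n_i"].to_numpy(float)
    W = (n + n * T) / (1.0 + n * T)
    return float(T), W


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    p_value: float
    b: float
    t_icc: float
    msa: float
    msw: float
    n0: float
    n_bar: float
    k: int
    n_total: int
    T: float
    weights: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        d = {f: getattr(self, f) for f in
             ("h2", "se", "p_value", "b", "t_icc", "msa", "msw",
              "n0", "n_bar", "k", "n_total", "T")}
        return pd.DataFrame([d])


def estimate_heritability(families: pd.DataFrame) -> HeritabilityEstimate:
    """Full estimate from a family table (see :func:`build_family_table`)."""
    k = len(families)
    if k < 3:
        raise HeritabilityError("heritability estimation requires at least 3 families")
    x = families["midparent"].to_numpy(float)
    y = families["offspring_mean"].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise HeritabilityError("zero midparent variance; slope undefined")
    X = sm.add_constant(x)
    b = float(sm.OLS(y, X).fit().params[1])
    t_icc, msa, msw = intraclass_correlation(families)
    T, W = family_weights(families, b, t_icc)
    wls = sm.WLS(y, X, weights=W).fit()
    n = families["n_i"].to_numpy(float)
    return HeritabilityEstimate(
        h2=float(wls.params[1]),
        se=float(wls.bse[1]),
        p_value=float(wls.pvalues[1]),
        b=b, t_icc=t_icc, msa=msa, msw=msw,
        n0=effective_family_size(families),
        n_bar=float(n.mean()), k=k, n_total=int(n.sum()), T=T,
        weights=pd.Series(W, index=families["family_id"].to_numpy(), name="W_i"),
    )
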