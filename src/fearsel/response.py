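"""Response-to-selection tests and contingency-table statistics.

After one generation, the shift in phenotype incidence is assessed with
exact binomial tests against the founding population's expected incidence
(20 % by construction of the two-of-three typing rules): for the LE line,
the directional hypotheses that LE-type incidence rose and HE-type incidence
fell; the mirror for the HE line; two-sided tests for the random-bred
control.  Incidence associations (e.g. vocalizer counts by line and sex) use
the Pearson chi-square statistic with no continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fearsel.phenotyping import HE_TYPE, LE_TYPE


@dataclass
class BinomialTestResult:
    observed: int
    n: int
    p0: float
    alternative: str
    p_value: float

    @property
    def proportion(self) -> float:
        return self.observed / self.n

    @property
    def proportion_se(self) -> float:
        """Binomial standard error of the observed proportion."""
        p = self.proportion
        return float(np.sqrt(p * (1.0 - p) / self.n))


def exact_binomial_test(
    observed: int,
    n: int,
    p0: float,
    alternative: str = "two_sided",
) -> BinomialTestResult:
    """Exact binomial tail probability.

    ``greater``: P[X >= observed]; ``less``: P[X <= observed];
    ``two_sided``: minimum-likelihood method — the sum of all outcome
    probabilities no larger than that of the observed outcome.
    """
    if not (0 <= observed <= n) or n < 1:
        raise ValueError(f"need 0 <= observed <= n with n >= 1, got {observed}/{n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie strictly in (0, 1), got {p0}")
    dist = stats.binom(n, p0)
    if alternative == "greater":
        p = float(dist.sf(observed - 1))
    elif alternative == "less":
        p = float(dist.cdf(observed))
    elif alternative == "two_sided":
        pmf = dist.pmf(np.arange(n + 1))
        p = float(pmf[pmf <= pmf[observed] * (1.0 + 1e-12)].sum())
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return BinomialTestResult(observed=int(observed), n=int(n), p0=float(p0),
                              alternative=alternative, p_value=min(1.0, p))


def response_report(
    counts: pd.DataFrame,
    p0: float = 0.20,
) -> pd.DataFrame:
    """Directional binomial tests of phenotype incidence, per line.

    ``counts`` needs columns ``line``, ``n_tested``, ``n_LE_type``,
    ``n_HE_type``.  Selected lines get one-tailed tests in the selected
    direction (LE line: LE-type greater / HE-type less; HE line mirrored);
    any other line (e.g. RB) gets two-sided tests.  The observed proportion
    and its binomial standard error accompany every p-value.
    """
    alt = {
        "LE": {LE_TYPE: "greater", HE_TYPE: "less"},
        "HE": {LE_TYPE: "less", HE_TYPE: "greater"},
    }
    rows = []
    for _, r in counts.iterrows():
        line = str(r["line"])
        for ptype, col in ((LE_TYPE, "n_LE_type"), (HE_TYPE, "n_HE_type")):
            alternative = alt.get(line, {}).get(ptype, "two_sided")
            res = exact_binomial_test(int(r[col]), int(r["n_tested"]), p0, alternative)
            rows.append({
                "line": line, "phenotype": ptype, "observed": res.observed,
                "n": res.n, "proportion": res.proportion,
                "proportion_se": res.proportion_se, "p0": p0,
                "alternative": alternative, "p_value": res.p_value,
            })
    return pd.DataFrame(rows)


def litter_composition(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-litter percentages of LE-type and HE-type tested offspring.

    Returns one row per litter with the parents' line, the number of tested
    offspring, and ``pct_LE_type`` / ``pct_HE_type`` in [0, 100].  Litters
    with no tested offspring are excluded with a warning.
    """
    if "phenotype_type" not in subjects.columns:
        raise ValueError("subjects must carry phenotype_type; run score_subjects first")
    offspring = subjects[subjects["litter"].notna()]
    if "tested" in offspring.columns:
        n_empty = offspring.groupby("litter", observed=True)["tested"].sum().eq(0).sum()
        if n_empty:
            warnings.warn(f"excluding {int(n_empty)} litters with no tested offspring",
                          stacklevel=2)
        offspring = offspring[offspring["tested"]]
    rows = []
    for litter, g in offspring.groupby("litter", sort=True, observed=True):
        n = len(g)
        rows.append({
            "litter": litter,
            "line": g["line"].iloc[0] if "line" in g else pd.NA,
            "n_tested": n,
            "n_LE_type": int((g["phenotype_type"] == LE_TYPE).sum()),
            "n_HE_type": int((g["phenotype_type"] == HE_TYPE).sum()),
        })
    out = pd.DataFrame(rows)
    out["pct_LE_type"] = 100.0 * out["n_LE_type"] / out["n_tested"]
    out["pct_HE_type"] = 100.0 * out["n_HE_type"] / out["n_tested"]
    return out


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-square of independence, no continuity correction.

    ``table`` is any 2-D array-like (or DataFrame) of non-negative counts
    with at least 2 rows and 2 columns and no all-zero row or column.
    Expected counts come from the row/column margins; df = (r-1)(c-1).
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be 2-D with at least 2 rows and 2 columns")
    if np.any(obs < 0) or np.any(~np.isfinite(obs)):
        raise ValueError("counts must be finite and non-negative")
    total = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if total <= 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate margins: zero grand total or an all-zero row/column")
    expected = np.outer(row, col) / total
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return Chi2Result(statistic=statistic, df=df,
                      p_value=float(stats.chi2.sf(statistic, df)),
                      expected=expected)
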