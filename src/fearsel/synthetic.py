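"""Synthetic selective-breeding populations with known genetic ground truth.

The generator follows a liability/Gaussian-copula scheme.  Each subject
carries a latent extinction liability L = A + E with additive component
A ~ N(0, h2) and environmental component E ~ N(0, 1 - h2), so Var(L) = 1 and
the offspring-on-midparent regression of L has expected slope h2.  A latent
acquisition liability is correlated with L at a configurable rho.  Observable
phenotypes on the percent-freezing scale are obtained by pushing the latent
quantile through a configured marginal (inverse-CDF transform), which
reproduces the negatively skewed post-acquisition and bimodal/right-tailed
post-extinction distributions without disturbing the latent genetics.  On the
``identity`` marginal the phenotype *is* the latent liability ("Gaussian
scale"), the setting used for estimator-recovery experiments; the copula
transform is a distribution-shape device and distorts additive variance on
the transformed scale.

Breeding draws a litter size (truncated Poisson by default), assigns pup sex
by fair coin, and culls litters above ``cull_max`` by discarding pups from
the majority sex first, emulating culling to 12 pups at the most equal sex
ratio possible.  Offspring additive values follow the Mendelian-sampling
rule A = (A_sire + A_dam)/2 + N(0, h2/2).

Trial-level freezing is anchored to the subject's two phenotype scores: the
first three extinction trials have expectation equal to the post-acquisition
score, the recall trials equal the post-extinction score, and intermediate
extinction trials interpolate linearly, with bounded noise and clipping to
[0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fearsel.config import ConfigError, SimConfig
from fearsel.usv import BAND_GATES, CSSchedule

SUBJECT_COLUMNS = [
    "id", "sex", "line", "generation", "sire", "dam", "litter", "tested",
    "latent_A", "latent_ext", "latent_acq", "acq_score", "ext_score",
]


@dataclass
class SimPopulation:
    """A simulated cohort: subjects table plus optional derived tables.

    ``subjects`` carries identity, pedigree (sire/dam/litter; NA for
    founders), the hidden latent values, and the two phenotype scores.
    """

    subjects: pd.DataFrame
    trials: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None
    shock: pd.DataFrame | None = None
    schedules: dict = field(default_factory=dict)

    def merge(self, other: "SimPopulation") -> "SimPopulation":
        """Concatenate two cohorts (e.g. founders + one line's offspring)."""
        def cat(a, b):
            if a is None:
                return b
            if b is None:
                return a
            return pd.concat([a, b], ignore_index=True)
        return SimPopulation(
            subjects=cat(self.subjects, other.subjects),
            trials=cat(self.trials, other.trials),
            calls=cat(self.calls, other.calls),
            shock=cat(self.shock, other.shock),
            schedules={**self.schedules, **other.schedules},
        )


def _rng(config: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _phenotypes(config: SimConfig, sexes: np.ndarray, A: np.ndarray,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent liabilities and marginal-mapped phenotype scores."""
    n = len(A)
    e_sd = np.sqrt(max(0.0, 1.0 - config.true_h2))
    E = rng.normal(0.0, 1.0, size=n) * e_sd
    L = A + E
    rho = config.acq_ext_latent_correlation
    z_acq = rho * L + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(0.0, 1.0, size=n)
    acq_m = config.acq_marginal()
    acq = np.asarray(acq_m.ppf(stats.norm.cdf(z_acq)), float)
    ext = np.empty(n)
    for sex in ("M", "F"):
        mask = sexes == sex
        if mask.any():
            ext[mask] = np.asarray(
                config.ext_marginal(sex).ppf(stats.norm.cdf(L[mask])), float
            )
    return {"latent_A": A, "latent_ext": L, "latent_acq": z_acq,
            "acq_score": acq, "ext_score": ext}


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> SimPopulation:
    """Draw the founding population (generation 0, line ``founder``)."""
    rng = _rng(config, rng)
    n_m, n_f = config.n_founder_males, config.n_founder_females
    sexes = np.array(["M"] * n_m + ["F"] * n_f)
    A = rng.normal(0.0, 1.0, size=n_m + n_f) * np.sqrt(config.true_h2)
    ph = _phenotypes(config, sexes, A, rng)
    ids = [f"G0{sex}{i:03d}" for i, sex in enumerate(sexes, start=1)]
    subjects = pd.DataFrame({
        "id": ids, "sex": sexes, "line": "founder", "generation": 0,
        "sire": pd.NA, "dam": pd.NA, "litter": pd.NA, "tested": True, **ph,
    })[SUBJECT_COLUMNS]
    return SimPopulation(subjects=subjects)


def _draw_litter_size(config: SimConfig, rng: np.random.Generator) -> int:
    spec = config.litter_size_distribution
    kind = spec.get("kind")
    if kind == "fixed":
        return int(spec["size"])
    if kind == "truncated_poisson":
        lo = int(spec.get("min", 1))
        for _ in range(1000):
            size = int(rng.poisson(float(spec["mean"])))
            if size >= lo:
                return size
        raise ConfigError("litter-size rejection sampling failed; check parameters")
    raise ConfigError(f"unknown litter_size_distribution kind: {kind!r}")


def _cull(sexes: list[str], cull_max: int, rng: np.random.Generator) -> list[str]:
    """Discard pups from the majority sex first until at most cull_max remain."""
    sexes = list(sexes)
    while len(sexes) > cull_max:
        n_m = sexes.count("M")
        n_f = len(sexes) - n_m
        drop_sex = "M" if n_m > n_f else "F" if n_f > n_m else ("M" if rng.random() < 0.5 else "F")
        idx = [i for i, s in enumerate(sexes) if s == drop_sex]
        sexes.pop(int(rng.choice(idx)))
    return sexes


def simulate_breeding(
    population: SimPopulation,
    pairs: list[tuple[str, str]],
    config: SimConfig,
    line: str = "RB",
    generation: int = 1,
    rng: np.random.Generator | None = None,
) -> SimPopulation:
    """Produce one line's offspring cohort from (sire, dam) id pairs.

    Each pair yields one litter: size drawn from the configured distribution,
    culled to ``cull_max`` balancing sexes, offspring additive values from
    Mendelian sampling, and ``offspring_tested_per_litter`` pups flagged as
    phenotyped.  The returned population contains only the offspring; merge
    with the parents' population for a pedigree-closed cohort.
    """
    if len(pairs) == 0:
        raise ValueError("simulate_breeding requires at least one breeding pair")
    rng = _rng(config, rng)
    parents = population.subjects.set_index("id")
    rows = []
    for p, (sire, dam) in enumerate(pairs, start=1):
        for pid in (sire, dam):
            if pid not in parents.index:
                raise ValueError(f"parent {pid!r} not present in population")
        if parents.loc[sire, "sex"] != "M" or parents.loc[dam, "sex"] != "F":
            raise ValueError(f"pair ({sire}, {dam}) is not one male and one female")
        a_mid = 0.5 * (parents.loc[sire, "latent_A"] + parents.loc[dam, "latent_A"])
        size = _draw_litter_size(config, rng)
        sexes = _cull(list(rng.choice(["M", "F"], size=size)), config.cull_max, rng)
        litter = f"{line}-L{p:03d}"
        n = len(sexes)
        A = a_mid + rng.normal(0.0, 1.0, size=n) * np.sqrt(config.true_h2 / 2.0)
        ph = _phenotypes(config, np.array(sexes), A, rng)
        n_test = min(config.offspring_tested_per_litter, n)
        tested = np.zeros(n, dtype=bool)
        if n_test > 0:
            tested[rng.choice(n, size=n_test, replace=False)] = True
        for j in range(n):
            rows.append({
                "id": f"{litter}-{j + 1:02d}", "sex": sexes[j], "line": line,
                "generation": generation, "sire": sire, "dam": dam,
                "litter": litter, "tested": bool(tested[j]),
                **{k: v[j] for k, v in ph.items()},
            })
    subjects = pd.DataFrame(rows)[SUBJECT_COLUMNS]
    return SimPopulation(subjects=subjects)


def simulate_trials(
    population: SimPopulation,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial-level freezing for every tested subject.

    Sessions: ``acquisition`` (expectation ramping up to the post-acquisition
    score across the conditioning trials), ``extinction`` (trials 1-3 at the
    post-acquisition score, then linear interpolation toward the
    post-extinction score), ``recall`` (at the post-extinction score).  Noise
    is Gaussian with SD ``trial_noise_sd``; values clipped to [0, 100].
    """
    if len(population.subjects) == 0:
        raise ValueError("population is empty")
    rng = _rng(config, rng)
    n_acq, n_ext, n_rec = (config.n_acquisition_trials, config.n_extinction_trials,
                           config.n_recall_trials)
    rows = []
    tested = population.subjects[population.subjects["tested"]]
    for _, s in tested.iterrows():
        acq, ext = float(s["acq_score"]), float(s["ext_score"])
        expect = []
        for j in range(1, n_acq + 1):
            expect.append(("acquisition", j, acq * j / n_acq))
        anchor = min(3, n_ext)
        for j in range(1, n_ext + 1):
            if j <= anchor:
                mu = acq
            else:
                mu = acq + (ext - acq) * (j - anchor) / (n_ext - anchor)
            expect.append(("extinction", j, mu))
        for j in range(1, n_rec + 1):
            expect.append(("recall", j, ext))
        noise = rng.normal(0.0, 1.0, size=len(expect)) * config.trial_noise_sd
        for (sess, j, mu), eps in zip(expect, noise):
            rows.append({"subject_id": s["id"], "session": sess, "trial_index": j,
                         "freezing_pct": float(np.clip(mu + eps, 0.0, 100.0))})
    trials = pd.DataFrame(rows)
    population.trials = trials
    return trials


def _make_schedule(n_tones: int, rng: np.random.Generator,
                   tone_s: float = 20.0, start_s: float = 120.0) -> CSSchedule:
    """Tone schedule with 20-s tones separated by a variable 1-3 min ITI."""
    onsets = [start_s]
    for _ in range(n_tones - 1):
        onsets.append(onsets[-1] + tone_s + rng.uniform(60.0, 180.0))
    return CSSchedule(onsets=np.array(onsets), tone_s=tone_s)


def simulate_usv(
    population: SimPopulation,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call tables and shock-reactivity values for tested subjects.

    Vocalizer status is Bernoulli per band with the configured line-by-sex
    rate; vocalizers emit calls whose frequency and duration respect the
    band gates, with onsets placed in the pre-CS/CS/post-CS windows of the
    session's tone schedule.  Shock-reactivity deltas are drawn from the
    configured right-skewed distribution (lognormal: strictly positive).
    """
    if len(population.subjects) == 0:
        raise ValueError("population is empty")
    rng = _rng(config, rng)
    schedules = {
        "acquisition": _make_schedule(config.n_acquisition_trials, rng),
        "extinction": _make_schedule(config.n_extinction_trials, rng),
    }
    tested = population.subjects[population.subjects["tested"]]
    call_rows, shock_rows = [], []
    for _, s in tested.iterrows():
        cell = f"{s['line']}/{s['sex']}"
        for band, rates in config.vocalizer_rates.items():
            if cell not in rates:
                raise ConfigError(f"no vocalizer rate for cell {cell!r} in band {band!r}")
            if rng.random() >= rates[cell]:
                continue
            flo, fhi, dlo, dhi = BAND_GATES[band]
            n_calls = 1 + int(rng.poisson(max(0.0, config.calls_per_vocalizer_mean - 1)))
            for _ in range(n_calls):
                sess = str(rng.choice(["acquisition", "extinction"]))
                sched = schedules[sess]
                tone = float(rng.choice(sched.onsets))
                w = rng.random()
                if w < 0.25:  # pre-CS
                    onset = tone - rng.uniform(0.0, sched.margin_s)
                elif w < 0.75:  # during CS
                    onset = tone + rng.uniform(0.0, sched.tone_s)
                else:  # post-CS
                    onset = tone + sched.tone_s + rng.uniform(0.0, sched.margin_s)
                call_rows.append({
                    "subject_id": s["id"], "session": sess,
                    "onset_s": round(max(0.0, onset), 3),
                    "duration_ms": round(rng.uniform(dlo, dhi), 1),
                    "peak_freq_khz": round(rng.uniform(flo, fhi - 1e-6), 2),
                    "peak_amp_db": round(rng.normal(62.0, 4.0), 1),
                })
        spec = config.shock_db_params
        if spec.get("kind") != "lognormal":
            raise ConfigError(f"unknown shock_db_params kind: {spec.get('kind')!r}")
        delta = float(rng.lognormal(np.log(float(spec["median"])), float(spec["sigma"])))
        before = float(rng.normal(55.0, 3.0))
        shock_rows.append({"subject_id": s["id"], "db_before": round(before, 2),
                           "db_after": round(before + delta, 2),
                           "delta_db": round(delta, 4)})
    calls = pd.DataFrame(
        call_rows,
        columns=["subject_id", "session", "onset_s", "duration_ms",
                 "peak_freq_khz", "peak_amp_db"],
    )
    shock = pd.DataFrame(
        shock_rows, columns=["subject_id", "db_before", "db_after", "delta_db"]
    )
    population.calls, population.shock = calls, shock
    population.schedules = schedules
    return calls, shock
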