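"""Generator contracts: determinism, pedigree, culling, marginal fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fearsel.config import ConfigError, SimConfig, make_marginal
from fearsel.heritability import HeritabilityError, build_family_table, estimate_heritability
from fearsel.phenotyping import classify_phenotype
from fearsel.pipeline import heritability_recovery
from fearsel.synthetic import (
    SimPopulation,
    simulate_breeding,
    simulate_founders,
    simulate_trials,
    simulate_usv,
)

FIG1_MIXTURE = {"kind": "normal_mixture", "means": [22.0, 100.0],
                "sds": [13.0, 12.0], "weights": [0.6, 0.4]}


def _full_run(seed):
    cfg = SimConfig(n_founder_males=6, n_founder_females=6, seed=seed,
                    offspring_tested_per_litter=4)
    rng = np.random.default_rng(cfg.seed)
    pop = simulate_founders(cfg, rng=rng)
    males = pop.subjects.loc[pop.subjects["sex"] == "M", "id"].tolist()
    females = pop.subjects.loc[pop.subjects["sex"] == "F", "id"].tolist()
    off = simulate_breeding(pop, list(zip(males, females)), cfg, line="LE", rng=rng)
    trials = simulate_trials(off, cfg, rng=rng)
    calls, shock = simulate_usv(off, cfg, rng=rng)
    return pop, off, trials, calls, shock


def test_identical_seed_gives_identical_tables():
    a = _full_run(7)
    b = _full_run(7)
    for x, y in zip(a, b):
        if isinstance(x, SimPopulation):
            pd.testing.assert_frame_equal(x.subjects, y.subjects)
        else:
            pd.testing.assert_frame_equal(x, y)


def test_different_seed_changes_phenotypes():
    a = _full_run(7)[0].subjects
    b = _full_run(8)[0].subjects
    assert not np.allclose(a["ext_score"], b["ext_score"])


def test_pedigree_closure_and_latents():
    pop, off, *_ = _full_run(1)
    merged = pop.merge(off).subjects
    ids = set(merged["id"])
    nonfounders = merged[merged["sire"].notna()]
    assert set(nonfounders["sire"]).issubset(ids)
    assert set(nonfounders["dam"]).issubset(ids)
    assert merged["latent_A"].notna().all()


def test_oversized_litters_culled_to_twelve_with_balanced_sexes():
    cfg = SimConfig(n_founder_males=3, n_founder_females=3, seed=0,
                    litter_size_distribution={"kind": "fixed", "size": 14},
                    cull_max=12)
    rng = np.random.default_rng(0)
    pop = simulate_founders(cfg, rng=rng)
    males = pop.subjects.loc[pop.subjects["sex"] == "M", "id"].tolist()
    females = pop.subjects.loc[pop.subjects["sex"] == "F", "id"].tolist()
    off = simulate_breeding(pop, list(zip(males, females)), cfg, rng=rng)
    sizes = off.subjects.groupby("litter")["id"].count()
    assert (sizes == 12).all()


def test_culling_discards_from_majority_sex_first(rng):
    from fearsel.synthetic import _cull

    # an 8/6 litter culled to 12 ends perfectly balanced
    culled = _cull(["M"] * 8 + ["F"] * 6, 12, rng)
    assert culled.count("M") == culled.count("F") == 6
    # a tied 7/7 litter stays tied after the cull
    culled = _cull(["M"] * 7 + ["F"] * 7, 12, rng)
    assert culled.count("M") == culled.count("F") == 6
    # a single-sex litter simply loses pups
    assert _cull(["M"] * 14, 12, rng) == ["M"] * 12
    # litters at or under the ceiling are untouched
    assert _cull(["M", "F", "F"], 12, rng) == ["M", "F", "F"]


def test_breeding_requires_parents_and_pairs():
    cfg = SimConfig(n_founder_males=2, n_founder_females=2, seed=0)
    pop = simulate_founders(cfg)
    with pytest.raises(ValueError, match="at least one breeding pair"):
        simulate_breeding(pop, [], cfg)
    with pytest.raises(ValueError, match="not present"):
        simulate_breeding(pop, [("nope", pop.subjects["id"].iloc[2])], cfg)
    m, f = pop.subjects["id"].iloc[0], pop.subjects["id"].iloc[2]
    with pytest.raises(ValueError, match="one male and one female"):
        simulate_breeding(pop, [(f, m)], cfg)


def test_untested_offspring_propagate_to_estimation_refusal(gauss_config):
    cfg = gauss_config(true_h2=0.4, n_families=1, n_tested=0, litter_size=4)
    rng = np.random.default_rng(0)
    pop = simulate_founders(cfg, rng=rng)
    pair = [(pop.subjects["id"].iloc[0], pop.subjects["id"].iloc[1])]
    off = simulate_breeding(pop, pair, cfg, rng=rng)
    assert not off.subjects["tested"].any()
    merged = pd.concat([pop.subjects, off.subjects], ignore_index=True)
    with pytest.raises(HeritabilityError):
        build_family_table(merged, "ext_score")


def test_zero_heritability_gives_zero_parent_offspring_slope(gauss_config):
    slopes = []
    for seed in range(40):
        cfg = gauss_config(true_h2=0.0, n_families=20, n_tested=6, seed=seed)
        rng = np.random.default_rng(seed)
        pop = simulate_founders(cfg, rng=rng)
        males = pop.subjects.loc[pop.subjects["sex"] == "M", "id"].tolist()
        females = pop.subjects.loc[pop.subjects["sex"] == "F", "id"].tolist()
        off = simulate_breeding(pop, list(zip(males, females)), cfg, rng=rng)
        merged = pd.concat([pop.subjects, off.subjects], ignore_index=True)
        fams = build_family_table(merged, "ext_score")
        slope = np.polyfit(fams["midparent"], fams["offspring_mean"], 1)[0]
        slopes.append(slope)
    assert abs(np.mean(slopes)) < 0.05


def test_founder_marginals_match_configured_distributions():
    """KS fidelity of the copula transform at n = 5000, alpha = 0.01."""
    cfg = SimConfig(n_founder_males=5000, n_founder_females=10, seed=42,
                    ext_marginal_params={"M": FIG1_MIXTURE, "F": FIG1_MIXTURE})
    pop = simulate_founders(cfg)
    males = pop.subjects[pop.subjects["sex"] == "M"]
    ext = make_marginal(FIG1_MIXTURE)
    assert stats.kstest(males["ext_score"], ext.cdf).pvalue > 0.01
    acq = make_marginal(cfg.acq_marginal_params)
    assert stats.kstest(males["acq_score"], acq.cdf).pvalue > 0.01
    assert males["acq_score"].between(0, 100).all()
    assert males["ext_score"].between(0, 100).all()
    # negative skew of the acquisition marginal survives the transform
    assert stats.skew(males["acq_score"]) < -0.5


def test_noiseless_trials_anchor_to_phenotype_scores():
    subjects = pd.DataFrame({
        "id": ["a", "b"], "sex": ["M", "F"], "line": "founder",
        "generation": 0, "sire": pd.NA, "dam": pd.NA, "litter": pd.NA,
        "tested": True, "latent_A": 0.0, "latent_ext": 0.0, "latent_acq": 0.0,
        "acq_score": [90.0, 80.0], "ext_score": [10.0, 95.0],
    })
    cfg = SimConfig(trial_noise_sd=0.0, seed=0)
    trials = simulate_trials(SimPopulation(subjects=subjects), cfg)
    for sid, acq, ext in (("a", 90.0, 10.0), ("b", 80.0, 95.0)):
        sub = trials[trials["subject_id"] == sid]
        first3 = sub[(sub["session"] == "extinction") & (sub["trial_index"] <= 3)]
        assert np.median(first3["freezing_pct"]) == acq
        recall = sub[sub["session"] == "recall"]
        assert np.median(recall["freezing_pct"]) == ext
    assert trials["freezing_pct"].between(0, 100).all()
    # a 10 % post-extinction subject shows robust extinction (HE type)
    assert classify_phenotype(trials[trials["subject_id"] == "a"]) == "HE_type"


def test_trial_values_clipped_with_noise():
    subjects = pd.DataFrame({
        "id": ["a"], "sex": ["M"], "line": "founder", "generation": 0,
        "sire": pd.NA, "dam": pd.NA, "litter": pd.NA, "tested": True,
        "latent_A": 0.0, "latent_ext": 0.0, "latent_acq": 0.0,
        "acq_score": [99.0], "ext_score": [1.0],
    })
    cfg = SimConfig(trial_noise_sd=40.0, seed=3)
    trials = simulate_trials(SimPopulation(subjects=subjects), cfg)
    assert trials["freezing_pct"].between(0, 100).all()


def test_recovery_of_generating_heritability(gauss_config):
    """Mean estimate over replicates recovers the generating value."""
    reps = heritability_recovery(true_h2=0.4, n_families=30, n_tested=8,
                                 n_replicates=120, seed=11)
    assert abs(reps["h2"].mean() - 0.4) < 0.05


def test_slope_converges_at_large_family_count(gauss_config):
    """With 200 families the mean estimate sits within +/-0.05 of truth."""
    reps = heritability_recovery(true_h2=0.36, n_families=200, n_tested=8,
                                 n_replicates=100, seed=5)
    assert abs(reps["h2"].mean() - 0.36) < 0.05


def test_usv_generator_contracts():
    pop, off, trials, calls, shock = _full_run(2)
    # every generated call respects its band's gates by construction
    neg = calls[(calls["peak_freq_khz"] >= 18) & (calls["peak_freq_khz"] < 32)]
    assert neg["duration_ms"].between(300, 4000).all()
    pos = calls[(calls["peak_freq_khz"] >= 32) & (calls["peak_freq_khz"] < 96)]
    assert pos["duration_ms"].between(30, 50).all()
    assert len(neg) + len(pos) == len(calls)
    assert (shock["delta_db"] > 0).all()
    assert np.allclose(shock["db_after"] - shock["db_before"], shock["delta_db"],
                       atol=0.02)


def test_zero_vocalizer_rate_gives_empty_call_table():
    cfg = SimConfig(n_founder_males=5, n_founder_females=5, seed=0)
    cfg.vocalizer_rates = {band: {k: 0.0 for k in rates}
                           for band, rates in cfg.vocalizer_rates.items()}
    pop = simulate_founders(cfg)
    calls, shock = simulate_usv(pop, cfg)
    assert len(calls) == 0
    assert len(shock) == len(pop.subjects)


def test_missing_vocalizer_cell_is_a_config_error():
    cfg = SimConfig(n_founder_males=2, n_founder_females=2, seed=0)
    cfg.vocalizer_rates = {"negative_18_32": {"LE/M": 0.5}}
    pop = simulate_founders(cfg)
    with pytest.raises(ConfigError, match="founder/M"):
        simulate_usv(pop, cfg)


def test_shock_delta_median_matches_configuration():
    cfg = SimConfig(n_founder_males=500, n_founder_females=500, seed=9)
    pop = simulate_founders(cfg)
    _, shock = simulate_usv(pop, cfg)
    assert abs(np.median(shock["delta_db"]) - 10.0) < 1.5


def test_config_validation_rejects_bad_values():
    with pytest.raises(ConfigError):
        SimConfig(true_h2=1.2)
    with pytest.raises(ConfigError):
        SimConfig(cull_max=0)
    with pytest.raises(ConfigError):
        SimConfig(ext_marginal_params={"kind": "normal_mixture", "means": [0, 50],
                                       "sds": [10, 10], "weights": [0.7, 0.7]})
    with pytest.raises(ConfigError):
        SimConfig(vocalizer_rates={"negative_18_32": {"LE/M": 1.5}})
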