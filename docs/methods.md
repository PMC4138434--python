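# Methods note

This note records the generative model behind `fearsel.synthetic`, the
default parameters and their rationale, what the generator does and does not
emulate, and the numerical choices made in the estimators.

## Generative model

### Latent genetics and phenotype marginals

Each founder carries an extinction liability `L_ext = A + E` with additive
value `A ~ N(0, h²)` and environment `E ~ N(0, 1 − h²)`, so `Var(L_ext) = 1`
and the generating narrow-sense heritability on the liability scale is
exactly `true_h2` (default 0.36). An acquisition liability is drawn jointly
Gaussian with `L_ext` at correlation `acq_ext_latent_correlation`
(default 0.5): good acquirers tend to hold fear longer, which is what makes
the acquisition-cutoff confound worth optimizing away.

Observable percent-freezing scores come from a Gaussian copula: the score is
`marginal.ppf(Φ(L))`, so the score follows the configured marginal
distribution exactly while inheriting the familial correlation structure of
the liabilities. Default marginals:

- acquisition: Beta(6, 1.5) scaled to 0–100 — most subjects acquire strongly;
- extinction, males: a two-component normal mixture (means 22 and 100, SDs
  13 and 12, weights 0.6/0.4) truncated and renormalized on [0, 100] —
  a bimodal population of fast extinguishers and non-extinguishers;
- extinction, females: a right-tailed mixture (means 35 and 80, SDs 12 and
  18, weights 0.85/0.15) on the same support.

Truncation is renormalized, not clipped, so there is no probability atom at
0 or 100 and the marginal admits a continuous CDF (used by the KS fidelity
tests). The mixture `ppf` is obtained by bracketing + `brentq` on the CDF.

The copula distorts additive variance on the transformed scale, so the
regression slope on percent-freezing scores need not equal `true_h2` under
non-identity marginals. Estimator-recovery tests therefore use the identity
marginal ("Gaussian scale"), where the expected midparent slope is `true_h2`
exactly.

### Trials

Trial-level scores interpolate the subject's endpoint scores: acquisition
trials ramp linearly up to the acquisition score; extinction trials 1–3 sit
at the acquisition score (so the post-acquisition median recovers it),
trials 4–18 interpolate linearly down to the extinction score; the 3 recall
trials sit at the extinction score. Independent Gaussian noise
(`trial_noise_sd`, default 8) is added and scores are clipped to [0, 100].

### Breeding

Chosen breeders are paired at random within line. Litter sizes are drawn
truncated-Poisson (mean 12, minimum 1); litters above `cull_max = 12` are
culled to 12, discarding from the majority sex first to keep sexes balanced.
Offspring additive values follow the infinitesimal model,
`A_off = ½(A_sire + A_dam) + N(0, h²/2)` (Mendelian-sampling variance for
unrelated, non-inbred parents), with a fresh environmental deviate. Eight
offspring per litter (`offspring_tested_per_litter`) are marked tested.

### Vocalizations and shock reactivity

Vocalizer status is Bernoulli per band with line-by-sex rates chosen close
to the bundled reference incidences; vocalizers emit `1 + Poisson(mean − 1)`
calls whose frequency/duration respect the band gates and whose onsets land
in the pre-CS/CS/post-CS windows of the session's tone schedule (first tone
at 120 s, 20 s tones, 1–3 min inter-trial intervals). Shock reactivity is a
strictly positive lognormal dB increase with median 10 and log-scale sigma
0.8, emulating the observed right-skewed 1–48 dB range.

### What the generator does not emulate

- no trial-order autocorrelation or within-session fatigue beyond the
  deterministic ramp; trial noise is i.i.d.;
- no maternal, litter-environment, dominance or epistatic effects — the
  full-sib covariance comes from additive values only, so `t ≈ h²/2`;
- no linkage or genotyping; genetics is purely infinitesimal;
- call acoustics are uniform within the band gates rather than clustered at
  the 22/50 kHz modes; amplitudes are decorative;
- vocalizer status is independent of the freezing phenotype (rates are fixed
  per line × sex cell), so line differences in incidence are built in rather
  than emergent.

## Defaults as study conditions

The `SimConfig` defaults encode the reference design: 50 + 50 founders
screened; 3/18/3 acquisition/extinction/recall trials; cutoff grid 1–85 %;
k = 10 breeders per sex per selected line; litters culled to 12 with 8
tested per litter (~30 families, ~240 tested offspring); type thresholds
75/25 % with 2-of-3 rules; founding type incidence p₀ = 0.20.

## Numerical and policy choices

- **Phenotype rules** are inclusive (≥/≤) at the 75/25 boundaries;
  non-robust acquirers are typed `non_robust` and excluded from the
  response-to-selection counts.
- **Cutoff sweep** uses an inclusive filter (≥ θ) so that J is a function of
  the grid value; the founder filter applied at selection time is strict
  (> θ), so the pipeline steps the chosen optimum down one grid unit before
  selecting. If the per-sex optimal intervals are disjoint, the narrowest
  stratum's interval is used (warned); if the resulting cutoff is infeasible
  for the other sex, it is relaxed down the grid until both strata can be
  filled (warned).
- **Rank ties** at selection are broken by a seeded random draw
  (`SelectionConfig.rng_seed`) and noted with a warning, keeping selection
  deterministic given the seed.
- **Intraclass correlation** uses the unequal-size effective family size
  n₀ = n̄ − Σ(nᵢ − n̄)² / ((k − 1)N); singleton-only or constant data raise
  rather than silently degenerate.
- **Negative T** (weights formula) is clamped to 0 with a warning, like a
  negative variance component: the weights reduce to family sizes instead of
  failing on noisy data. t ≥ 1 still raises (infinite T).
- **Weighted regression** is solved by `statsmodels` WLS with an intercept;
  the standard error and p-value come from the slope t-test on k − 2 df.
- **Exact binomial tests** sum the binomial PMF directly; the two-sided
  p-value is the minimum-likelihood convention (sum of all outcomes with
  PMF ≤ observed, with a 1 + 1e−12 relative tolerance against floating-point
  ties), matching `scipy.stats.binomtest`.
- **Pearson chi-square** uses no continuity correction: that is the form
  under which the bundled reference tables reproduce their published
  statistics. Expected counts come from the margins; degenerate margins
  raise.
- **USV band gates** are half-open in frequency at the 32 kHz boundary
  (18–32 kHz exclusive above; 32–96 kHz exclusive above) and closed in
  duration; CS windows are half-open `[start, end)` with the earlier tone
  winning on (warned) overlaps. Vocalizer status counts acquisition and
  extinction sessions only.
- **Reproducibility**: every simulation routine accepts a
  `numpy.random.Generator`; the pipeline threads a single generator seeded
  from `SimConfig.seed`. Replicate studies (`heritability_recovery`,
  `scripts/acceptance.py`) derive independent sub-seeds via
  `numpy.random.SeedSequence`, each reduced below 2³¹.

## Problem sizes

Replicate counts in the tests and the acceptance script (500 recovery
replicates, 1000-subject shock sample, 5000-subject KS fidelity samples) are
this package's own choices, sized so sampling error is comfortably below the
asserted tolerances while the whole suite runs in about a minute.
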