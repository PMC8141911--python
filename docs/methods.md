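# Methods

`vicfound` implements a demographic-inference pipeline for a two-population
system — an insect-pollinated Alpine forest-understory herb split into
western and eastern genetic groups is the motivating case — together with
the paleoclimate-downscaled species distribution model (SDM) used to
corroborate the inferred refugial history. This note records the models, the
numerical choices, and what the synthetic data can and cannot demonstrate.

## Scaled demographic units

All demographic quantities use diffusion units: population sizes `nu` are
relative to an ancestral reference size `N_ref`; times are in units of
`2 N_ref` generations; migration rates `m12`/`m21` are `2 N_ref` times the
fraction of deme 1 (resp. 2) replaced per generation by migrants from the
other deme, so a lineage in deme 1 traces its ancestry to deme 2 at rate
`m12` per scaled time unit. `theta = 4 N_ref mu` per site. Fitted parameters
are reported in these units and deliberately not converted to absolute sizes
or years; absolute dating is done separately (below) from an independent
coalescent estimate of the node age.

## The island model registry

Eight two-population "island" models are registered, generated by the grid
{vicariance, founder event} x {no migration, ancestral asymmetric migration}
x (founder only) {two-epoch expansion-then-constant, continuous exponential
growth}, plus two "recent founder" variants whose split time is bounded
inside 0.01 scaled time units. Three names follow the published usage
(`vic_no_mig`, `vic_anc_asym_mig`, `founder_anc_asym_two_epoch`); the other
five names and all event orders are reconstructions, flagged as such in the
registry (`ModelSpec.reconstructed`).

Event-order conventions (forward in time):

* All models start from an ancestral population of relative size `nuA`
  splitting into fractions `1 - s` (mainland, population 1) and `s` (island,
  population 2), with `s <= 0.5` by construction.
* **Vicariance**: the daughters spend the older epoch at the founding sizes
  `nuA (1-s)` / `nuA s` and the recent epoch at the present sizes
  `nu1` / `nu2`. In `vic_anc_asym_mig` the older epoch has duration `T1`
  with asymmetric migration (`m12`, `m21`) and the recent isolation epoch
  duration `T2`; in `vic_no_mig` the single duration `T` is split evenly
  between the two sub-epochs so that every reported parameter is
  genealogically active.
* **Founder**: the island is founded at `s * nuA` and grows exponentially to
  `nu2` — during the older epoch `T1` in the two-epoch variants (then
  constant), or over the whole divergence in the growth variants. The
  mainland stays at `nuA (1-s)` during the contact epoch and `nu1`
  afterwards. Migration, where present, is restricted to the older (contact)
  epoch.

Exponential growth is represented as a piecewise-constant discretization (16
geometric-midpoint steps per epoch). Both the in-package engine and the
msprime translation consume the identical discretized schedule, so the two
simulation routes agree exactly in the model they simulate and can be
cross-checked numerically.

## Expected spectra: Monte-Carlo branch-length engine

The expected joint site frequency spectrum (JSFS) for a model is computed by
coalescent Monte Carlo: a compiled (numba) Gillespie simulation of the
structured coalescent runs thousands of replicate genealogies and, for every
branch, accumulates its length into the cell indexed by the branch's
descendant counts in the two demes. The mean over replicates is the expected
branch length subtending each frequency class — proportional to the expected
SFS under infinite sites — with the mutation-rate scale left arbitrary
because the likelihood profiles it out.

Engine properties that matter downstream:

* **Determinism / common random numbers.** The generator is reseeded at
  every call (`EngineSettings.seed`), so repeated evaluations are
  bit-identical and nearby parameter values share random numbers, keeping
  the likelihood surface smooth enough for derivative-free optimization.
* **Precision.** With `n_reps` replicates the per-cell relative error decays
  as `n_reps^{-1/2}`; branch-length (rather than mutation-count)
  accumulation removes the Poisson mutation noise. Defaults: 20,000
  replicates for stand-alone use; the fitting protocol uses fewer during
  search and re-evaluates candidates at high precision (below).
* **Validation.** The engine is validated in the test suite against msprime
  branch-mode frequency spectra under asymmetric migration, against the
  `E[xi_i] = theta/i` neutral closed form, against the panmictic limit of a
  vanishing split time, and by exact schedule-level agreement of nested
  models.

## Spectrum algebra

Spectra are built from diploid genotype matrices with the standard RADseq
filters (genotypes below 5x depth set missing; sites with more than 50%
missing individuals dropped; optional one-SNP-per-locus thinning).
Down-projection to smaller haploid sizes uses the hypergeometric expectation
(fractional mass, not resampling); mass that becomes monomorphic lands in
the masked corner cells so conservation is auditable to 1e-12. Projection
sizes are chosen by maximizing the expected number of segregating sites
retained, ties broken toward larger samples. Ancestral states are treated as
unknown: all fitting uses folded spectra, where cell `(i, j)` is combined
with `(n1-i, n2-j)`, cells on the fold line keep half of the combined mass,
and the redundant half is masked.

The fit criterion is the Poisson form of the multinomial composite
likelihood: the model spectrum is rescaled by `theta_hat = sum(data) /
sum(model)` over unmasked cells (making the result invariant to model
normalization) and `sum(D ln lam - lam - ln D!)` is returned. `theta_hat` is
reported but never optimized, and is excluded from the parameter count `k`
used by AIC.

## Fitting protocol

Each model is fitted by multi-round perturbed restarts: the default protocol
runs rounds of 3-, 2-, 2- and 1-fold perturbations (`p * 2^U(-fold, fold)`)
with 10, 20, 30 and 60 replicates; round 1 scatters log-uniform probes over
the bounds and starts from the best few, later rounds perturb the incumbent
best. Each replicate is a bounded derivative-free search in log10-parameter
space — Nelder-Mead with an explicit ~2-fold initial simplex, alternating
with Powell's direction-set method, because the two stall differently on
ridged surfaces. Three further stabilizers address the Monte-Carlo nature of
the objective:

* the engine's random-number stream is refreshed each round, so a point that
  is only favored by one stream's noise does not survive;
* the first replicate of each round restarts unperturbed at the incumbent
  best with a fresh simplex;
* an optional final "polish" stage re-optimizes briefly at a much higher
  replicate count;
* the search-stage objective can be switched from the Poisson composite
  log-likelihood to the squared Hellinger distance between the data and the
  scaled model spectrum (`sum (sqrt(D) - sqrt(theta_hat M))^2`). The
  square-root transform stabilizes the Poisson variance per cell, so
  Monte-Carlo noise in near-empty model cells — which can make the
  log-likelihood of a genuinely good region evaluate as `-inf` or tens of
  units too low at low replicate counts — inflates the Hellinger objective
  by a nearly parameter-independent constant instead of distorting its
  ranking. Fits searched this way still report the Poisson log-likelihood
  of their final point, so they remain AIC-comparable.

Replicate seeds derive deterministically from `(master seed, round,
replicate)`, so a whole fit is reproducible bit-for-bit. Models are ranked
by `AIC = 2k - 2 logL`, `delta AIC`, and Akaike weights
`w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`.

For model comparisons in the acceptance suite, every candidate with a rich
(8-parameter) surface is fitted twice — once with the Poisson multiround
search and once with the Hellinger search from a screened scatter start —
because the two fail in different ways on noisy surfaces; the rich models
then mutually warm-start each other (identical treatment for both), and
every candidate point, including the untouched warm starts, is re-evaluated
at high engine precision before computing AIC, so the comparison is not
distorted by search-stage noise or by a refit drifting off a good start.

## Divergence-time calibration

A node age `tau`, expressed in expected substitutions per site, is converted
to absolute time by sampling substitution rates from a gamma density with
mean `7e-9` per site per generation and CV 0.10 (a "10% deviation"
interpreted as a gamma CV), optionally sampling the generation time `g` the
same way, and computing `t = tau * g / mu` per draw. The default generation
times are 5, 10 and 20 years. Because the mean averages `1/mu`
(inverse-gamma), it sits a factor `k/(k-1) = 100/99` above the plug-in
estimate `tau g / mu_mean` — visible in the third decimal of the headline
numbers. The reported 2.5%/97.5% quantiles integrate rate and
generation-time uncertainty only; they are narrower than credible intervals
that also propagate the posterior uncertainty of `tau` itself, which would
require the original posterior sample and is out of scope.

Note on conventions: the conversion uses `t_generations = tau / mu`. The
alternative `tau / (2 mu)` is sometimes quoted, but only the former
reproduces the published headline times from the printed `tau`; the package
follows the numerically consistent convention.

## Diversity statistics

Per population or group: called sites; percentage of polymorphic sites
(among sites with at least two called alleles); expected heterozygosity
`mean 2p(1-p)`; nucleotide diversity with the unbiased correction
`pi = mean n/(n-1) 2p(1-p)` over called alleles; and private alleles,
counted against the other units of the analysis (both the reference and the
alternate allele can be private). Group comparisons use a two-sided
Mann-Whitney U with midranks: the exact permutation distribution up to a
combined sample size of 12, the tie-corrected normal approximation beyond.

## Paleoclimate downscaling and the SDM

The delta method reconstructs fine-resolution historic climate in two steps:
(1) anomalies between a historic 30-year window and a reference window
(default 1950-1980) of the coarse simulated series are interpolated by an
exact thin plate spline (zero smoothing — affine fields reproduced exactly,
node values honored) and applied to the mid-resolution observational series;
(2) the resulting mid-resolution anomalies relative to a second reference
window (default 1979-2013) are interpolated onto the fine climatology.
Temperature anomalies are differences, precipitation anomalies ratios (a
zero-precipitation reference cell gets ratio 1 and a flag; negative
downscaled precipitation is clamped to 0 and flagged). Deltas are computed
and interpolated per month; bioclim summaries are derived only afterwards.

Bioclim conventions: bio1 = annual mean temperature; bio4 = population SD of
the 12 monthly mean temperatures x 100; bio12 = annual precipitation;
bio15 = 100 x SD/mean of monthly precipitation. Population (n-denominator)
standard deviations are used for bio4, bio15 and for topographic roughness
(SD of fine-cell elevations within each coarse cell). Collinearity screening
flags predictor pairs with Pearson |r| > 0.7.

The SDM is a binomial GLM with logit link, one linear and one quadratic term
per standardized predictor, fitted by IRLS to tolerance 1e-8; perfect
separation is caught and flagged with coefficients returned at the
iteration cap. Pseudo-absences are distinct cells drawn uniformly from the
domain minus exclusion masks. Refugial augmentation appends, for each
refugial area, the historic-climate cell with the highest occurrence
probability under the current model as one presence, regenerates
pseudo-absences half from historic and half from current climate (excluding
refugia, glaciated areas and the current distribution), and refits.

## Synthetic data

The genotype generator (`coalsim`) simulates independent non-recombining
RAD-like loci with msprime under the same demographic schedules as the model
registry, drops infinite-sites mutations (continuous coordinates mapped to
distinct integer positions; collisions re-drawn among free sites), pairs
consecutive haploid genomes into diploids, and can inject missing calls with
Poisson per-genotype depths so the depth and missingness filters are
exercised. Scenario defaults: the vicariance scenario uses the published
no-migration vicariance parameter estimates; the old-founder and
recent-founder scenarios use round mid-range values (island founded at
s = 0.1, halved present size, splits at 0.4 respectively 0.005 scaled time
units) chosen once as representative of the hypothesis each scenario
encodes. Climate/elevation generators produce seeded multi-resolution
monthly series with smooth spatial structure, a sinusoidal seasonal cycle
and small interannual noise.

What the synthetic data do **not** emulate: sequencing error, allele
dropout and paralogy (the raw-read and SNP-calling stages are out of scope);
linkage within loci; spatial autocorrelation structure of real climate
fields beyond smoothness; and observation bias in occurrence records.
Passing tests therefore demonstrate the correctness of the algorithms under
the stated models, not robustness to these real-data artifacts.

## Problem sizes in the test suite

The acceptance checks run at desk scale, chosen to finish comfortably on one
CPU: coalescent oracles at 1e5 replicates; model recovery on 20 seeded
datasets of ~1e4 SNPs at 14 + 12 haploids with the scaled-down two-round
protocol (2- and 1-fold perturbations, 5 and 10 replicates, 600-replicate
search engine, 60,000-replicate final evaluation); one-parameter recovery on
~1e4 SNPs at 12 haploids. The registry of demographic models, filters and
conversions carries no scale limits beyond memory.

## Known limitations

* The expected-SFS engine is Monte Carlo; likelihood values carry noise of a
  few units at search precision, which the protocol mitigates but does not
  remove. A deterministic diffusion/moments solver could be substituted
  behind `expected_sfs` without touching callers.
* Five of the eight registry models are name-and-structure reconstructions;
  analyses that depend on the precise event order of those variants should
  treat them as a model family, not as replicas of any published variant.
* Folded-spectrum fits leave some parameter combinations weakly identified
  (e.g., short-strong vs long-mild bottlenecks); the one-parameter recovery
  check deliberately uses an expansion history, whose folded signature is
  unambiguous.
* The divergence-time quantiles understate total uncertainty (no `tau`
  posterior).
* The SDM quadratic logit extrapolates poorly outside the training climate
  range, as all parametric SDMs do; predictions are clamped to [0, 1] by the
  link function but not otherwise safeguarded.
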