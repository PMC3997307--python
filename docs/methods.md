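# Methods

## The estimation problem

Apparent survival (φ) of adult birds is estimated from encounter
histories: per-bird binary detection vectors over annual August–July
capture occasions.  "Apparent" because death and permanent emigration are
confounded; both end a bird's availability for recapture.  Mist-netting
data from volunteer ringing schemes add two complications the pipeline is
built around: capture effort varies enormously across locations, and a
substantial fraction of captures are transients — birds netted once while
moving through that have effectively zero probability of local survival.
Ignoring transience biases survival downward, so the model separates
"settling" from "surviving".

## Data preparation

* **Effort.** A netting location is an exact coordinate pair; its effort
  is the number of distinct calendar dates with at least one capture over
  the study window.  Only locations with ≥ `min_effort_days` (default 24)
  enter the analysis.  Note this species-specific record file cannot
  recover an all-species ringing-day effort measure; distinct capture
  dates of the focal species are the implementable proxy, a documented
  limitation.
* **Pooling.** Records within `pooling_radius` (default 0.17 decimal
  degrees) of a high-effort location are assigned to the nearest one and
  then mapped through an explicit merge map onto pooled sites.  The
  radius is interpreted as a Chebyshev box (max of |Δlat|, |Δlon|),
  matching the "10 minutes south and east" reading of the radius;
  Euclidean distance is available behind a config switch.  Ties go to the
  lower site id.  Records outside all boxes are dropped and counted;
  pooling never creates records.
* **Occasions.** The occasion of a record is the Aug–Jul year containing
  its date; within-occasion repeats collapse to a single detection.
  Birds first captured at the final occasion are excluded — after
  conditioning on first capture they carry no likelihood information.
* **Migratory split.** A site is migratory iff its latitude is strictly
  south of `migratory_latitude` (default −26°); the boundary itself is
  sedentary, a documented tie-break for a threshold that is only "rough"
  in the underlying biology.
* **Age.** Only adult records are analysed; juvenile/unknown rows are
  dropped at read time with a logged count.

## Transience goodness of fit (3.SR)

For each occasion i, birds detected at i are cross-classified newly vs
previously marked × reencountered later vs never.  Each informative table
(no zero margin) contributes z_i = sign·√χ²_i, the signed root of the
Pearson statistic without continuity correction, positive when newly
marked birds are reencountered less than expected.  The pooled statistic
is Z = Σz_i/√M over the M informative tables, referred one-sided to
N(0,1).  Equal weighting of components is this package's documented
combination rule; results are reproducible across runs of this code but
not guaranteed numerically identical to other GOF software whose exact
weighting is unpublished.  Tables with a zero margin are skipped rather
than continuity-corrected, which keeps the null calibration cleanly
testable by simulation: under no transience the empirical null of Z is
indistinguishable from standard normal (KS over 1000 simulated datasets),
and the size of the α = 0.05 test sits inside the exact binomial 99%
interval over 500 null simulations.  The calibration scenario uses a
single site with detection probability 0.4 rather than the sparse 0.12 of
the survival analysis, chosen on expected-cell-count grounds so the 2×2
tables have informative margins; power against a 50% transient fraction
at 500 birds exceeds 0.9.

## Likelihood

The three-state model (Initial, Resident, Dead; matrices in the README)
is evaluated as an exact marginal likelihood by a forward recursion over
latent states, conditioning on first capture: probability 1 on Initial at
release, transition with φψ over the first interval and φ thereafter,
emission p/(1−p) for Residents and certain non-detection otherwise.  The
recursion normalizes at each step and accumulates log normalizers, so
long histories cannot underflow.  Marginalizing the states (rather than
sampling them, as a BUGS-family implementation would) makes the
likelihood deterministic, decouples the model from the sampler, and lets
brute-force path enumeration serve as an oracle: the test suite checks
agreement to relative 1e−10 over 1000 random parameter draws, exact
probability conservation over all detection patterns, and exact reduction
to the Cormack–Jolly–Seber m-array likelihood at ψ = 1.

The sampler uses an algebraically collapsed form of the same likelihood:
conditioned on first capture f and last capture l, a history factorises
into ψ, survival terms over [f, l), detection terms, and a
never-seen-after tail χ_l computed by a backward recursion, with
single-capture birds contributing (1−ψ) + ψχ̃_f.  Per-site count
statistics make one evaluation O(T) regardless of sample size; the
collapsed and forward likelihoods are tested to agree to machine
precision.

Dimension conventions: year effects ε index the T−1 intervals; recapture
effects γ index site × occasions 2…T.  Recapture at occasion 1 is
undefined (unidentifiable after conditioning on first capture).  No
losses on capture are modelled; every capture is a release.

## Inference

Priors: μ, β ~ U(−5,5); ψ_s ~ U(0,1); σ_space, σ_time, σ_γ ~ U(0,5);
η, ε, γ normal given their SDs.  Sampling is adaptive random-walk
Metropolis within Gibbs on an unconstrained parameterization (logit for
ψ, log for SDs, with the corresponding Jacobians).  Proposal scales adapt
toward ≈ 0.44 acceptance in batches of 50 iterations during burn-in only;
freezing adaptation afterwards preserves detailed balance of the retained
draws.  Three extra translation moves — joint shifts of (μ, η), (μ, ε)
and (β, γ) that leave the likelihood invariant — decorrelate the
intercepts from their centred random effects, a standard fix for the slow
mixing of centred hierarchical models; they are ordinary
Metropolis–Hastings moves and all scalar updates are retained.  SD
updates touch only the prior; site-local parameters re-evaluate only
their own site's likelihood.

Chains are initialized from prior draws (the uniform priors make these
overdispersed), with a bounded retry on a non-finite likelihood.  Each
chain's RNG stream derives from (seed, chain index), so runs are bitwise
reproducible.  Default settings are the scaled-down protocol 3 chains ×
20,000 iterations, burn-in 10,000, thinning 10; `McmcSettings.paper_scale()`
gives 3 × 100,000 / 50,000 / 20.  Convergence is monitored with the
classic Brooks–Gelman–Rubin PSRF (R̂ = √(((n−1)/n·W + B/n)/W)) computed
per parameter across chains, plus effective sample sizes.

Sampler correctness is established three ways: a reduced model (one site,
three occasions, ψ = 1, constant φ and p) agrees with a fine-grid numeric
posterior in the mean of φ to within 0.01; a fit with zero individuals
returns the priors (ψ centred on 0.5 within Monte Carlo error, SD
posteriors passing a KS test against U(0,5) on heavily thinned draws —
heavy thinning because the KS test assumes independent samples); and
parameter recovery at the default truths (below).

## Summaries

All derived quantities are computed per retained draw and only then
summarized with equal-tailed 95% percentile intervals (no HPD).
Probability-scale quantities are transformed per draw — never the inverse
logit of a posterior mean — so Jensen's gap is handled correctly.  Site
mean survival in a draw averages expit(μ + η_s + ε_t) over the study
intervals (a period average); group means are unweighted across member
sites.  The survival–latitude correlation (per draw, Pearson on the logit
scale across sites) is exploratory plumbing for inspecting the fitted
spatial pattern, not an estimate the underlying analysis defines.

Seasonality of a vegetation unit is scored APCV + MAT + MAFD and binned
low (< 50), intermediate ([50, 80)), high (≥ 80).  Applied to the bundled
published climate table, 12 of 16 units reproduce the published labels;
3 rows (KZN Highland Thornveld 56.5, Northern KZN Moist 59.2, Swartland
Shale 52.2) are labelled low in the source despite scores ≥ 50, and one
unit has missing covariates.  The package implements the stated rule and
reports the discrepancies rather than guessing the original intent (the
source's printed score range also cannot be reproduced from its own row
sums, suggesting unprinted precision in its APCV values; the one ">100"
APCV entry is encoded as 100, which reproduces the printed score maximum
of 117.0).

## Synthetic data

The generator is the package's study stand-in, with defaults at the
published posterior point estimates for this system: μ = logit(0.67),
σ_space = 0.70, σ_time = 1.08, β = logit(0.12), σ_γ = 1.21, and ψ_s
spanning 0.25–0.86 across sites; 16 sites over latitudes 21–34°S and 12
occasions at study scale.  Entrants arrive in equal per-occasion cohorts
over occasions 1…T−1 (the real entry schedule is unknown).  Latent states
evolve by the model's own transition matrix, so the generator and the
likelihood are two independent implementations of the same process — the
tests exploit this (detection-frequency checks against forward-computed
marginals, truth-beats-perturbation likelihood checks).

`simulate_records` writes dated, located captures: each detection becomes
1–3 records at the bird's fixed netting station (1–3 stations per site
within the pooling box of the centre), station effort is topped up to
clear the 24-day threshold using only already-detected bird-occasions,
and two kinds of contamination are planted — decoy locations whose effort
is exactly one day short of the threshold, and out-of-radius stray
records duplicating existing detections.  Preprocessing must remove both
without altering a single matrix entry, and the round-trip test asserts
exactly that.  The truth (parameters, effects, latent states) lives in a
sidecar object/file, never in the record file.

What the generator does not emulate: real SAFRING-style data have
unbalanced site sizes, within-season capture heterogeneity, age
misclassification, ring loss and spatially clustered effort.  Passing
tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to their violation.

## Problem sizes and numerical choices

Recovery tests and the acceptance run use 8 sites × 10 occasions × ~150
birds per site (17 entrants per site-occasion), ten replicates, with the
scaled-down MCMC protocol; this is the package's chosen benchmark design
in the published parameter regime, and at this size 95% CRIs cover the
true μ, σ_space and β in ≥ 8/10 replicates with R̂ < 1.1 throughout.
Tolerances: likelihood oracles at 1e−10 relative, CJS equivalence at
1e−8, grid-vs-sampler at 0.01 on the probability scale.  Degenerate
inputs are handled explicitly rather than raised through: impossible
histories return −∞ log-likelihood, zero-margin GOF tables are flagged
uninformative, a zero-variance R̂ is reported as degenerate, zero-data
fits are allowed (prior recovery), and draws with cross-site-constant
survival are excluded (and counted) from the latitude correlation.

## Known limitations

* Effort is measured from the focal species' records only.
* The 3.SR component weighting is this package's documented choice.
* The sampler is single-chain-sequential scalar Metropolis; it is fast
  because the likelihood is collapsed and compiled, but very large site
  counts would favour gradient-based samplers.
* ψ and p are nuisance parameters; with recapture near 0.12 their
  posteriors (and some site survivals) are wide — matching the sparse-data
  reality this design inhabits, not a defect of the implementation.
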