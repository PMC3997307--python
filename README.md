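# reedcmr

Hierarchical Bayesian multistate capture–mark–recapture (CMR) analysis of
apparent adult survival from bird-ringing records, built for the kind of
data a public ringing scheme produces: opportunistic mist-netting at many
sites, sparse recapture, and a sizeable fraction of transient birds that
are caught once while passing through.

The package takes raw capture records (ring id, date, coordinates, age),
applies the preparation rules of a multi-site ringing analysis — capture
effort per netting location, a 24-day effort filter, pooling of captures
within a 0.17-decimal-degree box of the high-effort locations, annual
August–July capture occasions, the 26°S migratory/sedentary split — tests
for transience, fits a three-state state-space model by MCMC, and derives
site-level and group-level survival with 95% credible intervals.

## The model

Newly captured birds start in an **Initial** state.  Over the first
interval a bird settles as a **Resident** with probability φψ (it must
survive, φ, *and* stay, ψ); otherwise it is absorbed in **Dead**, which
pools mortality with permanent emigration — including the transients.
Residents survive each year with φ and are recaptured with probability p:

```
            Initial    Resident   Dead                      seen   not seen
Initial   [   0          φψ      1−φψ ]        Initial    [  0        1   ]
Resident  [   0          φ       1−φ  ]        Resident   [  p       1−p  ]
Dead      [   0          0        1   ]        Dead       [  0        1   ]
```

Survival and recapture vary hierarchically on the logit scale,

```
logit(φ[s,t]) = μ + η[s] + ε[t],   η[s] ~ N(0, σ²_space),  ε[t] ~ N(0, σ²_time)
logit(p[s,t]) = β + γ[s,t],        γ[s,t] ~ N(0, σ²_γ)
```

with ψ[s] constant over time but free across sites.  Priors are
noninformative: U(−5,5) for μ and β, U(0,1) for each ψ[s], U(0,5) for the
standard deviations.  The likelihood of each encounter history
marginalizes the latent states exactly (forward algorithm), and sampling
is adaptive Metropolis-within-Gibbs with a compiled core; the
transience-aware goodness-of-fit test (the directional 3.SR z-test) checks
whether the Initial state is needed at all.

Because real multi-site ringing archives are typically not redistributable,
the package ships a first-class synthetic-data generator that emulates the
full regime — per-site cohorts, transients, logit-scale site and year
variation, mean recapture near 0.12 — and every claim the package makes is
tested against it (likelihood oracles, posterior-vs-grid checks, parameter
recovery, test calibration, pipeline round trips).

## Worked example

The `analysis/` scripts run the whole pipeline on a simulated study
(8 sites × 10 occasions × ~150 birds per site at the default truths):

```
python analysis/01_simulate_ringing_data.py --seed 1
python analysis/02_preprocess.py            --seed 1
python analysis/03_gof_transience.py
python analysis/04_fit_survival_model.py    --seed 1
python analysis/05_derived_summaries.py
```

Step 02 reports the preparation chain — `23 netting locations, 16 pass the
24-day effort filter`, `2822/2873 records pooled into 8 sites`, and a
lossless `round trip against simulated truth exact: True` (the dropped
records are the planted decoy locations and out-of-radius strays).  Step
03 prints the transience test on these data:

```
informative tables M = 8
Z = 3.3848
one-sided P = 0.000356136
-> transience detected; the three-state model is warranted
```

Z pools the per-occasion signed contrasts of newly vs previously marked
birds' reencounter rates; a small one-sided P says first-time captures are
reencountered less than residency alone can explain.  Step 04 fits the
model (3 chains × 20,000 iterations here; `--paper-scale` runs
3 × 100,000 / burn-in 50,000 / thinning 20) and prints the posterior next
to the generating truth:

```
parameter      post mean           95% CRI   R-hat    truth
phi_overall        0.797    (0.595, 0.972)   1.023    0.670
p_overall          0.087    (0.050, 0.132)   1.004    0.120
sigma_space        0.994    (0.145, 2.669)   1.005    0.700
sigma_time         0.792    (0.047, 2.905)   1.046    1.080
sigma_gamma        1.244    (0.850, 1.757)   1.002    1.210
max R-hat over all parameters: 1.046 (converged)
```

All truths fall inside their 95% CRIs; the wide intervals are the honest
price of ~12% recapture.  Step 05 writes the per-site survival table,
migratory/sedentary group means (here 0.744 vs 0.805), the exploratory
survival–latitude correlation (0.020, CRI −0.501 to 0.530 — a null
gradient, correctly straddling zero), and the seasonality scoring of the
bundled vegetation-unit climate table (12 units concordant with the
published low/intermediate/high labels, 3 discordant under the stated
additive rule, 1 undefined for missing covariates).

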