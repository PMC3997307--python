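"""Bayesian inference for the hierarchical three-state model.

Priors follow the noninformative choices of the analysis: U(-5, 5) for the
overall mean logit survival (mu) and recapture (beta), U(0, 1) for each
site's residence probability psi, U(0, 5) for the random-effect standard
deviations, with the site, year and site-by-occasion effects normally
distributed given their SDs.

Sampling is adaptive random-walk Metropolis within Gibbs on an
unconstrained parameterization (logit for psi, log for SDs), with proposal
scales tuned toward ~0.44 acceptance during burn-in only; adaptation is
frozen afterwards so the retained draws target the exact posterior.  Chains
are initialized from prior draws (uniform priors make these overdispersed)
and are bitwise reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from . import _kernels
from .cmr_model import ModelParameters
from .preprocess import EncounterHistoryMatrix
from .ringing_io import McmcSettings, PriorBounds

logger = logging.getLogger("reedcmr")


# ---------------------------------------------------------------------------
# Prior (natural scale, no transform Jacobians)
# ---------------------------------------------------------------------------

def log_prior(params: ModelParameters, bounds: PriorBounds | None = None) -> float:
    """Joint log prior density of a parameter set on the natural scale.

    Returns -inf outside the support, including the degenerate case of a
    zero SD with nonzero effects.
    """
    b = bounds or PriorBounds()
    lp = 0.0
    for x in (params.mu, params.beta):
        if not b.logit_mean_lo < x < b.logit_mean_hi:
            return -np.inf
        lp += -np.log(b.logit_mean_hi - b.logit_mean_lo)
    if ((params.psi <= 0) | (params.psi >= 1)).any():
        # boundary values have zero density under U(0,1)'s open interior
        if ((params.psi < 0) | (params.psi > 1)).any():
            return -np.inf
    for sigma, effects in (
        (params.sigma_space, params.eta),
        (params.sigma_time, params.eps),
        (params.sigma_gamma, params.gamma.ravel()),
    ):
        if not b.sd_lo <= sigma < b.sd_hi:
            return -np.inf
        lp += -np.log(b.sd_hi - b.sd_lo)
        if sigma == 0.0:
            if np.any(effects != 0.0):
                return -np.inf
        else:
            lp += norm.logpdf(effects, scale=sigma).sum()
    return float(lp)


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

def _suffstats(histories: EncounterHistoryMatrix, site_ids: np.ndarray, T: int):
    S = len(site_ids)
    n0 = np.zeros((S, T))
    R = np.zeros(S)
    Ssurv = np.zeros((S, T - 1))
    D = np.zeros((S, T))
    ND = np.zeros((S, T))
    L = np.zeros((S, T))
    pos = {sid: k for k, sid in enumerate(site_ids)}
    for i in range(histories.n_individuals):
        s = pos[histories.site_index[i]]
        det = histories.detections[i]
        caps = np.flatnonzero(det)
        f, l = caps[0], caps[-1]
        if l == f:
            n0[s, f] += 1
        else:
            R[s] += 1
            Ssurv[s, f:l] += 1
            for t in range(f + 1, l + 1):
                if det[t]:
                    D[s, t] += 1
                else:
                    ND[s, t] += 1
            L[s, l] += 1
    return n0, R, Ssurv, D, ND, L


def suffstat_total_loglik(histories: EncounterHistoryMatrix, params: ModelParameters) -> float:
    """Fast collapsed likelihood; must equal cmr_model.total_loglik."""
    site_ids = histories.site_ids
    T = histories.n_occasions
    n0, R, Ssurv, D, ND, L = _suffstats(histories, site_ids, T)
    phi = params.survival()
    p = params.recapture()
    total = 0.0
    for s in range(len(site_ids)):
        p_full = np.concatenate(([0.0], p[s]))
        total += _kernels.site_loglik(
            T, phi[s], p_full, float(params.psi[s]),
            n0[s], R[s], Ssurv[s], D[s], ND[s], L[s],
        )
    return float(total)


# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws: (chains, kept, parameters), natural scale."""

    draws: np.ndarray
    names: list[str]
    site_ids: np.ndarray
    n_occasions: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.site_ids = np.asarray(self.site_ids)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (chains, kept, parameters)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, kept)."""
        return self.draws[:, :, self.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        c, n, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * n, p), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(c), n))
        df.insert(1, "iteration", np.tile(np.arange(n), c))
        return df

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def parameter_names(site_ids, T: int) -> list[str]:
    I = T - 1
    names = ["mu", "beta", "sigma_space", "sigma_time", "sigma_gamma"]
    names += [f"eta[{sid}]" for sid in site_ids]
    names += [f"eps[{t + 1}]" for t in range(I)]
    names += [f"gamma[{sid},{t + 2}]" for sid in site_ids for t in range(I)]
    names += [f"psi[{sid}]" for sid in site_ids]
    return names


# ---------------------------------------------------------------------------
# Sampler driver
# ---------------------------------------------------------------------------

def run_mcmc(
    histories: EncounterHistoryMatrix | None,
    settings: McmcSettings | None = None,
    *,
    priors: PriorBounds | None = None,
    random_effects: bool = True,
    fix_psi: float | np.ndarray | None = None,
    n_sites: int | None = None,
    n_occasions: int | None = None,
    max_init_retries: int = 20,
) -> PosteriorDraws:
    """Fit the hierarchical three-state model by MCMC.

    Parameters
    ----------
    histories : encounter histories, or None/empty for a prior-only fit
        (then ``n_sites`` and ``n_occasions`` must be given).
    random_effects : when False the site/year/occasion effects and their
        SDs are fixed at zero — the reduced model with a single constant
        phi = expit(mu) and p = expit(beta).
    fix_psi : fix the residence probability at a value (scalar or per
        site) instead of sampling it; ``fix_psi=1.0`` gives the CJS limit.
    """
    settings = settings or McmcSettings()
    b = priors or PriorBounds()

    if histories is not None and histories.n_individuals > 0:
        site_ids = histories.site_ids
        T = histories.n_occasions
        if n_sites is not None and n_sites != len(site_ids):
            raise ValueError("n_sites disagrees with histories")
    else:
        if n_sites is None or n_occasions is None:
            raise ValueError("empty data: n_sites and n_occasions required")
        site_ids = np.arange(1, n_sites + 1)
        T = n_occasions
        histories = None
    S = len(site_ids)
    I = T - 1

    if histories is not None:
        n0, R, Ssurv, D, ND, L = _suffstats(histories, site_ids, T)
    else:
        n0, R = np.zeros((S, T)), np.zeros(S)
        Ssurv = np.zeros((S, I))
        D, ND, L = np.zeros((S, T)), np.zeros((S, T)), np.zeros((S, T))

    npar = _kernels.n_params(S, T)
    off_eta, off_eps, off_gam = 5, 5 + S, 5 + S + I
    off_psi = off_gam + S * I

    mask = np.ones(npar, dtype=bool)
    if not random_effects:
        mask[2:5] = False
        mask[off_eta:off_psi] = False
    if fix_psi is not None:
        fixed_psi = np.broadcast_to(np.asarray(fix_psi, dtype=float), (S,)).copy()
        if ((fixed_psi < 0) | (fixed_psi > 1)).any():
            raise ValueError("fix_psi must lie in [0, 1]")
        mask[off_psi:] = False
    else:
        fixed_psi = np.full(S, np.nan)

    n_kept = settings.kept_per_chain
    all_draws = np.empty((settings.chains, n_kept, npar))
    acc_rates = []
    final_scales = []
    for c in range(settings.chains):
        ss = np.random.SeedSequence([settings.seed, c])
        rng = np.random.default_rng(ss)
        kernel_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        theta0 = None
        for _ in range(max_init_retries):
            theta0 = _init_from_prior(rng, S, I, b, random_effects)
            ll = np.empty(S)
            _kernels.all_site_ll(theta0, S, T, fixed_psi, n0, R, Ssurv, D, ND, L, ll)
            if np.isfinite(ll.sum()):
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initialization")
        kept, acc, scales = _kernels.run_chain(
            n0, R, Ssurv, D, ND, L,
            S, T, mask, fixed_psi,
            b.logit_mean_lo, b.logit_mean_hi, b.sd_hi,
            settings.iterations, settings.burn_in, settings.thinning,
            kernel_seed, theta0,
        )
        all_draws[c] = kept
        acc_rates.append(acc)
        final_scales.append(scales)

    # back-transform to the natural scale
    all_draws[:, :, 2:5] = np.exp(all_draws[:, :, 2:5])
    if fix_psi is None:
        all_draws[:, :, off_psi:] = expit(all_draws[:, :, off_psi:])
    else:
        all_draws[:, :, off_psi:] = fixed_psi[None, None, :]

    names = parameter_names(site_ids, T)
    move_names = names + ["shift(mu,eta)", "shift(mu,eps)", "shift(beta,gamma)"]
    meta = {
        "settings": settings,
        "sampled": {n: bool(m) for n, m in zip(names, mask)},
        "acceptance": {
            n: (
                float(np.nanmean(vals))
                if np.isfinite(vals := np.array([a[k] for a in acc_rates])).any()
                else np.nan
            )
            for k, n in enumerate(move_names)
        },
        "proposal_scales": {
            n: float(np.mean([s[k] for s in final_scales]))
            for k, n in enumerate(move_names)
        },
    }
    return PosteriorDraws(all_draws, names, site_ids, T, meta)


def _init_from_prior(rng, S: int, I: int, b: PriorBounds, random_effects: bool):
    npar = 5 + S + I + S * I + S
    theta = np.zeros(npar)
    theta[0] = rng.uniform(b.logit_mean_lo, b.logit_mean_hi)
    theta[1] = rng.uniform(b.logit_mean_lo, b.logit_mean_hi)
    off_eta, off_eps, off_gam = 5, 5 + S, 5 + S + I
    off_psi = off_gam + S * I
    if random_effects:
        sds = rng.uniform(max(b.sd_lo, 1e-3), b.sd_hi, size=3)
        theta[2:5] = np.log(sds)
        theta[off_eta:off_eps] = rng.normal(0.0, sds[0], size=S)
        theta[off_eps:off_gam] = rng.normal(0.0, sds[1], size=I)
        theta[off_gam:off_psi] = rng.normal(0.0, sds[2], size=S * I)
    theta[off_psi:] = logit(rng.uniform(0.01, 0.99, size=S))
    return theta


def draws_to_params(draws: PosteriorDraws, chain: int, idx: int) -> ModelParameters:
    """Materialize one retained draw as a ModelParameters object."""
    row = draws.draws[chain, idx]
    S = len(draws.site_ids)
    T = draws.n_occasions
    I = T - 1
    off_eta, off_eps, off_gam = 5, 5 + S, 5 + S + I
    off_psi = off_gam + S * I
    return ModelParameters(
        mu=row[0],
        beta=row[1],
        sigma_space=row[2],
        sigma_time=row[3],
        sigma_gamma=row[4],
        eta=row[off_eta:off_eps],
        eps=row[off_eps:off_gam],
        gamma=row[off_gam:off_psi].reshape(S, I),
        psi=row[off_psi:],
    )


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor.

    ``chains``: (m, n) array of one parameter's draws.  Classic PSRF:
    R = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.  Degenerate
    within-chain variance returns nan.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 4:
        raise ValueError("need >= 2 chains of >= 4 draws")
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0.0:
        logger.warning("rhat: zero within-chain variance (degenerate)")
        return np.nan
    B = n * chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, central 95% credible interval,
    effective draw count and R-hat, as a table."""

    table: pd.DataFrame

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]


def summarize_array(chains: np.ndarray) -> dict:
    """Mean, equal-tailed 95% interval, ESS and R-hat of one quantity."""
    flat = chains.reshape(-1)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    ess = float(az.ess(np.asarray(chains)))
    r = rhat(chains) if chains.shape[0] >= 2 and chains.shape[1] >= 4 else np.nan
    return {
        "mean": float(flat.mean()),
        "cri_lo": float(lo),
        "cri_hi": float(hi),
        "ess": ess,
        "rhat": r,
    }


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior summary table in the reporting convention of the analysis:
    equal-tailed 95% intervals; survival/recapture means additionally
    reported on the probability scale (transformed per draw, never the
    inverse-logit of the posterior mean); SDs on their original scale.
    """
    rows = {}
    for k, name in enumerate(draws.names):
        if not draws.metadata.get("sampled", {}).get(name, True):
            continue
        rows[name] = summarize_array(draws.draws[:, :, k])
    # probability-scale counterparts of the mean logits, per draw
    rows["phi_overall"] = summarize_array(expit(draws.get("mu")))
    rows["p_overall"] = summarize_array(expit(draws.get("beta")))
    table = pd.DataFrame(rows).T
    return PosteriorSummary(table)
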