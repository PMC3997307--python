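"""Compiled numerical core of the sampler.

The per-site likelihood here is an algebraically collapsed form of the
three-state forward recursion: conditioned on first capture, an encounter
history factorises into a settlement term (psi), survival terms over the
intervals between first and last capture, detection/non-detection terms,
and a "never seen after last capture" tail probability chi computed by a
backward recursion.  Sufficient statistics (counts of survivals at risk,
detections, last captures and single-capture first occasions) make one
likelihood evaluation O(T) per site regardless of sample size.  The pure
numpy forward recursion in :mod:`reedcmr.cmr_model` is the reference; the
test suite checks the two agree.

Parameter vector layout (S sites, I = T-1 intervals), all unconstrained:

    [mu, beta, log sigma_space, log sigma_time, log sigma_gamma,
     eta_1..eta_S, eps_1..eps_I, gamma_11..gamma_SI (row-major),
     logit psi_1..psi_S]
"""

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453


def n_params(S: int, T: int) -> int:
    I = T - 1
    return 5 + S + I + S * I + S


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _logit_jacobian(x):
    # log(psi * (1 - psi)) for psi = expit(x), stable both directions
    if x >= 0.0:
        return -x - 2.0 * np.log1p(np.exp(-x))
    return x - 2.0 * np.log1p(np.exp(x))


@njit(cache=True)
def site_loglik(T, phi, p, psi, n0, R, Ssurv, D, ND, L):
    """Collapsed log-likelihood of one site's histories.

    phi: (T-1,) interval survival; p: (T,) occasion recapture (entry 0
    unused); psi: settlement probability; counts as float64 arrays:
    n0[f] single-capture individuals by first occasion, R recaptured
    total, Ssurv[t] survival intervals at risk, D/ND detections and
    misses at occasions 1..T-1, L[l] last-capture occasions of
    recaptured individuals.
    """
    chi = np.empty(T)
    chi[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        chi[t] = (1.0 - phi[t]) + phi[t] * (1.0 - p[t + 1]) * chi[t + 1]
    ll = 0.0
    if R > 0.0:
        if psi <= 0.0:
            return -np.inf
        ll += R * np.log(psi)
    for t in range(T - 1):
        if Ssurv[t] > 0.0:
            if phi[t] <= 0.0:
                return -np.inf
            ll += Ssurv[t] * np.log(phi[t])
    for t in range(1, T):
        if D[t] > 0.0:
            if p[t] <= 0.0:
                return -np.inf
            ll += D[t] * np.log(p[t])
        if ND[t] > 0.0:
            if p[t] >= 1.0:
                return -np.inf
            ll += ND[t] * np.log(1.0 - p[t])
    for l in range(T):
        if L[l] > 0.0:
            if chi[l] <= 0.0:
                return -np.inf
            ll += L[l] * np.log(chi[l])
    for f in range(T - 1):
        if n0[f] > 0.0:
            nf = (1.0 - psi) + psi * (
                (1.0 - phi[f]) + phi[f] * (1.0 - p[f + 1]) * chi[f + 1]
            )
            if nf <= 0.0:
                return -np.inf
            ll += n0[f] * np.log(nf)
    return ll


@njit(cache=True)
def _site_ll_theta(theta, s, S, T, fixed_psi, n0, R, Ssurv, D, ND, L):
    I = T - 1
    phi = np.empty(I)
    p = np.empty(T)
    p[0] = 0.0
    mu = theta[0]
    beta = theta[1]
    off_eps = 5 + S
    off_gam = 5 + S + I
    for t in range(I):
        phi[t] = _expit(mu + theta[5 + s] + theta[off_eps + t])
        p[t + 1] = _expit(beta + theta[off_gam + s * I + t])
    if np.isnan(fixed_psi[s]):
        psi = _expit(theta[off_gam + S * I + s])
    else:
        psi = fixed_psi[s]
    return site_loglik(T, phi, p, psi, n0[s], R[s], Ssurv[s], D[s], ND[s], L[s])


@njit(cache=True)
def all_site_ll(theta, S, T, fixed_psi, n0, R, Ssurv, D, ND, L, out):
    for s in range(S):
        out[s] = _site_ll_theta(theta, s, S, T, fixed_psi, n0, R, Ssurv, D, ND, L)


@njit(cache=True)
def _group_normal_lp(theta, off, n, sigma):
    ss = 0.0
    for k in range(n):
        ss += theta[off + k] * theta[off + k]
    return -0.5 * ss / (sigma * sigma) - n * np.log(sigma) - 0.5 * n * LOG2PI


@njit(cache=True)
def run_chain(
    n0, R, Ssurv, D, ND, L,
    S, T,
    mask,
    fixed_psi,
    mean_lo, mean_hi, sd_hi,
    iterations, burn_in, thinning,
    seed, init_theta,
):
    """One adaptive Metropolis-within-Gibbs chain.

    Scalar random-walk updates on the unconstrained scale for every
    parameter with ``mask`` set, plus three likelihood-invariant
    translation moves ((mu, eta), (mu, eps), (beta, gamma)) that decorrelate
    the intercepts from their centred random effects.  Proposal scales
    adapt toward 0.44 acceptance in batches of 50 iterations during
    burn-in only.  Returns the thinned post-burn-in draws (unconstrained
    scale), post-burn-in acceptance rates, and final proposal scales.
    """
    np.random.seed(seed)
    I = T - 1
    off_eta = 5
    off_eps = 5 + S
    off_gam = 5 + S + I
    off_psi = off_gam + S * I
    npar = init_theta.shape[0]
    nmove = npar + 3

    theta = init_theta.copy()
    site_ll = np.empty(S)
    all_site_ll(theta, S, T, fixed_psi, n0, R, Ssurv, D, ND, L, site_ll)
    new_ll = np.empty(S)

    scales = np.full(nmove, 0.3)
    acc_batch = np.zeros(nmove)
    att_batch = np.zeros(nmove)
    acc_post = np.zeros(nmove)
    att_post = np.zeros(nmove)

    n_kept = (iterations - burn_in) // thinning
    kept = np.empty((n_kept, npar))
    k_out = 0

    shift_on = np.zeros(3, dtype=np.bool_)
    # translation moves only make sense when both blocks are sampled
    shift_on[0] = mask[0] and mask[off_eta]
    shift_on[1] = mask[0] and mask[off_eps]
    shift_on[2] = mask[1] and mask[off_gam]

    for it in range(iterations):
        in_burn = it < burn_in
        for j in range(npar):
            if not mask[j]:
                continue
            x = theta[j]
            xp = x + scales[j] * np.random.normal()
            dprior = 0.0
            local_site = -1
            need_ll = True
            reject = False

            if j == 0 or j == 1:  # mu, beta: flat prior inside bounds
                if xp <= mean_lo or xp >= mean_hi:
                    reject = True
            elif j < 5:  # log SDs: prior-only updates
                need_ll = False
                sig_new = np.exp(xp)
                sig_old = np.exp(x)
                if sig_new >= sd_hi:
                    reject = True
                else:
                    if j == 2:
                        off, n = off_eta, S
                    elif j == 3:
                        off, n = off_eps, I
                    else:
                        off, n = off_gam, S * I
                    dprior = (
                        _group_normal_lp(theta, off, n, sig_new)
                        - _group_normal_lp(theta, off, n, sig_old)
                        + (xp - x)  # log-scale Jacobian of the U(0, sd_hi) prior
                    )
            elif j < off_eps:  # eta_s
                sig = np.exp(theta[2])
                dprior = -0.5 * (xp * xp - x * x) / (sig * sig)
                local_site = j - off_eta
            elif j < off_gam:  # eps_t
                sig = np.exp(theta[3])
                dprior = -0.5 * (xp * xp - x * x) / (sig * sig)
            elif j < off_psi:  # gamma_st
                sig = np.exp(theta[4])
                dprior = -0.5 * (xp * xp - x * x) / (sig * sig)
                local_site = (j - off_gam) // I
            else:  # logit psi_s
                dprior = _logit_jacobian(xp) - _logit_jacobian(x)
                local_site = j - off_psi

            att_batch[j] += 1.0
            if not in_burn:
                att_post[j] += 1.0
            if reject:
                continue

            if need_ll:
                theta[j] = xp
                if local_site >= 0:
                    ll_new_s = _site_ll_theta(
                        theta, local_site, S, T, fixed_psi, n0, R, Ssurv, D, ND, L
                    )
                    dll = ll_new_s - site_ll[local_site]
                else:
                    all_site_ll(theta, S, T, fixed_psi, n0, R, Ssurv, D, ND, L, new_ll)
                    dll = new_ll.sum() - site_ll.sum()
                log_alpha = dprior + dll
                if np.log(np.random.random()) < log_alpha:
                    if local_site >= 0:
                        site_ll[local_site] = ll_new_s
                    else:
                        site_ll[:] = new_ll
                    acc_batch[j] += 1.0
                    if not in_burn:
                        acc_post[j] += 1.0
                else:
                    theta[j] = x
            else:
                if np.log(np.random.random()) < dprior:
                    theta[j] = xp
                    acc_batch[j] += 1.0
                    if not in_burn:
                        acc_post[j] += 1.0

        # translation moves: likelihood-invariant joint shifts
        for mv in range(3):
            if not shift_on[mv]:
                continue
            jm = npar + mv
            att_batch[jm] += 1.0
            if not in_burn:
                att_post[jm] += 1.0
            delta = scales[jm] * np.random.normal()
            if mv == 0:
                mean_idx, off, n, sig = 0, off_eta, S, np.exp(theta[2])
            elif mv == 1:
                mean_idx, off, n, sig = 0, off_eps, I, np.exp(theta[3])
            else:
                mean_idx, off, n, sig = 1, off_gam, S * I, np.exp(theta[4])
            m_new = theta[mean_idx] + delta
            if m_new <= mean_lo or m_new >= mean_hi:
                continue
            dprior = 0.0
            for k in range(n):
                xo = theta[off + k]
                xn = xo - delta
                dprior += -0.5 * (xn * xn - xo * xo) / (sig * sig)
            if np.log(np.random.random()) < dprior:
                theta[mean_idx] = m_new
                for k in range(n):
                    theta[off + k] -= delta
                acc_batch[jm] += 1.0
                if not in_burn:
                    acc_post[jm] += 1.0

        if in_burn and (it + 1) % 50 == 0:
            step = min(0.1, 5.0 / np.sqrt(it + 1.0))
            for k in range(nmove):
                if att_batch[k] > 0.0:
                    rate = acc_batch[k] / att_batch[k]
                    if rate > 0.44:
                        scales[k] *= np.exp(step)
                    else:
                        scales[k] *= np.exp(-step)
                    if scales[k] < 1e-6:
                        scales[k] = 1e-6
                    elif scales[k] > 50.0:
                        scales[k] = 50.0
                acc_batch[k] = 0.0
                att_batch[k] = 0.0

        if not in_burn and (it - burn_in) % thinning == 0 and k_out < n_kept:
            kept[k_out] = theta
            k_out += 1

    acc_rate = np.full(nmove, np.nan)
    for k in range(nmove):
        if att_post[k] > 0.0:
            acc_rate[k] = acc_post[k] / att_post[k]
    return kept, acc_rate, scales
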