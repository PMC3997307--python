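"""Three-state capture-recapture model and its exact marginal likelihood.

The model follows newly captured birds through three latent states:

* ``Initial`` — the state at first capture.  Over the first interval the
  bird becomes a ``Resident`` with probability phi * psi (it must both
  survive, phi, and settle, psi) and otherwise leaves the study for good
  (absorbed in ``Dead``, which here pools death with permanent emigration —
  including the transient birds that were only passing through).
* ``Resident`` — survives each interval with probability phi and, while
  alive, is recaptured at an occasion with probability p.
* ``Dead`` — absorbing; never observed.

Transition matrix (rows: state at t; columns: state at t+1):

    Initial   [ 0   phi*psi   1 - phi*psi ]
    Resident  [ 0   phi       1 - phi     ]
    Dead      [ 0   0         1           ]

Observation: a Resident is seen with probability p; Initial and Dead are
never seen (the first capture itself is conditioned on, not modelled).

The likelihood of an encounter history is the exact marginal over latent
state paths, computed by a forward (filtering) recursion — mathematically
identical to sampling the states but deterministic, which keeps the
likelihood unit-testable against brute-force path enumeration.

Hierarchical structure on the probability parameters (logit scale):

    logit(phi[s, t]) = mu + eta[s] + eps[t]      eta ~ N(0, sigma_space^2)
                                                 eps ~ N(0, sigma_time^2)
    logit(p[s, t])   = beta + gamma[s, t]        gamma ~ N(0, sigma_gamma^2)

with psi[s] constant over time but free across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

from .preprocess import EncounterHistoryMatrix, MArray

STATE_INITIAL, STATE_RESIDENT, STATE_DEAD = 0, 1, 2
STATE_NAMES = ("Initial", "Resident", "Dead")


@dataclass
class ModelParameters:
    """All model unknowns for S sites and T occasions.

    ``eta`` rows (and ``gamma`` rows, ``psi`` entries) correspond to the
    sorted unique site ids of the encounter-history matrix being analysed.
    ``eps`` indexes the T-1 intervals t -> t+1; ``gamma`` indexes site by
    recapture occasion 2..T (T-1 columns).
    """

    mu: float
    eta: np.ndarray  # (S,)
    eps: np.ndarray  # (T-1,)
    sigma_space: float
    sigma_time: float
    beta: float
    gamma: np.ndarray  # (S, T-1)
    sigma_gamma: float
    psi: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        for name in ("sigma_space", "sigma_time", "sigma_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if ((self.psi < 0) | (self.psi > 1)).any():
            raise ValueError("psi must lie in [0, 1]")
        S, I = self.gamma.shape
        if self.eta.shape != (S,) or self.psi.shape != (S,) or self.eps.shape != (I,):
            raise ValueError("inconsistent parameter dimensions")

    @property
    def n_sites(self) -> int:
        return self.eta.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.eps.shape[0] + 1

    def survival(self) -> np.ndarray:
        """phi[s, t] = inverse-logit(mu + eta_s + eps_t), shape (S, T-1)."""
        return expit(self.mu + self.eta[:, None] + self.eps[None, :])

    def recapture(self) -> np.ndarray:
        """p[s, t] for recapture occasions 2..T, shape (S, T-1)."""
        return expit(self.beta + self.gamma)


def transition_matrix(phi: float, psi: float) -> np.ndarray:
    """3x3 row-stochastic latent transition matrix over (Initial, Resident, Dead)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi={phi} outside [0, 1]")
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi={psi} outside [0, 1]")
    return np.array(
        [
            [0.0, phi * psi, 1.0 - phi * psi],
            [0.0, phi, 1.0 - phi],
            [0.0, 0.0, 1.0],
        ]
    )


def observation_row(p: float, state: int) -> tuple[float, float]:
    """(P(seen as Resident), P(not seen)) for a given true state."""
    if state == STATE_RESIDENT:
        return (p, 1.0 - p)
    return (0.0, 1.0)


def history_loglik(
    history: np.ndarray,
    first_capture: int,
    phi_t: np.ndarray,
    p_t: np.ndarray,
    psi: float,
) -> float:
    """Exact marginal log-probability of the detections after first capture.

    Parameters
    ----------
    history : 0/1 vector of length T with ``history[first_capture] == 1``.
    phi_t : survival probabilities for the T-1 intervals t -> t+1.
    p_t : recapture probabilities for the T occasions (entry 0 unused:
        detection at an occasion before any release cannot occur).
    psi : residence probability applied to the first interval after release.

    Impossible histories (e.g. a detection after an interval with phi = 0)
    return ``-inf`` rather than raising.
    """
    history = np.asarray(history)
    T = history.shape[0]
    if history[first_capture] != 1:
        raise ValueError("history must have a detection at first_capture")
    if len(phi_t) != T - 1 or len(p_t) != T:
        raise ValueError("phi_t must have T-1 entries and p_t T entries")

    # forward filter over (Initial, Resident, Dead) with per-step
    # normalization; log of the normalizers accumulates the log-likelihood
    alpha = np.array([1.0, 0.0, 0.0])
    loglik = 0.0
    for t in range(first_capture + 1, T):
        alpha = alpha @ transition_matrix(phi_t[t - 1], psi)
        p = p_t[t]
        emit = np.array(
            [observation_row(p, s)[0 if history[t] else 1] for s in range(3)]
        )
        alpha = alpha * emit
        c = alpha.sum()
        if c <= 0.0:
            return -np.inf
        loglik += np.log(c)
        alpha /= c
    return float(loglik)


def total_loglik(histories: EncounterHistoryMatrix, params: ModelParameters) -> float:
    """Sum of history log-likelihoods under the hierarchical logit model.

    Site s of an individual selects eta[s], gamma[s, :] and psi[s], where
    rows follow the sorted unique site ids of ``histories``.
    """
    site_ids = histories.site_ids
    S = len(site_ids)
    T = histories.n_occasions
    if params.n_sites != S:
        raise ValueError(
            f"parameters define {params.n_sites} site(s) but histories contain {S}"
        )
    if params.n_occasions != T:
        raise ValueError(
            f"parameters define {params.n_occasions} occasions but histories have {T}"
        )
    phi = params.survival()  # (S, T-1)
    p = params.recapture()  # (S, T-1), occasions 2..T
    site_pos = {sid: k for k, sid in enumerate(site_ids)}
    total = 0.0
    for i in range(histories.n_individuals):
        s = site_pos[histories.site_index[i]]
        p_t = np.concatenate(([0.0], p[s]))
        total += history_loglik(
            histories.detections[i],
            int(histories.first_capture[i]),
            phi[s],
            p_t,
            float(params.psi[s]),
        )
    return total


def cjs_loglik_marray(marray: MArray, phi_t: np.ndarray, p_t: np.ndarray) -> float:
    """Cormack-Jolly-Seber product-multinomial log-likelihood from an m-array.

    This is the psi = 1 special case of the three-state model, used as an
    independent oracle.  ``phi_t`` has T-1 entries (intervals), ``p_t`` T
    entries (occasions; entry 0 unused).  The multinomial coefficient, a
    data-dependent constant, is omitted.
    """
    phi_t = np.asarray(phi_t, dtype=float)
    p_t = np.asarray(p_t, dtype=float)
    T = marray.m.shape[1]
    loglik = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(T - 1):
            # cell probability of first reencounter at j: survive i..j-1,
            # missed at i+1..j-1, seen at j
            cell = np.zeros(T)
            carry = 1.0
            for j in range(i + 1, T):
                carry *= phi_t[j - 1]
                cell[j] = carry * p_t[j]
                carry *= 1.0 - p_t[j]
            never = 1.0 - cell.sum()
            for j in range(i + 1, T):
                if marray.m[i, j]:
                    loglik += marray.m[i, j] * np.log(cell[j])
            n_never = marray.never[i]
            if n_never:
                loglik += n_never * np.log(max(never, 0.0))
    return float(loglik)
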