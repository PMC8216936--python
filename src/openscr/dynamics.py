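"""Open-population (Jolly-Seber superpopulation) presence dynamics.

The population of M data-augmented individuals evolves over T primary
periods through a binary presence state z[i, t]:

    z[i, 1] ~ Bernoulli(gamma_1)
    z[i, t] ~ Bernoulli(phi_{t-1} * z[i, t-1] + gamma_t * (1 - z[i, t-1]))

gamma_t (arrival / recruitment) follows a quadratic, and phi_t (persistence /
survival) a linear, function of standardized time on the logit scale.
Individuals may enter and leave the study area multiple times; re-entry uses
the same gamma as initial entry.

Derived quantities are deterministic functions of z: abundance
N_t = sum_i z[i, t], recruitment R_t = sum_i (1 - z[i, t-1]) z[i, t], and the
superpopulation size (individuals ever present).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def standardize_time(T: int, ddof: int = 0) -> np.ndarray:
    """Primary-period indices 1..T standardized to mean 0, sd 1.

    The population standard deviation (``ddof=0``) is the default; pass
    ``ddof=1`` for the sample-sd convention.
    """
    if T < 2:
        raise ValueError("need T >= 2 primary periods to standardize time")
    t = np.arange(1, T + 1, dtype=float)
    return (t - t.mean()) / t.std(ddof=ddof)


def gamma_t(beta_gamma, time_t) -> np.ndarray | float:
    """Arrival probability: inverse-logit of a quadratic in standardized time."""
    b = np.asarray(beta_gamma, dtype=float)
    time_t = np.asarray(time_t, dtype=float)
    return expit(b[..., 0] + b[..., 1] * time_t + b[..., 2] * time_t ** 2)


def phi_t(beta_phi, time_t) -> np.ndarray | float:
    """Persistence probability: inverse-logit of a linear trend in time."""
    b = np.asarray(beta_phi, dtype=float)
    time_t = np.asarray(time_t, dtype=float)
    return expit(b[..., 0] + b[..., 1] * time_t)


def gamma_schedule(beta_gamma, time: np.ndarray) -> np.ndarray:
    """gamma_t for t = 1..T; beta_gamma may be (3,) or (V, 3) (-> (V, T))."""
    b = np.asarray(beta_gamma, dtype=float)
    time = np.asarray(time, dtype=float)
    if b.ndim == 1:
        return gamma_t(b, time)
    return expit(b[:, [0]] + b[:, [1]] * time[None, :] + b[:, [2]] * time[None, :] ** 2)


def phi_schedule(beta_phi, time: np.ndarray) -> np.ndarray:
    """phi_t for t = 1..T; beta_phi may be (2,) or (V, 2) (-> (V, T))."""
    b = np.asarray(beta_phi, dtype=float)
    time = np.asarray(time, dtype=float)
    if b.ndim == 1:
        return phi_t(b, time)
    return expit(b[:, [0]] + b[:, [1]] * time[None, :])


def transition_prob(z_prev, phi_prev, gamma_now) -> np.ndarray | float:
    """P(z_t = 1 | z_{t-1}): phi if previously present, gamma otherwise.

    At t = 1 call with ``z_prev = 0`` so the result is gamma_1, the fraction
    of the M augmented individuals present in the first period.
    """
    z_prev = np.asarray(z_prev, dtype=float)
    return phi_prev * z_prev + gamma_now * (1.0 - z_prev)


def simulate_presence(M: int, gamma: np.ndarray, phi: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Forward-simulate the z chain for M individuals.

    Parameters
    ----------
    gamma : (T,) arrival probabilities; phi : (T,) persistence probabilities
        (phi[t] applies to the t -> t+1 transition; phi[T-1] is unused).
    """
    gamma = np.asarray(gamma, dtype=float)
    phi = np.asarray(phi, dtype=float)
    T = gamma.size
    z = np.zeros((M, T), dtype=np.int8)
    z[:, 0] = rng.random(M) < gamma[0]
    for t in range(1, T):
        p = transition_prob(z[:, t - 1], phi[t - 1], gamma[t])
        z[:, t] = rng.random(M) < p
    return z


def expected_abundance(M: int, gamma: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Closed-form E[N_t] via the recursion
    E[N_t] = phi_{t-1} E[N_{t-1}] + gamma_t (M - E[N_{t-1}])."""
    gamma = np.asarray(gamma, dtype=float)
    phi = np.asarray(phi, dtype=float)
    T = gamma.size
    en = np.empty(T)
    en[0] = M * gamma[0]
    for t in range(1, T):
        en[t] = phi[t - 1] * en[t - 1] + gamma[t] * (M - en[t - 1])
    return en


def derive_abundance(z: np.ndarray) -> np.ndarray:
    """N_t = sum_i z[i, t], the number of individuals present per period."""
    return np.asarray(z).sum(axis=0)


def derive_recruits(z: np.ndarray) -> np.ndarray:
    """Entries per period: R[0] = N_1 (initial entries, reported as such
    since recruitment before the study is undefined), then
    R[t] = sum_i (1 - z[i, t-1]) z[i, t]."""
    z = np.asarray(z)
    if z.shape[1] < 1:
        raise ValueError("z must have at least one period")
    r = np.empty(z.shape[1], dtype=int)
    r[0] = int(z[:, 0].sum())
    if z.shape[1] > 1:
        r[1:] = ((1 - z[:, :-1]) * z[:, 1:]).sum(axis=0)
    return r


def superpopulation_size(z: np.ndarray) -> int:
    """Number of individuals ever present: sum_i 1{max_t z[i, t] = 1}."""
    return int(np.asarray(z).max(axis=1).sum())
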