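"""Latent demographic-group membership.

Individuals belong to one of V groups (e.g., calving females vs. all other
right whales).  Membership is data when observed and latent otherwise —
including for every augmented individual.  The group-probability simplex
carries a flat Dirichlet prior expressed through independent Gamma(1, 1)
variates:

    pi_group[v] = a[v] / sum_v' a[v'],   a[v] ~ Gamma(1, 1)

which makes pi_group ~ Dirichlet(1, ..., 1).  The Gibbs update for
pi_group given group counts is therefore Dirichlet(1 + counts).
"""

from __future__ import annotations

import numpy as np


def pi_group_from_a(a: np.ndarray) -> np.ndarray:
    """Normalize positive Gamma variates into the group simplex."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("Gamma variates a must be positive")
    return a / a.sum()


def sample_group(likelihood_by_group: np.ndarray, pi_group: np.ndarray,
                 rng: np.random.Generator) -> int:
    """Draw a group index with probability proportional to
    pi_group[v] * likelihood_by_group[v] (the full conditional for an
    unknown-group individual)."""
    lik = np.asarray(likelihood_by_group, dtype=float)
    if np.any(lik < 0):
        raise ValueError("group likelihoods must be nonnegative")
    w = np.asarray(pi_group, dtype=float) * lik
    tot = w.sum()
    if tot <= 0 or not np.isfinite(tot):
        raise ValueError("all-zero group likelihood: impossible state")
    return int(rng.choice(w.size, p=w / tot))


def sample_pi_group_posterior(counts: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    """Gibbs draw pi_group ~ Dirichlet(1 + counts) under the flat prior."""
    counts = np.asarray(counts, dtype=float)
    return rng.dirichlet(1.0 + counts)
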