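"""Space-use (movement) model around activity centers.

The probability that an individual anchored at activity center s is in
pixel g on a secondary occasion combines a Gaussian distance kernel with
the habitat predictor (a resource-selection form):

    log mu[g] = -d(s, g)^2 / (2 sigma_move^2) + sum_j beta_j X[j, g, t]
    pi_movement[g] = mu[g] / sum_g' mu[g']

Distances are between pixel centers.  Within the drawn pixel the exact
location is uniform on the pixel square.  Normalization subtracts the
maximum log-kernel before exponentiation, so small sigma_move cannot
underflow to an all-zero kernel.

By default the movement model shares the state-space grid, covariates, and
coefficients beta with the density model; neither constraint is intrinsic
and the sampler configuration can decouple the coefficient vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

from .geometry import StateSpaceGrid, pairwise_center_distances


def center_pixel_distances(s_pixel: int, grid: StateSpaceGrid) -> np.ndarray:
    """Distances d(s, g) from the center of pixel ``s_pixel`` to all centers."""
    c = grid.pixel_centers
    ref = c[s_pixel]
    return np.hypot(c[:, 0] - ref[0], c[:, 1] - ref[1])


def movement_log_kernel(s_pixel: int, sigma_move: float, beta, X,
                        t: int, grid: StateSpaceGrid) -> np.ndarray:
    """Unnormalized log space-use kernel over pixels, (G,)."""
    if sigma_move <= 0:
        raise ValueError("sigma_move must be positive")
    d = center_pixel_distances(s_pixel, grid)
    eta = np.einsum("j,jg->g", np.asarray(beta, dtype=float),
                    np.asarray(X)[:, :, t])
    return -0.5 * (d / sigma_move) ** 2 + eta


def pi_movement(s_pixel: int, sigma_move: float, beta, X, t: int,
                grid: StateSpaceGrid) -> np.ndarray:
    """Space-use pixel probabilities (softmax of the log kernel), (G,)."""
    return softmax(movement_log_kernel(s_pixel, sigma_move, beta, X, t, grid))


def movement_kernel_matrix(sigma_move: float, D2: np.ndarray) -> np.ndarray:
    """exp(-D2 / (2 sigma^2)) for a precomputed (G, G) squared-distance matrix.

    Row s gives the (unweighted) distance kernel for activity center s; the
    habitat weight multiplies in columnwise.  Used heavily by the sampler.
    """
    if sigma_move <= 0:
        raise ValueError("sigma_move must be positive")
    return np.exp(-0.5 * D2 / sigma_move ** 2)


def squared_center_distances(grid: StateSpaceGrid) -> np.ndarray:
    """(G, G) squared distances between pixel centers."""
    d = pairwise_center_distances(grid)
    return d * d


def sample_location(pi_movement_vec: np.ndarray, grid: StateSpaceGrid,
                    rng: np.random.Generator) -> tuple[int, float, float]:
    """Draw (pixel, x, y): categorical pixel, then uniform within the square."""
    pi_movement_vec = np.asarray(pi_movement_vec, dtype=float)
    g = int(rng.choice(pi_movement_vec.size, p=pi_movement_vec))
    cx, cy = grid.pixel_centers[g]
    half = grid.side / 2.0
    x = rng.uniform(cx - half, cx + half)
    y = rng.uniform(cy - half, cy + half)
    return g, float(x), float(y)
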