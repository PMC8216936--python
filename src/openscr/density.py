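"""Habitat-covariate model for expected density and activity centers.

Expected relative density in pixel g at primary period t is log-linear in a
stack of J standardized covariates, with no intercept (total abundance is
set by the population process, so only relative density is identified):

    log E(D[g, t]) = sum_j beta_j * X[j, g, t]

Activity centers s[i, t] are categorical over pixels with probabilities
pi_density[g, t] = E(D[g, t]) / sum_g E(D[g, t]), independently across
primary periods.  Realized absolute density is the number of present
activity centers per pixel divided by pixel area.

Quadratic covariate effects are data construction, not model structure: the
stack can append squared companions of selected columns (squaring the
already-standardized base covariate), and the density model stays strictly
linear in the supplied columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .geometry import StateSpaceGrid


@dataclass
class CovariateStack:
    """Per-pixel, per-period covariate values X[j, g, t].

    ``base`` flags which columns are base covariates (standardized to mean 0,
    sd 1 pooling over all pixels and periods) as opposed to derived squared
    companions, which are not re-standardized.
    """

    X: np.ndarray  # (J, G, T)
    names: list[str]
    base: np.ndarray = field(default=None)  # (J,) bool

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("X must have shape (J, G, T)")
        if len(self.names) != self.X.shape[0]:
            raise ValueError("names must match the number of covariates")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariate stack contains non-finite values")
        if self.base is None:
            self.base = np.ones(self.X.shape[0], dtype=bool)
        else:
            self.base = np.asarray(self.base, dtype=bool)

    @property
    def J(self) -> int:
        return self.X.shape[0]

    @property
    def G(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> int:
        return self.X.shape[2]

    def validate_standardized(self, tol: float = 1e-6) -> None:
        """Check base columns pool to mean 0, sd 1 (within ``tol``)."""
        for j in np.flatnonzero(self.base):
            v = self.X[j]
            if abs(v.mean()) > tol or abs(v.std() - 1.0) > tol:
                raise ValueError(
                    f"covariate {self.names[j]!r} is not standardized "
                    f"(mean {v.mean():.3g}, sd {v.std():.3g})"
                )


def standardize(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1, pooling over all pixels and periods."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0.0:
        raise ValueError("cannot standardize a constant covariate (sd = 0)")
    return (values - values.mean()) / sd


def add_squared(stack: CovariateStack, columns: list[str]) -> CovariateStack:
    """Append squared companions of the named (standardized) base columns."""
    X = [stack.X[j] for j in range(stack.J)]
    names = list(stack.names)
    base = list(stack.base)
    for name in columns:
        j = names.index(name)
        X.append(stack.X[j] ** 2)
        names.append(name + "2")
        base.append(False)
    return CovariateStack(np.stack(X), names, np.array(base))


def interpolate_missing(values: np.ndarray, grid: StateSpaceGrid,
                        radius: float = 1.5) -> np.ndarray:
    """Fill NaN pixels with the mean of non-missing neighbors within ``radius``.

    ``radius`` is in the grid's scaled units; the default 1.5 corresponds to
    15 km when one unit is 10 km.  A missing pixel with no non-missing
    neighbor within the radius is an error.
    """
    values = np.asarray(values, dtype=float).copy()
    missing = np.flatnonzero(np.isnan(values))
    if missing.size == 0:
        return values
    centers = grid.pixel_centers
    filled = values.copy()
    for g in missing:
        d = np.hypot(centers[:, 0] - centers[g, 0], centers[:, 1] - centers[g, 1])
        nbr = (d <= radius) & ~np.isnan(values) & (d > 0)
        if not nbr.any():
            raise ValueError(
                f"pixel {g} has no non-missing neighbor within radius {radius}"
            )
        filled[g] = values[nbr].mean()
    return filled


def expected_density(beta: np.ndarray, X: np.ndarray, t: int) -> np.ndarray:
    """E(D[g, t]) = exp(sum_j beta_j X[j, g, t]); strictly positive, (G,)."""
    beta = np.asarray(beta, dtype=float)
    return np.exp(np.einsum("j,jg->g", beta, np.asarray(X)[:, :, t]))


def log_density_predictor(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(T, G) linear predictor sum_j beta_j X[j, g, t] for all periods."""
    return np.einsum("j,jgt->tg", np.asarray(beta, dtype=float), np.asarray(X))


def pi_density(beta: np.ndarray, X: np.ndarray, t: int) -> np.ndarray:
    """Activity-center pixel probabilities for period t (sums to 1)."""
    eta = np.einsum("j,jg->g", np.asarray(beta, dtype=float),
                    np.asarray(X)[:, :, t])
    return softmax(eta)


def sample_activity_centers(pi_density_t: np.ndarray, M: int,
                            rng: np.random.Generator) -> np.ndarray:
    """M i.i.d. categorical pixel indices from the density surface."""
    pi_density_t = np.asarray(pi_density_t, dtype=float)
    return rng.choice(pi_density_t.size, size=M, p=pi_density_t)


def realized_density(z: np.ndarray, s: np.ndarray, grid: StateSpaceGrid,
                     t: int) -> np.ndarray:
    """RD[g, t]: present activity centers in pixel g divided by pixel area.

    The area-weighted sum recovers abundance:
    sum_g RD[g, t] * side^2 = N_t.
    """
    z = np.asarray(z)
    s = np.asarray(s)
    counts = np.bincount(s[z[:, t] == 1, t], minlength=grid.G)
    return counts / grid.pixel_area
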