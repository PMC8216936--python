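"""Distance- and platform-dependent detection model.

Detection probability on a secondary occasion depends on ``mindist`` — the
distance from the individual's location to the closest point on the closest
surveyed transect — through a distance-sampling detection function chosen by
the nearest segment's platform:

    half-normal:  p = p0 * exp(-d^2 / (2 sigma_hn^2))
    hazard-rate:  p = p0 * (1 - exp(-(d / sigma_hr)^(-b))),  b > 1

Unlike conventional distance sampling, p0 (detection on the line) is an
estimable parameter, possibly differing by platform and demographic group;
the shape parameters (sigma, b) are shared across groups so the effect of
distance on detection is common.  The hazard-rate expression is undefined at
exactly d = 0 and is assigned its limit p0 there.

The observation model is y ~ Bernoulli(z * p): an individual can only be
detected while present, at most once per secondary occasion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import _as_segment_array, segment_point_distances

HALF_NORMAL = "hn"
HAZARD_RATE = "hr"


@dataclass
class DetectionParams:
    """Detection-function parameters.

    forms : per-platform family, each ``"hn"`` or ``"hr"``
    p0 : (P, V) baseline detection probability per platform and group
    sigma : (P,) scale per platform (only used by that platform's family)
    b : (P,) hazard-rate shape per platform (ignored for half-normal)
    """

    forms: tuple
    p0: np.ndarray
    sigma: np.ndarray
    b: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.p0 = np.atleast_2d(np.asarray(self.p0, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.b is None:
            self.b = np.full(len(self.forms), 2.0)
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if not all(f in (HALF_NORMAL, HAZARD_RATE) for f in self.forms):
            raise ValueError("detection forms must be 'hn' or 'hr'")
        if np.any(self.p0 < 0) or np.any(self.p0 > 1):
            raise ValueError("p0 must lie in [0, 1]")
        if np.any(self.sigma <= 0):
            raise ValueError("detection scales must be positive")
        hr = [i for i, f in enumerate(self.forms) if f == HAZARD_RATE]
        if any(self.b[i] <= 1 for i in hr):
            raise ValueError("hazard-rate shape b must exceed 1")

    @property
    def n_platforms(self) -> int:
        return len(self.forms)

    @property
    def n_groups(self) -> int:
        return self.p0.shape[1]


def p_halfnormal(mindist, p0, sigma) -> np.ndarray | float:
    """Half-normal detection function p0 * exp(-d^2 / (2 sigma^2))."""
    d = np.asarray(mindist, dtype=float)
    return p0 * np.exp(-0.5 * (d / sigma) ** 2)


def p_hazardrate(mindist, p0, sigma, b) -> np.ndarray | float:
    """Hazard-rate detection function p0 * (1 - exp(-(d/sigma)^(-b)));
    p(0) = p0 by continuity."""
    d = np.asarray(mindist, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        h = np.where(d > 0, (d / sigma) ** (-b), np.inf)
    out = p0 * (-np.expm1(-h))
    return out if out.ndim else float(out)


def detection_function(mindist, platform: int, params: DetectionParams,
                       group: int = 0) -> np.ndarray | float:
    """Evaluate the platform's detection function with the group's p0."""
    p0 = params.p0[platform, group]
    if params.forms[platform] == HALF_NORMAL:
        return p_halfnormal(mindist, p0, params.sigma[platform])
    return p_hazardrate(mindist, p0, params.sigma[platform], params.b[platform])


def detection_prob(x: float, y: float, segments, params: DetectionParams,
                   group: int = 0) -> float:
    """Detection probability for a location given the occasion's transects.

    Computes mindist over all segments, then applies the detection function
    of the *nearest* segment's platform.  An occasion with no surveyed
    segments offers no detection opportunity: probability 0.
    """
    coords, platforms = _as_segment_array(segments) if segments is not None \
        else (np.empty((0, 4)), np.empty(0, dtype=int))
    if coords.shape[0] == 0:
        return 0.0
    d = segment_point_distances(np.array([[x, y]]), coords)[0]
    idx = int(np.argmin(d))
    return float(detection_function(d[idx], int(platforms[idx]), params, group))


def observation_loglik(y, z, p) -> np.ndarray | float:
    """Bernoulli(z * p) log-mass of observations y.

    ``y = 1`` with ``z = 0`` has probability 0 and yields ``-inf`` — an
    inconsistent latent state that valid samplers never propose.
    """
    y = np.asarray(y, dtype=float)
    q = np.asarray(z, dtype=float) * np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        ll = np.where(y == 1, np.log(q), np.log1p(-q))
    return ll if ll.ndim else float(ll)
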