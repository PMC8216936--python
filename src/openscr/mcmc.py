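"""Metropolis-within-Gibbs sampler for the full hierarchical model.

Latent states (presence z, activity centers s, group membership, and —
under the default "latent" likelihood — per-occasion locations U of
undetected individuals) are updated by Gibbs or independence-Metropolis
steps; parameters are updated in random-walk Metropolis blocks with
proposal scales adapted during burn-in only (target acceptance 0.2-0.5),
then frozen, which preserves the stationary distribution.

Two observation-likelihood modes are available:

* ``latent`` (default, mirrors the BUGS-style formulation): a location
  U[i, k, t] is instantiated for every individual-occasion with y = 0 and
  refreshed by an independence proposal from the movement kernel accepted
  with ratio (1 - z p(U')) / (1 - z p(U)).
* ``marginal``: U is integrated out of the y = 0 likelihood,
  P(y=0 | s, z=1) = sum_g pi_movement[g] (1 - pbar[g]), where pbar[g]
  approximates the within-pixel average detection probability by an
  m x m quadrature over the pixel (m = 1 uses the pixel center).  This is
  the major runtime lever; the two modes agree up to the quadrature error.

Priors are uniform on all parameters (bounds configurable).  Convergence is
assessed with split-R-hat (threshold 1.1 by convention); because squared
covariate columns make individual habitat coefficients collinear, summaries
can also be computed on composed response curves rather than raw
coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import dynamics
from .density import CovariateStack
from .detection import (HALF_NORMAL, HAZARD_RATE, DetectionParams,
                        p_halfnormal, p_hazardrate)
from .geometry import StateSpaceGrid, segment_point_distances
from .io_cli import EncounterData, Study, SurveyDesign, augment
from .movement import squared_center_distances

__all__ = [
    "ModelConfig", "SamplerConfig", "ModelParams", "Priors", "Sampler",
    "PosteriorDraws", "fit", "gelman_rubin", "summarize",
    "brute_force_posterior", "sample_params_from_priors",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Structural switches of the fitted model."""

    V: int = 1
    mode: str = "latent"            # "latent" | "marginal"
    quad_m: int = 1                 # per-axis quadrature points for pbar
    p0_mode: str = "auto"           # "auto" | "crossed" | "additive"
    decouple_movement_beta: bool = False

    def resolved_p0_mode(self) -> str:
        if self.p0_mode != "auto":
            return self.p0_mode
        return "additive" if self.V > 1 else "crossed"


@dataclass
class SamplerConfig:
    """MCMC run settings (defaults follow common practice for this model
    family: 3 chains, 12,000 iterations, first half discarded)."""

    n_chains: int = 3
    n_iter: int = 12000
    n_burnin: int = 6000
    thin: int = 1
    adapt: bool = True
    adapt_interval: int = 25
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class ModelParams:
    """All estimable parameters (group-indexed rows where applicable)."""

    beta_gamma: np.ndarray          # (V, 3)
    beta_phi: np.ndarray            # (V, 2)
    beta_density: np.ndarray        # (J,)
    beta_move: np.ndarray           # (J,), equals beta_density when shared
    sigma_move: np.ndarray          # (V,)
    sigma_det: np.ndarray           # (P,)
    b_det: np.ndarray               # (P,)
    pi_group: np.ndarray            # (V,)
    p0: np.ndarray = None           # (P, V), crossed mode storage
    alpha_plat: np.ndarray = None   # (P,), additive mode
    alpha_group: np.ndarray = None  # (V-1,), additive mode

    def copy(self) -> "ModelParams":
        return ModelParams(**{
            k: (None if v is None else np.array(v, dtype=float, copy=True))
            for k, v in self.__dict__.items()
        })

    def p0_matrix(self) -> np.ndarray:
        """(P, V) baseline detection probabilities in either parameterization."""
        if self.alpha_plat is not None:
            off = np.concatenate([[0.0], np.atleast_1d(self.alpha_group)]) \
                if self.alpha_group is not None and self.alpha_group.size \
                else np.array([0.0])
            return expit(self.alpha_plat[:, None] + off[None, :])
        return self.p0

    def detection(self, forms) -> DetectionParams:
        return DetectionParams(forms=tuple(forms), p0=self.p0_matrix(),
                               sigma=self.sigma_det, b=self.b_det)


class Priors:
    """Uniform prior bounds per parameter block.

    Defaults: coefficients U(-10, 10); spatial scales U(~0, state-space
    diameter); hazard-rate shape U(1, 50); crossed p0 U(0, 1); additive
    detection offsets U(-10, 10).  Override any block via ``bounds``.
    """

    def __init__(self, diameter: float, bounds: dict | None = None):
        self.bounds = {
            "beta_gamma": (-10.0, 10.0),
            "beta_phi": (-10.0, 10.0),
            "beta_density": (-10.0, 10.0),
            "beta_move": (-10.0, 10.0),
            "sigma_move": (1e-3, diameter),
            "sigma_det": (1e-3, diameter),
            "b_det": (1.0, 50.0),
            "p0": (1e-6, 1.0),
            "alpha_plat": (-10.0, 10.0),
            "alpha_group": (-10.0, 10.0),
        }
        if bounds:
            self.bounds.update(bounds)

    def contains(self, name: str, value) -> bool:
        lo, hi = self.bounds[name]
        value = np.asarray(value)
        return bool(np.all((value >= lo) & (value <= hi)))

    def sample(self, name: str, shape, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds[name]
        return rng.uniform(lo, hi, size=shape)


def sample_params_from_priors(config: ModelConfig, J: int, P: int,
                              priors: Priors,
                              rng: np.random.Generator) -> ModelParams:
    """Draw a full parameter vector from the prior (used by simulation-based
    calibration checks of the sampler)."""
    V = config.V
    params = ModelParams(
        beta_gamma=priors.sample("beta_gamma", (V, 3), rng),
        beta_phi=priors.sample("beta_phi", (V, 2), rng),
        beta_density=priors.sample("beta_density", (J,), rng),
        beta_move=None,
        sigma_move=priors.sample("sigma_move", (V,), rng),
        sigma_det=priors.sample("sigma_det", (P,), rng),
        b_det=priors.sample("b_det", (P,), rng),
        pi_group=rng.dirichlet(np.ones(V)),
    )
    params.beta_move = (priors.sample("beta_move", (J,), rng)
                        if config.decouple_movement_beta
                        else params.beta_density.copy())
    if config.resolved_p0_mode() == "crossed":
        params.p0 = priors.sample("p0", (P, V), rng)
    else:
        params.alpha_plat = priors.sample("alpha_plat", (P,), rng)
        params.alpha_group = priors.sample("alpha_group", (max(V - 1, 0),), rng)
    return params


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _pixel_quadrature(grid: StateSpaceGrid, m: int) -> np.ndarray:
    """(G, Q, 2) quadrature points per pixel (m x m midpoint rule)."""
    offs = (np.arange(m) + 0.5) / m - 0.5
    ox, oy = np.meshgrid(offs, offs)
    pts = np.column_stack([ox.ravel(), oy.ravel()]) * grid.side  # (Q, 2)
    return grid.pixel_centers[:, None, :] + pts[None, :, :]


def _shape_fn(form: str, sigma: float, b: float, d: np.ndarray) -> np.ndarray:
    """Detection function with p0 factored out."""
    if form == HALF_NORMAL:
        return p_halfnormal(d, 1.0, sigma)
    return p_hazardrate(d, 1.0, sigma, b)


class Sampler:
    """One MCMC chain over parameters and latent states.

    Parameters
    ----------
    study : Study
        Loaded (or simulated) study data; encounters need not be augmented.
    M : int
        Augmented population size.
    config, priors, sampler_config
        Model structure, uniform prior bounds, and run settings.
    init_params, init_latents
        Optional starting values (e.g., truth for calibration checks).
    sample_blocks
        Iterable restricting which parameter blocks are updated; ``None``
        updates all, ``()`` fixes all parameters (latent states still move).
    """

    PARAM_BLOCKS = ("dynamics", "beta_density", "beta_move", "sigma_move",
                    "detection", "group_prob")

    def __init__(self, study: Study, M: int, config: ModelConfig,
                 priors: Priors | None = None,
                 sampler_config: SamplerConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 init_params: ModelParams | None = None,
                 init_latents: dict | None = None,
                 sample_blocks=None,
                 update_latents: bool = True):
        self.rng = (rng if isinstance(rng, np.random.Generator)
                    else np.random.default_rng(rng))
        self.config = config
        self.scfg = sampler_config or SamplerConfig()
        self.grid: StateSpaceGrid = study.grid
        self.design: SurveyDesign = study.design
        self.stack: CovariateStack = study.covariates
        enc = study.encounters
        if enc.M < M:
            enc = augment(enc, M)
        elif enc.M != M:
            raise ValueError("encounter data rows exceed M")
        self.enc: EncounterData = enc
        self.M, self.T, self.V = M, study.design.T, config.V
        self.G, self.J = self.grid.G, self.stack.J
        self.P = study.design.n_platforms
        self.forms = None  # set below
        self.priors = priors or Priors(self.grid.diameter)
        if sample_blocks is None:
            sample_blocks = self.PARAM_BLOCKS
        self.sample_blocks = tuple(sample_blocks)
        self.update_latents = update_latents

        self._setup_static(study)
        self.params = (init_params.copy() if init_params is not None
                       else self._init_params())
        self._init_state(init_latents)
        self._refresh_density_cache()
        self._refresh_move_cache()
        self._refresh_det_cache()
        self._setup_scales()

    # -- static precomputation ---------------------------------------------

    def _setup_static(self, study: Study) -> None:
        design = self.design
        self.time = dynamics.standardize_time(self.T)
        self.D2 = squared_center_distances(self.grid)
        self.forms = tuple(design.platform_forms)
        self.occasions = [(t, k) for t, k in design.occasions()
                          if design.has_effort(t, k)]
        self.occ_index = {tk: o for o, tk in enumerate(self.occasions)}
        self.n_occ = len(self.occasions)
        # quadrature geometry per occasion
        m = self.config.quad_m
        qxy = _pixel_quadrature(self.grid, m)          # (G, Q, 2)
        self.Q = qxy.shape[1]
        self.qdist = np.empty((self.n_occ, self.G, self.Q))
        self.qplat = np.empty((self.n_occ, self.G, self.Q), dtype=int)
        for o, (t, k) in enumerate(self.occasions):
            coords = design.seg_coords(t, k)
            d = segment_point_distances(qxy.reshape(-1, 2), coords)
            near = d.argmin(axis=1)
            self.qdist[o] = d[np.arange(d.shape[0]), near].reshape(self.G, self.Q)
            self.qplat[o] = design.seg_platforms(t, k)[near].reshape(self.G, self.Q)
        # detected-occasion tables
        enc = self.enc
        i_det, t_det, k_det = np.nonzero(enc.y == 1)
        self.det_i, self.det_t, self.det_k = i_det, t_det, k_det
        self.det_o = np.array([self.occ_index[(t, k)]
                               for t, k in zip(t_det, k_det)], dtype=int)
        xs = enc.obs_x[i_det, t_det, k_det]
        ys = enc.obs_y[i_det, t_det, k_det]
        self.det_upix = (self.grid.pixel_of_point(xs, ys)
                         if i_det.size else np.empty(0, int))
        self.det_dist = np.empty(i_det.size)
        self.det_plat = np.empty(i_det.size, dtype=int)
        for j, (t, k, x, y) in enumerate(zip(t_det, k_det, xs, ys)):
            d = segment_point_distances(np.array([[x, y]]),
                                        design.seg_coords(t, k))[0]
            near = int(np.argmin(d))
            self.det_dist[j] = d[near]
            self.det_plat[j] = design.seg_platforms(t, k)[near]
        self.detected_period = enc.detected_in_period()  # (M, T) bool
        self.obs_upix = np.full((self.M, self.T, design.K_max), -1, dtype=int)
        self.obs_upix[i_det, t_det, k_det] = self.det_upix
        # per-occasion bookkeeping
        self.y = np.asarray(enc.y)
        self.occ_by_t = [[] for _ in range(self.T)]
        for o, (t, k) in enumerate(self.occasions):
            self.occ_by_t[t].append(o)
        # latent-location slots: every effort occasion with y = 0
        self.lat_mask = np.zeros((self.M, self.T, self.design.K_max), bool)
        for o, (t, k) in enumerate(self.occasions):
            self.lat_mask[:, t, k] = self.y[:, t, k] == 0

    def _init_params(self) -> ModelParams:
        rng, V, J, P = self.rng, self.V, self.J, self.P
        jit = lambda s, size=None: rng.normal(0.0, s, size=size)
        bg = np.column_stack([np.full(V, -1.0) + jit(0.3, V),
                              jit(0.2, V), jit(0.2, V)])
        bp = np.column_stack([np.full(V, 1.0) + jit(0.3, V), jit(0.2, V)])
        beta = jit(0.2, J)
        params = ModelParams(
            beta_gamma=bg, beta_phi=bp,
            beta_density=beta,
            beta_move=(jit(0.2, J) if self.config.decouple_movement_beta
                       else beta.copy()),
            sigma_move=np.full(V, self.grid.diameter / 8.0)
            * np.exp(jit(0.2, V)),
            sigma_det=np.full(P, self.grid.diameter / 10.0)
            * np.exp(jit(0.2, P)),
            b_det=np.full(P, 2.5) + np.abs(jit(0.3, P)),
            pi_group=np.full(V, 1.0 / V),
        )
        if self.config.resolved_p0_mode() == "crossed":
            params.p0 = np.clip(0.7 + jit(0.1, (P, V)), 0.05, 0.95)
        else:
            params.alpha_plat = logit(np.clip(0.7 + jit(0.1, P), 0.05, 0.95))
            params.alpha_group = jit(0.2, max(V - 1, 0))
        return params

    def _init_state(self, init_latents: dict | None) -> None:
        rng = self.rng
        M, T, G = self.M, self.T, self.G
        if init_latents is not None:
            self.z = np.array(init_latents["z"], dtype=np.int8, copy=True)
            self.s = np.array(init_latents["s"], dtype=int, copy=True)
            self.group = np.array(init_latents["group"], dtype=int, copy=True)
        else:
            self.z = self.detected_period.astype(np.int8).copy()
            free = ~self.detected_period
            self.z[free] = (rng.random(free.sum()) < 0.3).astype(np.int8)
            self.s = rng.integers(0, G, size=(M, T))
            # anchor s at a detection pixel where one exists
            for j in np.argsort(self.det_i):
                self.s[self.det_i[j], self.det_t[j]] = self.det_upix[j]
            self.group = np.where(self.enc.group >= 0, self.enc.group,
                                  rng.integers(0, self.V, M))
        self.known_group = self.enc.group >= 0
        self.z[self.detected_period] = 1
        # latent locations (latent mode): init from the movement prior
        self.U_pix = np.full((M, T, self.design.K_max), -1, dtype=int)
        self.lat_dist = np.zeros((M, T, self.design.K_max))
        self.lat_plat = np.zeros((M, T, self.design.K_max), dtype=int)
        if self.config.mode == "latent":
            self._prior_draw_latents()
            if init_latents is not None and "U_pix" in init_latents:
                # overwrite with provided locations where they exist
                for o, (t, k) in enumerate(self.occasions):
                    prov = init_latents["U_pix"][:, t, k]
                    sel = self.lat_mask[:, t, k] & (prov >= 0)
                    if not sel.any():
                        continue
                    idx = np.flatnonzero(sel)
                    self.U_pix[idx, t, k] = prov[idx]
                    ux = init_latents["U_x"][idx, t, k]
                    uy = init_latents["U_y"][idx, t, k]
                    self._set_latent_geometry(t, k, idx, ux, uy)

    def _set_latent_geometry(self, t, k, idx, ux, uy) -> None:
        coords = self.design.seg_coords(t, k)
        d = segment_point_distances(np.column_stack([ux, uy]), coords)
        near = d.argmin(axis=1)
        self.lat_dist[idx, t, k] = d[np.arange(len(idx)), near]
        self.lat_plat[idx, t, k] = self.design.seg_platforms(t, k)[near]

    def _prior_draw_latents(self) -> None:
        """Initialize latent U by drawing pixels uniformly + uniform x, y."""
        rng = self.rng
        half = self.grid.side / 2.0
        for o, (t, k) in enumerate(self.occasions):
            idx = np.flatnonzero(self.lat_mask[:, t, k])
            g = rng.integers(0, self.G, size=idx.size)
            cx, cy = self.grid.pixel_centers[g].T
            ux = rng.uniform(cx - half, cx + half)
            uy = rng.uniform(cy - half, cy + half)
            self.U_pix[idx, t, k] = g
            self._set_latent_geometry(t, k, idx, ux, uy)

    # -- parameter-dependent caches ----------------------------------------

    def _refresh_density_cache(self) -> None:
        eta = np.einsum("j,jgt->tg", self.params.beta_density, self.stack.X)
        eta = eta - eta.max(axis=1, keepdims=True)
        self.WD = np.exp(eta)
        self.log_pi_density = eta - np.log(self.WD.sum(axis=1, keepdims=True))

    def _refresh_move_cache(self) -> None:
        beta_m = (self.params.beta_density
                  if not self.config.decouple_movement_beta
                  else self.params.beta_move)
        eta = np.einsum("j,jgt->tg", beta_m, self.stack.X)
        eta = eta - eta.max(axis=1, keepdims=True)
        self.logWM = eta
        self.WM = np.exp(eta)
        self.logK = np.empty((self.V, self.G, self.G))
        self.Kmat = np.empty((self.V, self.G, self.G))
        for v in range(self.V):
            self.logK[v] = -0.5 * self.D2 / self.params.sigma_move[v] ** 2
            self.Kmat[v] = np.exp(self.logK[v])
        self.norm = np.einsum("vab,tb->vta", self.Kmat, self.WM)
        self.lognorm = np.log(self.norm)

    def _refresh_det_cache(self) -> None:
        p0 = self.params.p0_matrix()
        sig, b = self.params.sigma_det, self.params.b_det
        # detected occasions: shape (distance part) and platform index
        self.det_shape = np.empty(self.det_i.size)
        for p in range(self.P):
            sel = self.det_plat == p
            if sel.any():
                self.det_shape[sel] = _shape_fn(self.forms[p], sig[p], b[p],
                                                self.det_dist[sel])
        self._p0 = p0
        if self.config.mode == "marginal":
            # within-pixel average detection probability per group/occasion
            shape_q = np.empty_like(self.qdist)
            for p in range(self.P):
                sel = self.qplat == p
                shape_q[sel] = _shape_fn(self.forms[p], sig[p], b[p],
                                         self.qdist[sel])
            p0_q = p0[self.qplat]                      # (O, G, Q, V)
            self.pbar = np.einsum("ogqv,ogq->vog", p0_q, shape_q) / self.Q
            A = np.empty((self.V, self.n_occ, self.G))
            for o, (t, k) in enumerate(self.occasions):
                w = self.WM[t][None, :] * (1.0 - self.pbar[:, o, :])  # (V, G)
                A[:, o, :] = np.einsum("vab,vb->va", self.Kmat, w)
            with np.errstate(divide="ignore"):
                self.log_m0 = np.log(A)
            for o, (t, k) in enumerate(self.occasions):
                self.log_m0[:, o, :] -= self.lognorm[:, t, :]
        else:
            # latent mode: detection shape at current latent locations
            self.lat_shape = np.zeros_like(self.lat_dist)
            for o, (t, k) in enumerate(self.occasions):
                idx = np.flatnonzero(self.lat_mask[:, t, k])
                d = self.lat_dist[idx, t, k]
                pl = self.lat_plat[idx, t, k]
                sh = np.empty(idx.size)
                for p in range(self.P):
                    sel = pl == p
                    if sel.any():
                        sh[sel] = _shape_fn(self.forms[p], sig[p], b[p], d[sel])
                self.lat_shape[idx, t, k] = sh

    def _move_det_caches(self):
        keys = ["logWM", "WM", "logK", "Kmat", "norm", "lognorm",
                "det_shape", "_p0"]
        if self.config.mode == "marginal":
            keys += ["pbar", "log_m0"]
        else:
            keys += ["lat_shape"]
        return {k: getattr(self, k) for k in keys}

    # -- log-likelihood components -----------------------------------------

    def _schedules(self, params: ModelParams | None = None):
        params = params or self.params
        gam = dynamics.gamma_schedule(params.beta_gamma, self.time)
        phi = dynamics.phi_schedule(params.beta_phi, self.time)
        return np.atleast_2d(gam), np.atleast_2d(phi)

    def _ll_z_group(self, v: int, gam_v: np.ndarray, phi_v: np.ndarray) -> float:
        idx = self.group == v
        z = self.z[idx]
        if z.size == 0:
            return 0.0
        n1 = z[:, 0].sum()
        ll = n1 * np.log(gam_v[0]) + (z.shape[0] - n1) * np.log1p(-gam_v[0])
        for t in range(1, self.T):
            prev, cur = z[:, t - 1], z[:, t]
            a11 = int(((prev == 1) & (cur == 1)).sum())
            a10 = int(((prev == 1) & (cur == 0)).sum())
            a01 = int(((prev == 0) & (cur == 1)).sum())
            a00 = int(((prev == 0) & (cur == 0)).sum())
            ll += (a11 * np.log(phi_v[t - 1]) + a10 * np.log1p(-phi_v[t - 1])
                   + a01 * np.log(gam_v[t]) + a00 * np.log1p(-gam_v[t]))
        return float(ll)

    def _ll_s(self) -> float:
        return float(self.log_pi_density[np.arange(self.T)[None, :]
                                         .repeat(self.M, 0), self.s].sum())

    def _ll_move(self) -> float:
        """Movement terms for occasions with an instantiated location."""
        ll = 0.0
        v = self.group
        if self.det_i.size:
            si = self.s[self.det_i, self.det_t]
            ll += (self.logK[v[self.det_i], si, self.det_upix]
                   + self.logWM[self.det_t, self.det_upix]
                   - self.lognorm[v[self.det_i], self.det_t, si]).sum()
        if self.config.mode == "latent":
            for o, (t, k) in enumerate(self.occasions):
                idx = np.flatnonzero(self.lat_mask[:, t, k])
                si = self.s[idx, t]
                u = self.U_pix[idx, t, k]
                ll += (self.logK[v[idx], si, u] + self.logWM[t, u]
                       - self.lognorm[v[idx], t, si]).sum()
        return float(ll)

    def _ll_marg(self) -> float:
        """Marginalized P(y=0 | z=1, s) over undetected effort occasions."""
        ll = 0.0
        for o, (t, k) in enumerate(self.occasions):
            idx = np.flatnonzero((self.z[:, t] == 1) & self.lat_mask[:, t, k])
            ll += self.log_m0[self.group[idx], o, self.s[idx, t]].sum()
        return float(ll)

    def _ll_det(self) -> float:
        """Bernoulli observation terms at instantiated locations."""
        ll = 0.0
        if self.det_i.size:
            with np.errstate(divide="ignore"):
                # underflowing detection shapes yield -inf (proposal rejected)
                ll += np.log(self._p0[self.det_plat, self.group[self.det_i]]
                             * self.det_shape).sum()
        if self.config.mode == "latent":
            for o, (t, k) in enumerate(self.occasions):
                idx = np.flatnonzero((self.z[:, t] == 1)
                                     & self.lat_mask[:, t, k])
                p = (self._p0[self.lat_plat[idx, t, k], self.group[idx]]
                     * self.lat_shape[idx, t, k])
                ll += np.log1p(-p).sum()
        return float(ll)

    # -- latent-state updates ----------------------------------------------

    def _period_loglik_given_present(self) -> np.ndarray:
        """(M, T) log P(observations in period t | z=1, current latents)."""
        out = np.zeros((self.M, self.T))
        if self.config.mode == "marginal":
            for o, (t, k) in enumerate(self.occasions):
                sel = self.lat_mask[:, t, k]
                out[sel, t] += self.log_m0[self.group[sel], o,
                                           self.s[sel, t]]
        else:
            for o, (t, k) in enumerate(self.occasions):
                sel = self.lat_mask[:, t, k]
                p = (self._p0[self.lat_plat[sel, t, k], self.group[sel]]
                     * self.lat_shape[sel, t, k])
                out[sel, t] += np.log1p(-p)
        return out

    def _update_z(self) -> None:
        gam, phi = self._schedules()
        gam_i = gam[self.group]      # (M, T)
        phi_i = phi[self.group]
        llp = self._period_loglik_given_present()
        L1 = np.exp(llp)  # llp <= 0, no overflow possible
        for t in range(self.T):
            free = ~self.detected_period[:, t]
            if not free.any():
                continue
            c1 = (gam_i[:, t] if t == 0 else
                  np.where(self.z[:, t - 1] == 1, phi_i[:, t - 1], gam_i[:, t]))
            w1 = c1 * L1[:, t]
            w0 = 1.0 - c1
            if t < self.T - 1:
                znext = self.z[:, t + 1]
                f1 = np.where(znext == 1, phi_i[:, t], 1.0 - phi_i[:, t])
                f0 = np.where(znext == 1, gam_i[:, t + 1], 1.0 - gam_i[:, t + 1])
                w1, w0 = w1 * f1, w0 * f0
            prob1 = w1 / (w1 + w0)
            draw = (self.rng.random(self.M) < prob1).astype(np.int8)
            self.z[free, t] = draw[free]

    def _update_s(self) -> None:
        """Gibbs draw of activity centers, one period at a time.

        Under the latent mode every instantiated location (detected or
        latent, present or not) contributes a movement term, matching the
        joint in which U exists for every individual-occasion; under the
        marginal mode only present individuals carry data terms.
        """
        for t in range(self.T):
            logw = np.tile(self.log_pi_density[t], (self.M, 1))
            present = self.z[:, t] == 1
            for v in range(self.V):
                gsel = self.group == v
                if not gsel.any():
                    continue
                nterm = np.zeros(self.M)
                for o in self.occ_by_t[t]:
                    _, k = self.occasions[o]
                    det = gsel & (self.y[:, t, k] == 1)
                    if det.any():
                        u = self.obs_upix[det, t, k]
                        logw[det] += self.logK[v][:, u].T
                        nterm[det] += 1.0
                    if self.config.mode == "marginal":
                        und = gsel & present & self.lat_mask[:, t, k]
                        if und.any():
                            logw[und] += self.log_m0[v, o][None, :]
                    else:
                        und = gsel & self.lat_mask[:, t, k]
                        if und.any():
                            u = self.U_pix[und, t, k]
                            logw[und] += self.logK[v][:, u].T
                            nterm[und] += 1.0
                has = gsel & (nterm > 0)
                logw[has] -= nterm[has, None] * self.lognorm[v, t][None, :]
            gum = -np.log(-np.log(self.rng.random((self.M, self.G))))
            self.s[:, t] = np.argmax(logw + gum, axis=1)

    def _update_latent_locations(self) -> None:
        """Independence-Metropolis refresh of U from the movement kernel."""
        rng = self.rng
        half = self.grid.side / 2.0
        sig, b = self.params.sigma_det, self.params.b_det
        for o, (t, k) in enumerate(self.occasions):
            idx = np.flatnonzero(self.lat_mask[:, t, k])
            if idx.size == 0:
                continue
            v = self.group[idx]
            logmu = (self.logK[v, self.s[idx, t], :]
                     + self.logWM[t][None, :])
            gum = -np.log(-np.log(rng.random((idx.size, self.G))))
            gprop = np.argmax(logmu + gum, axis=1)
            cx, cy = self.grid.pixel_centers[gprop].T
            ux = rng.uniform(cx - half, cx + half)
            uy = rng.uniform(cy - half, cy + half)
            coords = self.design.seg_coords(t, k)
            d = segment_point_distances(np.column_stack([ux, uy]), coords)
            near = d.argmin(axis=1)
            dmin = d[np.arange(idx.size), near]
            plat = self.design.seg_platforms(t, k)[near]
            shp = np.empty(idx.size)
            for p in range(self.P):
                selp = plat == p
                if selp.any():
                    shp[selp] = _shape_fn(self.forms[p], sig[p], b[p],
                                          dmin[selp])
            p_new = self._p0[plat, v] * shp
            p_old = (self._p0[self.lat_plat[idx, t, k], v]
                     * self.lat_shape[idx, t, k])
            z1 = self.z[idx, t] == 1
            ratio = np.where(z1, (1.0 - p_new) / (1.0 - p_old), 1.0)
            acc = rng.random(idx.size) < ratio
            ai = idx[acc]
            self.U_pix[ai, t, k] = gprop[acc]
            self.lat_dist[ai, t, k] = dmin[acc]
            self.lat_plat[ai, t, k] = plat[acc]
            self.lat_shape[ai, t, k] = shp[acc]

    def _per_individual_group_loglik(self) -> np.ndarray:
        """(M, V) log-likelihood of each individual's data under each group."""
        M, V = self.M, self.V
        gam, phi = self._schedules()
        ll = np.zeros((M, V))
        for v in range(V):
            g, p = gam[v], phi[v]
            lp = np.where(self.z[:, 0] == 1, np.log(g[0]), np.log1p(-g[0]))
            for t in range(1, self.T):
                prev, cur = self.z[:, t - 1], self.z[:, t]
                tp = np.where(prev == 1,
                              np.where(cur == 1, np.log(p[t - 1]),
                                       np.log1p(-p[t - 1])),
                              np.where(cur == 1, np.log(g[t]),
                                       np.log1p(-g[t])))
                lp = lp + tp
            ll[:, v] = lp
        # movement + detection terms (group-specific kernel and p0)
        for v in range(V):
            contrib = np.zeros(M)
            if self.det_i.size:
                si = self.s[self.det_i, self.det_t]
                terms = (self.logK[v, si, self.det_upix]
                         - self.lognorm[v, self.det_t, si]
                         + np.log(self._p0[self.det_plat, v] * self.det_shape))
                np.add.at(contrib, self.det_i, terms)
            for o, (t, k) in enumerate(self.occasions):
                if self.config.mode == "marginal":
                    idx = np.flatnonzero((self.z[:, t] == 1)
                                         & self.lat_mask[:, t, k])
                    if idx.size:
                        contrib[idx] += self.log_m0[v, o, self.s[idx, t]]
                else:
                    idx = np.flatnonzero(self.lat_mask[:, t, k])
                    if idx.size:
                        u = self.U_pix[idx, t, k]
                        contrib[idx] += (self.logK[v, self.s[idx, t], u]
                                         - self.lognorm[v, t, self.s[idx, t]])
                        z1 = idx[self.z[idx, t] == 1]
                        p = self._p0[self.lat_plat[z1, t, k], v] \
                            * self.lat_shape[z1, t, k]
                        contrib[z1] += np.log1p(-p)
            ll[:, v] += contrib
        return ll

    def _update_groups(self) -> None:
        if self.V == 1:
            return
        unknown = np.flatnonzero(~self.known_group)
        if unknown.size:
            ll = self._per_individual_group_loglik()[unknown]
            logw = ll + np.log(self.params.pi_group)[None, :]
            gum = -np.log(-np.log(self.rng.random(logw.shape)))
            self.group[unknown] = np.argmax(logw + gum, axis=1)
        counts = np.bincount(self.group, minlength=self.V)
        if "group_prob" in self.sample_blocks:
            self.params.pi_group = self.rng.dirichlet(1.0 + counts)

    # -- parameter updates --------------------------------------------------

    def _setup_scales(self) -> None:
        self.scales = {
            "dynamics": np.full(5, 0.3),
            "beta_density": np.full(self.J, 0.08),
            "beta_move": np.full(self.J, 0.08),
            "sigma_move": np.full(1, 0.08),
            "detection": None,
        }
        nfree = self._det_free_vector().size
        self.scales["detection"] = np.full(nfree, 0.08)
        self._acc = {k: [0, 0] for k in
                     ("dynamics", "beta_density", "beta_move", "sigma_move",
                      "detection")}

    def _adapt(self, name: str) -> None:
        acc, tot = self._acc[name]
        if tot == 0:
            return
        rate = acc / tot
        self.scales[name] = np.clip(
            self.scales[name] * np.exp(1.2 * (rate - self.scfg.target_accept)),
            1e-4, 10.0)
        self._acc[name] = [0, 0]

    def _mh(self, name: str, logratio: float) -> bool:
        self._acc[name][1] += 1
        ok = np.log(self.rng.random()) < logratio
        if ok:
            self._acc[name][0] += 1
        return bool(ok)

    def _update_dynamics(self) -> None:
        gam, phi = self._schedules()
        for v in range(self.V):
            cur = np.concatenate([self.params.beta_gamma[v],
                                  self.params.beta_phi[v]])
            prop = cur + self.rng.normal(size=5) * self.scales["dynamics"]
            if not (self.priors.contains("beta_gamma", prop[:3])
                    and self.priors.contains("beta_phi", prop[3:])):
                self._acc["dynamics"][1] += 1
                continue
            gam_p = dynamics.gamma_t(prop[:3], self.time)
            phi_p = dynamics.phi_t(prop[3:], self.time)
            ll_old = self._ll_z_group(v, gam[v], phi[v])
            ll_new = self._ll_z_group(v, gam_p, phi_p)
            if self._mh("dynamics", ll_new - ll_old):
                self.params.beta_gamma[v] = prop[:3]
                self.params.beta_phi[v] = prop[3:]
                gam, phi = self._schedules()

    def _movement_ll(self) -> float:
        if self.config.mode == "marginal":
            return self._ll_move() + self._ll_marg()
        return self._ll_move()

    def _update_beta_density(self) -> None:
        shared = not self.config.decouple_movement_beta
        cur = self.params.beta_density.copy()
        prop = cur + self.rng.normal(size=self.J) * self.scales["beta_density"]
        if not self.priors.contains("beta_density", prop):
            self._acc["beta_density"][1] += 1
            return
        ll_old = self._ll_s() + (self._movement_ll() if shared else 0.0)
        saved_d = (self.WD, self.log_pi_density)
        saved_m = self._move_det_caches() if shared else None
        self.params.beta_density = prop
        self._refresh_density_cache()
        if shared:
            self._refresh_move_cache()
            if self.config.mode == "marginal":
                self._refresh_det_cache()
        ll_new = self._ll_s() + (self._movement_ll() if shared else 0.0)
        if not self._mh("beta_density", ll_new - ll_old):
            self.params.beta_density = cur
            self.WD, self.log_pi_density = saved_d
            if shared:
                for k_, v_ in saved_m.items():
                    setattr(self, k_, v_)

    def _update_beta_move(self) -> None:
        if not self.config.decouple_movement_beta:
            return
        cur = self.params.beta_move.copy()
        prop = cur + self.rng.normal(size=self.J) * self.scales["beta_move"]
        if not self.priors.contains("beta_move", prop):
            self._acc["beta_move"][1] += 1
            return
        ll_old = self._movement_ll()
        saved = self._move_det_caches()
        self.params.beta_move = prop
        self._refresh_move_cache()
        if self.config.mode == "marginal":
            self._refresh_det_cache()
        ll_new = self._movement_ll()
        if not self._mh("beta_move", ll_new - ll_old):
            self.params.beta_move = cur
            for k_, v_ in saved.items():
                setattr(self, k_, v_)

    def _update_sigma_move(self) -> None:
        for v in range(self.V):
            cur = float(self.params.sigma_move[v])
            prop = cur + self.rng.normal() * float(self.scales["sigma_move"][0])
            if not self.priors.contains("sigma_move", prop):
                self._acc["sigma_move"][1] += 1
                continue
            ll_old = self._movement_ll()
            saved = self._move_det_caches()
            self.params.sigma_move[v] = prop
            self._refresh_move_cache()
            if self.config.mode == "marginal":
                self._refresh_det_cache()
            ll_new = self._movement_ll()
            if not self._mh("sigma_move", ll_new - ll_old):
                self.params.sigma_move[v] = cur
                for k_, v_ in saved.items():
                    setattr(self, k_, v_)

    def _det_free_vector(self) -> np.ndarray:
        p = self.params
        parts = []
        if self.config.resolved_p0_mode() == "crossed":
            parts.append(p.p0.ravel())
        else:
            parts += [p.alpha_plat, p.alpha_group]
        parts.append(p.sigma_det)
        parts.append(np.array([p.b_det[i] for i in range(self.P)
                               if self.forms[i] == HAZARD_RATE]))
        return np.concatenate([np.atleast_1d(x) for x in parts if x is not None
                               and np.atleast_1d(x).size])

    def _set_det_free_vector(self, vec: np.ndarray) -> bool:
        """Write the free detection vector back; returns prior-support flag."""
        p = self.params
        pos = 0
        ok = True
        if self.config.resolved_p0_mode() == "crossed":
            n = p.p0.size
            block = vec[pos:pos + n].reshape(p.p0.shape)
            ok &= self.priors.contains("p0", block)
            p.p0 = block
            pos += n
        else:
            n = p.alpha_plat.size
            ok &= self.priors.contains("alpha_plat", vec[pos:pos + n])
            p.alpha_plat = vec[pos:pos + n].copy()
            pos += n
            n = p.alpha_group.size
            if n:
                ok &= self.priors.contains("alpha_group", vec[pos:pos + n])
                p.alpha_group = vec[pos:pos + n].copy()
                pos += n
        n = p.sigma_det.size
        ok &= self.priors.contains("sigma_det", vec[pos:pos + n])
        p.sigma_det = vec[pos:pos + n].copy()
        pos += n
        for i in range(self.P):
            if self.forms[i] == HAZARD_RATE:
                ok &= self.priors.contains("b_det", vec[pos])
                p.b_det[i] = vec[pos]
                pos += 1
        return ok

    def _detection_ll(self) -> float:
        return self._ll_det() + (self._ll_marg()
                                 if self.config.mode == "marginal" else 0.0)

    def _update_detection(self) -> None:
        cur = self._det_free_vector()
        prop = cur + self.rng.normal(size=cur.size) * self.scales["detection"]
        saved_params = self.params.copy()
        saved = self._move_det_caches()
        ll_old = self._detection_ll()
        if not self._set_det_free_vector(prop):
            self.params = saved_params
            self._acc["detection"][1] += 1
            return
        self._refresh_det_cache()
        ll_new = self._detection_ll()
        if not self._mh("detection", ll_new - ll_old):
            self.params = saved_params
            for k_, v_ in saved.items():
                setattr(self, k_, v_)

    # -- main loop -----------------------------------------------------------

    def sweep(self, adapt: bool = False) -> None:
        """One full pass over latent states and parameter blocks."""
        if self.update_latents:
            if self.config.mode == "latent":
                self._update_latent_locations()
            self._update_z()
            self._update_s()
            self._update_groups()
        if "dynamics" in self.sample_blocks:
            self._update_dynamics()
        if "beta_density" in self.sample_blocks:
            self._update_beta_density()
        if "beta_move" in self.sample_blocks:
            self._update_beta_move()
        if "sigma_move" in self.sample_blocks:
            self._update_sigma_move()
        if "detection" in self.sample_blocks:
            self._update_detection()
        self._iter = getattr(self, "_iter", 0) + 1
        if adapt and self._iter % self.scfg.adapt_interval == 0:
            for name in self._acc:
                self._adapt(name)

    # -- monitoring ----------------------------------------------------------

    def monitor_names(self) -> list:
        names = []
        for v in range(self.V):
            names += [f"beta_gamma[{v},{j}]" for j in range(3)]
            names += [f"beta_phi[{v},{j}]" for j in range(2)]
        names += [f"beta[{j}]" for j in range(self.J)]
        if self.config.decouple_movement_beta:
            names += [f"beta_move[{j}]" for j in range(self.J)]
        names += [f"sigma_move[{v}]" for v in range(self.V)]
        for p in range(self.P):
            names += [f"p0[{p},{v}]" for v in range(self.V)]
        names += [f"sigma_det[{p}]" for p in range(self.P)]
        names += [f"b_det[{p}]" for p in range(self.P)
                  if self.forms[p] == HAZARD_RATE]
        if self.V > 1:
            names += [f"pi_group[{v}]" for v in range(self.V)]
        names += [f"N[{t}]" for t in range(self.T)]
        if self.V > 1:
            for v in range(self.V):
                names += [f"N[{v},{t}]" for t in range(self.T)]
        names += [f"R[{t}]" for t in range(self.T)]
        names += ["N_super"]
        if self.V > 1:
            names += [f"N_super[{v}]" for v in range(self.V)]
        return names

    def monitor_values(self) -> np.ndarray:
        p = self.params
        vals = []
        for v in range(self.V):
            vals += list(p.beta_gamma[v]) + list(p.beta_phi[v])
        vals += list(p.beta_density)
        if self.config.decouple_movement_beta:
            vals += list(p.beta_move)
        vals += list(p.sigma_move)
        p0 = p.p0_matrix()
        for pi in range(self.P):
            vals += list(p0[pi])
        vals += list(p.sigma_det)
        vals += [p.b_det[pi] for pi in range(self.P)
                 if self.forms[pi] == HAZARD_RATE]
        if self.V > 1:
            vals += list(p.pi_group)
        N = dynamics.derive_abundance(self.z)
        vals += list(N)
        if self.V > 1:
            for v in range(self.V):
                vals += list(dynamics.derive_abundance(self.z[self.group == v]))
        vals += list(dynamics.derive_recruits(self.z))
        vals += [dynamics.superpopulation_size(self.z)]
        if self.V > 1:
            vals += [dynamics.superpopulation_size(self.z[self.group == v])
                     for v in range(self.V)]
        return np.array(vals, dtype=float)

    def realized_density_draw(self) -> np.ndarray:
        """(T, G) realized density of the current state."""
        out = np.zeros((self.T, self.G))
        for t in range(self.T):
            counts = np.bincount(self.s[self.z[:, t] == 1, t],
                                 minlength=self.G)
            out[t] = counts / self.grid.pixel_area
        return out


# ---------------------------------------------------------------------------
# Posterior container, diagnostics, and the fit() driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws: (n_chains, n_kept, n_names)."""

    names: list
    draws: np.ndarray
    rd_mean: np.ndarray = None     # (T, G) posterior-mean realized density
    acceptance: dict = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def summary(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        out = pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": np.percentile(flat, 2.5, axis=0),
            "q97.5": np.percentile(flat, 97.5, axis=0),
        }, index=self.names)
        if self.n_chains >= 2:
            out["rhat"] = [gelman_rubin(self.draws[:, :, j])
                           for j in range(len(self.names))]
        return out

    def to_csv(self, path) -> None:
        """Long format: chain, iteration, name, value."""
        C, N, P = self.draws.shape
        df = pd.DataFrame({
            "chain": np.repeat(np.arange(C), N * P) + 1,
            "iteration": np.tile(np.repeat(np.arange(N), P), C) + 1,
            "name": np.tile(self.names, C * N),
            "value": self.draws.ravel(),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        names = list(df.loc[df.chain.eq(df.chain.min())
                            & df.iteration.eq(df.iteration.min()), "name"])
        C = df.chain.nunique()
        N = df.iteration.nunique()
        draws = df.value.to_numpy().reshape(C, N, len(names))
        return cls(names=names, draws=draws)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (split-R-hat).

    ``chains`` is (n_chains, n_draws); each chain is split in half, giving
    2C sequences whose between/within variance ratio is returned.  Values
    below ~1.1 are conventionally taken to indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("split-R-hat needs >= 2 chains of equal length")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short for split-R-hat")
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, sd, 95% credible interval, and split-R-hat per
    monitored quantity."""
    return draws.summary()


def fit(study: Study, M: int, config: ModelConfig | None = None,
        priors: Priors | None = None,
        sampler_config: SamplerConfig | None = None,
        seed: int = 0, monitor_rd: bool = False,
        sample_blocks=None, init_params: ModelParams | None = None,
        progress: bool = False) -> PosteriorDraws:
    """Run the full MCMC and return posterior draws with derived quantities.

    Chains run sequentially with independent streams spawned from ``seed``;
    fixing the seed reproduces the draws exactly.
    """
    config = config or ModelConfig()
    scfg = sampler_config or SamplerConfig()
    streams = np.random.SeedSequence(seed).spawn(scfg.n_chains)
    n_kept = (scfg.n_iter - scfg.n_burnin) // scfg.thin
    all_draws = None
    rd_sum, rd_n = None, 0
    acceptance = {}
    for c, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        smp = Sampler(study, M, config, priors=priors, sampler_config=scfg,
                      rng=rng, sample_blocks=sample_blocks,
                      init_params=init_params)
        if all_draws is None:
            names = smp.monitor_names()
            all_draws = np.empty((scfg.n_chains, n_kept, len(names)))
        kept = 0
        for it in range(scfg.n_iter):
            smp.sweep(adapt=scfg.adapt and it < scfg.n_burnin)
            if it >= scfg.n_burnin and (it - scfg.n_burnin) % scfg.thin == 0 \
                    and kept < n_kept:
                all_draws[c, kept] = smp.monitor_values()
                if monitor_rd:
                    rd = smp.realized_density_draw()
                    rd_sum = rd if rd_sum is None else rd_sum + rd
                    rd_n += 1
                kept += 1
        acceptance[f"chain{c + 1}"] = {
            k: (a / t if t else np.nan) for k, (a, t) in smp._acc.items()}
    return PosteriorDraws(names=names, draws=all_draws,
                          rd_mean=None if rd_sum is None else rd_sum / rd_n,
                          acceptance=acceptance)


# ---------------------------------------------------------------------------
# Brute-force posterior oracle for micro instances
# ---------------------------------------------------------------------------

def brute_force_posterior(study: Study, M: int, params: ModelParams,
                          config: ModelConfig | None = None):
    """Exact latent-state marginals by exhaustive enumeration.

    For tiny instances (a handful of individuals, pixels, and periods) the
    discrete latent space (z-paths x s-paths per individual, independent
    across individuals given fixed parameters) is summed directly, giving
    exact marginals P(z[i, t] = 1) and P(s[i, t] = g) under the marginalized
    observation likelihood (same within-pixel quadrature as the sampler).
    Intended as an independent correctness reference for the MCMC.
    """
    config = config or ModelConfig(mode="marginal")
    grid, design, stack = study.grid, study.design, study.covariates
    enc = study.encounters
    if enc.M < M:
        enc = augment(enc, M)
    G, T = grid.G, design.T
    time = dynamics.standardize_time(T)
    gam = np.atleast_2d(dynamics.gamma_schedule(params.beta_gamma, time))
    phi = np.atleast_2d(dynamics.phi_schedule(params.beta_phi, time))
    p0 = params.p0_matrix()
    eta = np.einsum("j,jgt->tg", params.beta_density, stack.X)
    pi_d = np.exp(eta - eta.max(axis=1, keepdims=True))
    pi_d /= pi_d.sum(axis=1, keepdims=True)          # (T, G)
    dmat = np.sqrt(squared_center_distances(grid))
    V = config.V
    forms = [HALF_NORMAL] * design.n_platforms
    # within-pixel quadrature for the y = 0 marginal
    qxy = _pixel_quadrature(grid, config.quad_m)
    occ = [(t, k) for t, k in design.occasions() if design.has_effort(t, k)]

    def pbar_for(t, k, v):
        coords = design.seg_coords(t, k)
        plats = design.seg_platforms(t, k)
        d = segment_point_distances(qxy.reshape(-1, 2), coords)
        near = d.argmin(axis=1)
        dmin = d[np.arange(d.shape[0]), near]
        pl = plats[near]
        out = np.empty(dmin.size)
        for p in set(pl):
            sel = pl == p
            out[sel] = p0[p, v] * _shape_fn(
                _platform_form(study, p), params.sigma_det[p],
                params.b_det[p], dmin[sel])
        return out.reshape(grid.G, -1).mean(axis=1)

    def _platform_form(study, p):
        forms = getattr(study, "platform_forms", None)
        if forms is None:
            forms = getattr(study.design, "platform_forms", None)
        return forms[p] if forms is not None else HALF_NORMAL

    # movement pixel distributions per (v, s, t): pi_move[v][t][s, g]
    pi_move = np.empty((V, T, G, G))
    etam = eta  # shared coefficients
    for v in range(V):
        for t in range(T):
            lk = -0.5 * (dmat / params.sigma_move[v]) ** 2 + etam[t][None, :]
            lk -= lk.max(axis=1, keepdims=True)
            w = np.exp(lk)
            pi_move[v, t] = w / w.sum(axis=1, keepdims=True)

    pbar = {(t, k, v): pbar_for(t, k, v) for (t, k) in occ for v in range(V)}
    m0 = {key: pi_move[key[2], key[0]] @ (1.0 - val)   # (s,) marginal
          for key, val in pbar.items()}

    z_marg = np.zeros((M, T))
    s_marg = np.zeros((M, T, G))
    det_period = enc.detected_in_period()
    for i in range(M):
        v = int(enc.group[i]) if enc.group[i] >= 0 else 0
        best = {}
        tot = 0.0
        zm = np.zeros(T)
        sm = np.zeros((T, G))
        for zp in itertools.product([0, 1], repeat=T):
            if any(det_period[i, t] and zp[t] == 0 for t in range(T)):
                continue
            prior = gam[v, 0] if zp[0] else 1 - gam[v, 0]
            for t in range(1, T):
                pr = phi[v, t - 1] if zp[t - 1] else gam[v, t]
                prior *= pr if zp[t] else 1 - pr
            # per-period sum over s of pi_density * likelihood
            like_t = []
            for t in range(T):
                w = pi_d[t].copy()
                if zp[t] == 1:
                    for (tt, k) in occ:
                        if tt != t:
                            continue
                        if enc.y[i, t, k] == 1:
                            u = grid.pixel_of_point(enc.obs_x[i, t, k],
                                                    enc.obs_y[i, t, k])
                            d, idx = _det_geom(design, t, k,
                                               enc.obs_x[i, t, k],
                                               enc.obs_y[i, t, k])
                            p = p0[idx, v] * _shape_fn(
                                _platform_form(study, idx),
                                params.sigma_det[idx], params.b_det[idx], d)
                            w = w * pi_move[v, t][:, u] * p / grid.pixel_area
                        else:
                            w = w * m0[(t, k, v)]
                like_t.append(w)
            weight = prior * np.prod([w.sum() for w in like_t])
            tot += weight
            for t in range(T):
                zm[t] += weight * zp[t]
                sm[t] += weight * like_t[t] / like_t[t].sum()
        z_marg[i] = zm / tot
        s_marg[i] = sm / tot
    return z_marg, s_marg


def _det_geom(design: SurveyDesign, t: int, k: int, x: float, y: float):
    d = segment_point_distances(np.array([[x, y]]),
                                design.seg_coords(t, k))[0]
    idx = int(np.argmin(d))
    return float(d[idx]), int(design.seg_platforms(t, k)[idx])
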