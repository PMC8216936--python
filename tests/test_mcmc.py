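"""Sampler components: diagnostics, prior recovery, cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import openscr
from openscr import dynamics, mcmc
from openscr.density import CovariateStack, standardize
from openscr.geometry import build_grid
from openscr.io_cli import EncounterData, Study, SurveyDesign


def zero_effort_study(M_rows=0, T=3, n=4, seed=0):
    """A study with no surveyed transects: the observation model is inert,
    so detection parameters keep their uniform prior."""
    grid = build_grid(0, 0, 1.0, n, n)
    design = SurveyDesign(T=T, K=np.ones(T, int), segments={}, n_platforms=1)
    enc = EncounterData(ids=[], group=np.empty(0, int),
                        y=np.zeros((0, T, 1), np.int8),
                        obs_x=np.empty((0, T, 1)), obs_y=np.empty((0, T, 1)))
    rng = np.random.default_rng(seed)
    X = np.stack([standardize(rng.normal(size=(grid.G, T)))])
    return Study(grid=grid, design=design, encounters=enc,
                 covariates=CovariateStack(X, ["cov1"]))


class TestGelmanRubin:
    def test_iid_normal_chains_near_one(self, rng):
        chains = rng.normal(size=(2, 10_000))
        assert mcmc.gelman_rubin(chains) < 1.01

    def test_shifted_chains_flagged(self, rng):
        chains = rng.normal(size=(2, 2_000))
        chains[1] += 10.0
        assert mcmc.gelman_rubin(chains) > 1.1

    def test_single_chain_is_error(self, rng):
        with pytest.raises(ValueError):
            mcmc.gelman_rubin(rng.normal(size=(1, 100)))

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        # mildly autocorrelated chains
        chains = np.cumsum(rng.normal(size=(4, 3000)), axis=1) * 0.01 \
            + rng.normal(size=(4, 3000))
        ours = mcmc.gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains),
                               method="split").x.values)
        assert ours == pytest.approx(theirs, abs=0.01)


class TestSummaries:
    def test_constant_draws_zero_width(self):
        draws = mcmc.PosteriorDraws(names=["a"], draws=np.full((2, 50, 1), 3.0))
        summ = draws.summary()
        assert summ.loc["a", "mean"] == 3.0
        assert summ.loc["a", "q2.5"] == summ.loc["a", "q97.5"] == 3.0

    def test_normal_draw_quantiles(self, rng):
        draws = mcmc.PosteriorDraws(names=["a"],
                                    draws=rng.normal(size=(2, 50_000, 1)))
        summ = draws.summary()
        assert summ.loc["a", "q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert summ.loc["a", "q97.5"] == pytest.approx(1.96, abs=0.05)
        assert summ.loc["a", "rhat"] < 1.01

    def test_csv_roundtrip(self, tmp_path, rng):
        draws = mcmc.PosteriorDraws(names=["a", "b"],
                                    draws=rng.normal(size=(2, 20, 2)))
        path = tmp_path / "draws.csv"
        draws.to_csv(path)
        back = mcmc.PosteriorDraws.from_csv(str(path))
        assert back.names == ["a", "b"]
        assert np.allclose(back.draws, draws.draws)


class TestPriorRecovery:
    def test_flat_likelihood_returns_uniform_prior(self):
        """With zero survey effort the detection block's likelihood is
        constant, so its posterior must reproduce the uniform prior."""
        study = zero_effort_study(T=3)
        priors = mcmc.Priors(study.grid.diameter,
                             {"sigma_det": (0.5, 2.5), "p0": (0.0, 1.0)})
        smp = mcmc.Sampler(study, 10, mcmc.ModelConfig(mode="marginal"),
                           priors=priors, rng=1)
        for _ in range(1000):
            smp.sweep(adapt=True)
        p0s, sigs = [], []
        for i in range(10_000):
            smp.sweep(adapt=False)
            if i % 25 == 0:
                p0s.append(float(smp.params.p0[0, 0]))
                sigs.append(float(smp.params.sigma_det[0]))
        assert stats.kstest(p0s, stats.uniform(0, 1).cdf).pvalue > 0.001
        assert stats.kstest(sigs, stats.uniform(0.5, 2.0).cdf).pvalue > 0.001


class TestDynamicsBlockCrossCheck:
    def test_matches_independent_ensemble_sampler(self):
        """With z fully observed and all other blocks frozen, the arrival/
        persistence posterior must agree with an independent affine-invariant
        ensemble sampler (emcee) run on the same Bernoulli likelihood."""
        emcee = pytest.importorskip("emcee")
        from scipy.special import expit

        T, M = 5, 200
        time = dynamics.standardize_time(T)
        truth = np.array([-0.8, 0.5, -0.4, 1.0, 0.4])
        rng = np.random.default_rng(3)
        gam = expit(truth[0] + truth[1] * time + truth[2] * time ** 2)
        phi = expit(truth[3] + truth[4] * time)
        z_true = dynamics.simulate_presence(M, gam, phi, rng)

        def loglik(theta):
            if np.any(np.abs(theta) > 10):
                return -np.inf
            g = expit(theta[0] + theta[1] * time + theta[2] * time ** 2)
            p = expit(theta[3] + theta[4] * time)
            ll = (z_true[:, 0] * np.log(g[0])
                  + (1 - z_true[:, 0]) * np.log1p(-g[0])).sum()
            for t in range(1, T):
                prev, cur = z_true[:, t - 1], z_true[:, t]
                pr = np.where(prev == 1, p[t - 1], g[t])
                ll += np.where(cur == 1, np.log(pr), np.log1p(-pr)).sum()
            return ll

        ens = emcee.EnsembleSampler(32, 5, loglik)
        state = truth + 0.05 * rng.normal(size=(32, 5))
        ens.run_mcmc(state, 2500, progress=False)
        ref = ens.get_chain(discard=1000, flat=True)

        study = zero_effort_study(T=T)
        smp = mcmc.Sampler(study, M, mcmc.ModelConfig(mode="marginal"),
                           rng=7, sample_blocks=("dynamics",),
                           update_latents=False)
        smp.z = z_true.copy()
        smp.group = np.zeros(M, int)
        for _ in range(1500):
            smp.sweep(adapt=True)
        draws = []
        for _ in range(12_000):
            smp.sweep(adapt=False)
            draws.append(np.concatenate([smp.params.beta_gamma[0],
                                         smp.params.beta_phi[0]]))
        draws = np.asarray(draws)
        sd_ref = ref.std(axis=0)
        assert np.all(np.abs(draws.mean(axis=0) - ref.mean(axis=0))
                      < 0.3 * sd_ref)
        assert np.all(np.abs(draws.std(axis=0) / sd_ref - 1) < 0.3)


class TestModeAgreement:
    def test_latent_and_marginal_posteriors_agree(self, small_sim):
        """The BUGS-style latent-location likelihood and the marginalized
        likelihood are the same model up to within-pixel quadrature; their
        posteriors for abundance and detection must agree."""
        M = small_sim.scenario.M
        results = {}
        for mode, quad_m in (("latent", 1), ("marginal", 3)):
            cfg = mcmc.ModelConfig(mode=mode, quad_m=quad_m)
            scfg = mcmc.SamplerConfig(n_chains=1, n_iter=3000, n_burnin=1200)
            draws = mcmc.fit(small_sim.study, M, cfg, sampler_config=scfg,
                             seed=5)
            results[mode] = draws.summary()
        T = small_sim.scenario.T
        for t in range(T):
            a = results["latent"].loc[f"N[{t}]", "mean"]
            b = results["marginal"].loc[f"N[{t}]", "mean"]
            assert abs(a - b) < max(3.0, 0.2 * max(a, b))
        dp = abs(results["latent"].loc["p0[0,0]", "mean"]
                 - results["marginal"].loc["p0[0,0]", "mean"])
        assert dp < 0.12

    def test_abundance_draws_bounded(self, small_sim):
        cfg = mcmc.ModelConfig(mode="marginal")
        scfg = mcmc.SamplerConfig(n_chains=1, n_iter=600, n_burnin=200)
        draws = mcmc.fit(small_sim.study, 40, cfg, sampler_config=scfg, seed=9)
        enc = small_sim.study.encounters
        observed = enc.detected_in_period().sum(axis=0)
        for t in range(small_sim.scenario.T):
            N = draws.get(f"N[{t}]")
            assert N.min() >= observed[t]
            assert N.max() <= 40

    def test_fit_is_deterministic_under_seed(self, small_sim):
        cfg = mcmc.ModelConfig(mode="marginal")
        scfg = mcmc.SamplerConfig(n_chains=2, n_iter=80, n_burnin=40)
        a = mcmc.fit(small_sim.study, 40, cfg, sampler_config=scfg, seed=3)
        b = mcmc.fit(small_sim.study, 40, cfg, sampler_config=scfg, seed=3)
        assert np.array_equal(a.draws, b.draws)
        c = mcmc.fit(small_sim.study, 40, cfg, sampler_config=scfg, seed=4)
        assert not np.array_equal(a.draws, c.draws)
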