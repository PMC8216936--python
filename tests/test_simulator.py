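"""Forward simulator: generative consistency, determinism, file round-trips."""

import dataclasses

import numpy as np
import pytest

import openscr
from openscr import dynamics, simulator
from openscr.io_cli import load_and_validate


def small_scenario(**kw):
    base = dict(n_x=6, n_y=6, T=3, K=2, M=30, n_transects=4,
                J=2, add_squares=False, beta=(0.4, -0.2))
    base.update(kw)
    return openscr.SimulationScenario(**base)


class TestCovariates:
    def test_standardized_and_deterministic(self):
        scn = small_scenario()
        grid = scn.grid()
        a = simulator.simulate_covariates(scn, grid, np.random.default_rng(5))
        b = simulator.simulate_covariates(scn, grid, np.random.default_rng(5))
        assert np.array_equal(a.X, b.X)
        a.validate_standardized(tol=1e-9)

    def test_squared_companions_appended(self):
        scn = small_scenario(add_squares=True, beta=(0.4, -0.2, -0.1, -0.1))
        stack = simulator.simulate_covariates(scn, scn.grid(),
                                              np.random.default_rng(0))
        assert stack.J == 4
        assert np.allclose(stack.X[2], stack.X[0] ** 2)


class TestPopulation:
    def test_gamma_zero_empty_population(self):
        scn = small_scenario(beta_gamma=((-40.0, 0.0, 0.0),))
        sim = openscr.simulate_study(scn, 1)
        assert sim.truth["N"].sum() == 0
        assert sim.study.encounters.n == 0

    def test_full_persistence_constant_abundance(self):
        # gamma ~ 1 at t=1 and ~ 0 afterwards, phi = 1: N_t stays constant
        scn = small_scenario(beta_gamma=((-30.0, -25.0, 0.0),),
                             beta_phi=((40.0, 0.0),))
        sim = openscr.simulate_study(scn, 3)
        N = sim.truth["N"]
        assert N[0] > 0
        assert np.all(N == N[0])

    def test_mean_abundance_matches_recursion(self):
        scn = small_scenario()
        time = dynamics.standardize_time(scn.T)
        gam = dynamics.gamma_t(np.array(scn.beta_gamma[0]), time)
        phi = dynamics.phi_t(np.array(scn.beta_phi[0]), time)
        expect = dynamics.expected_abundance(scn.M, gam, phi)
        rng = np.random.default_rng(11)
        stack = simulator.simulate_covariates(scn, scn.grid(), rng)
        reps = 2000
        N = np.empty((reps, scn.T))
        for r in range(reps):
            z, _, _ = simulator.simulate_population(scn, stack, rng)
            N[r] = dynamics.derive_abundance(z)
        se = N.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(N.mean(axis=0) - expect) < 3 * se + 1e-9)


class TestSurvey:
    def test_detections_require_presence(self):
        sim = openscr.simulate_study(small_scenario(), 4)
        y, z = sim.truth["y"], sim.truth["z"]
        for t in range(sim.scenario.T):
            assert not np.any(y[:, t, :].any(axis=1) & (z[:, t] == 0))

    def test_zero_p0_zero_detections(self):
        scn = small_scenario(p0=((0.0,),))
        sim = openscr.simulate_study(scn, 5)
        assert sim.truth["y"].sum() == 0

    def test_saturated_detection(self):
        # dense transects, certain on-line detection, near-flat kernel
        scn = small_scenario(n_transects=12, p0=((1.0,),), sigma_det=(1e6,))
        sim = openscr.simulate_study(scn, 6)
        y, z = sim.truth["y"], sim.truth["z"]
        for t in range(scn.T):
            present = z[:, t] == 1
            assert np.all(y[present, t, :scn.K] == 1)

    def test_detection_rate_monotone_in_p0_and_effort(self):
        def rate(scn, seed=9):
            sim = openscr.simulate_study(scn, seed)
            y, z = sim.truth["y"], sim.truth["z"]
            pres = z.sum() * sim.scenario.K
            return y.sum() / pres if pres else 0.0

        lo = rate(small_scenario(p0=((0.2,),)))
        hi = rate(small_scenario(p0=((0.9,),)))
        assert hi > lo
        sparse = rate(small_scenario(n_transects=2))
        dense = rate(small_scenario(n_transects=10))
        assert dense > sparse

    def test_observed_locations_equal_true_locations(self):
        sim = openscr.simulate_study(small_scenario(), 8)
        enc = sim.study.encounters
        obs_idx = sim.truth["observed_index"]
        det = enc.y == 1
        assert np.array_equal(enc.obs_x[det],
                              sim.truth["U_x"][obs_idx][det])
        assert np.array_equal(enc.obs_y[det],
                              sim.truth["U_y"][obs_idx][det])

    def test_detection_curve_recovery(self):
        """Empirical detection frequency at binned mindist follows the
        half-normal curve within binomial error."""
        scn = small_scenario(M=60, T=4, K=3, p0=((0.8,),), sigma_det=(1.2,))
        dists, dets = [], []
        for seed in range(40):
            sim = openscr.simulate_study(scn, seed)
            y, z = sim.truth["y"], sim.truth["z"]
            ux, uy = sim.truth["U_x"], sim.truth["U_y"]
            for t in range(scn.T):
                for k in range(scn.K):
                    coords = sim.study.design.seg_coords(t, k)
                    pres = np.flatnonzero(z[:, t] == 1)
                    if pres.size == 0:
                        continue
                    pts = np.column_stack([ux[pres, t, k], uy[pres, t, k]])
                    from openscr.geometry import segment_point_distances
                    d = segment_point_distances(pts, coords).min(axis=1)
                    dists.append(d)
                    dets.append(y[pres, t, k])
        d = np.concatenate(dists)
        det = np.concatenate(dets)
        edges = np.array([0.0, 0.3, 0.6, 0.9, 1.2, 1.6])
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (d >= lo) & (d < hi)
            n = sel.sum()
            if n < 50:
                continue
            obs = det[sel].mean()
            expect = (0.8 * np.exp(-0.5 * (d[sel] / 1.2) ** 2)).mean()
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(obs - expect) < 4 * se + 0.01


class TestWriteRead:
    def test_roundtrip_through_csv(self, tmp_path):
        scn = small_scenario(add_squares=True, beta=(0.4, -0.2, -0.1, -0.1))
        sim = openscr.simulate_study(scn, 10)
        paths = simulator.write_study(sim, tmp_path)
        study, report = load_and_validate(
            str(paths["transects"]), str(paths["sightings"]),
            str(paths["covariates"]), scn.grid(), T=scn.T,
            covariates_standardized=True)
        assert report.n_dropped_duplicates == 0
        assert not report.warnings
        enc0, enc1 = sim.study.encounters, study.encounters
        assert enc1.n == enc0.n
        assert np.array_equal(enc1.y, enc0.y)
        det = enc0.y == 1
        assert np.allclose(enc1.obs_x[det], enc0.obs_x[det])
        assert np.array_equal(enc1.group, enc0.group)
        assert np.allclose(study.covariates.X, sim.study.covariates.X)
        for t, k in sim.study.design.occasions():
            assert np.allclose(study.design.seg_coords(t, k),
                               sim.study.design.seg_coords(t, k))

    def test_truth_sidecar_written(self, tmp_path):
        sim = openscr.simulate_study(small_scenario(), 11)
        paths = simulator.write_study(sim, tmp_path)
        assert paths["truth_params"].exists()
        assert paths["truth_states"].exists()

    def test_seeded_determinism(self):
        a = openscr.simulate_study(small_scenario(), 12)
        b = openscr.simulate_study(small_scenario(), 12)
        assert np.array_equal(a.truth["y"], b.truth["y"])
        assert a.study.encounters.ids == b.study.encounters.ids
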