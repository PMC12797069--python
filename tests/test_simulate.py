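import math

import numpy as np
import pytest

from multimsm import (BDParams, DiscretizerParams, FeatureSpace,
                      NestedChainSpec, PotentialSpec, basin_ground_truth,
                      bd_simulate, nested_chain, new_multiscale_msm,
                      potential_energy, potential_force, stream_chunks,
                      two_spheres_fixture, update_base_counts)
from multimsm._constants import (KB_KCAL_PER_MOL_K,
                                 stokes_einstein_diffusion)
from multimsm.simulate import ChainSimulator

from conftest import sample_chain


class TestPotential:
    def test_force_matches_finite_difference(self, rng):
        spec, _, _ = two_spheres_fixture()
        d = rng.uniform(20.0, 58.0, size=100)
        h = 1e-6
        numeric = -(potential_energy(d + h, spec) - potential_energy(d - h, spec)) / (2 * h)
        analytic = potential_force(d, spec)
        scale = np.maximum(np.abs(analytic), 1.0)
        assert np.max(np.abs(numeric - analytic) / scale) < 1e-6

    def test_flat_potential(self):
        spec = PotentialSpec(domain=(0.0, 10.0), tilt=0.0, scales=())
        d = np.linspace(0.5, 9.5, 50)
        np.testing.assert_allclose(potential_energy(d, spec), 0.0, atol=1e-15)
        np.testing.assert_allclose(potential_force(d, spec), 0.0, atol=1e-15)

    def test_barrier_at_anchor(self):
        spec, _, _ = two_spheres_fixture()
        d = np.linspace(38.0, 40.0, 401)
        u = potential_energy(d, spec)
        top = d[np.argmax(u)]
        assert abs(top - 39.0) < 0.1

    def test_walls_harmonic(self):
        spec = PotentialSpec(domain=(0.0, 10.0), tilt=0.0, scales=(), wall_k=2.0)
        assert potential_energy(-1.0, spec) == pytest.approx(0.5 * 2.0 * 1.0)
        assert potential_force(-1.0, spec) == pytest.approx(2.0)
        assert potential_force(11.0, spec) == pytest.approx(-2.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            PotentialSpec(domain=(5.0, 5.0))
        with pytest.raises(ValueError):
            PotentialSpec(scales=((-1.0, 2.0, 0.0),))
        with pytest.raises(ValueError):
            PotentialSpec(scales=((1.0, 0.0, 0.0),))


class TestDiffusionConstant:
    def test_stokes_einstein_value(self):
        # kB*300K / (6 pi * 0.8937e-3 Pa s * 5 A) in A^2/ps
        d = stokes_einstein_diffusion(300.0, 5.0)
        assert d == pytest.approx(0.0492, abs=0.0005)


class TestBrownianDynamics:
    def test_free_diffusion_msd(self):
        # MSD after t steps must match 2 D t within 3 sigma over 1e4 walkers
        spec = PotentialSpec(domain=(-1e9, 1e9), tilt=0.0, scales=(), wall_k=0.0)
        params = BDParams(temperature=300.0, dt=0.03, stokes_radius=5.0)
        n_walkers, n_steps = 10_000, 100
        trajs = bd_simulate([0.0], k=n_walkers, m=n_steps + 1, params=params,
                            spec=spec, seed=2024)
        disp = np.array([t.frames[-1, 0] - t.frames[0, 0] for t in trajs])
        msd = np.mean(disp ** 2)
        expected = 2.0 * params.diffusion * params.dt * n_steps
        # Var(X^2) = 2 sigma^4 for gaussian displacements
        sigma = expected * math.sqrt(2.0 / n_walkers)
        assert abs(msd - expected) < 3 * sigma

    def test_harmonic_equipartition(self):
        # U = 0.5 * kappa * x^2 via a wall-only potential centered at 0
        kappa = 1.0
        spec = PotentialSpec(domain=(0.0, 1e-12), tilt=0.0, scales=(),
                             wall_k=kappa)
        params = BDParams(temperature=300.0, dt=0.03, stokes_radius=5.0)
        n_steps = 2 * 10 ** 6
        traj = bd_simulate([0.0], k=1, m=n_steps + 1, params=params, spec=spec,
                           seed=7)[0]
        x = traj.frames[5000:, 0]  # discard equilibration
        var = np.var(x)
        expected = KB_KCAL_PER_MOL_K * 300.0 / kappa
        # correlation time of the OU process in steps
        tau_corr = expected / (params.diffusion * params.dt) * params.dt / params.dt
        tau_steps = KB_KCAL_PER_MOL_K * 300.0 / (params.diffusion * kappa) / params.dt
        neff = len(x) / (2 * tau_steps)
        sigma = expected * math.sqrt(2.0 / neff)
        assert abs(var - expected) < 3 * sigma

    def test_same_seed_identical(self):
        spec, params, xinit = two_spheres_fixture()
        a = bd_simulate(xinit, 2, 50, params, spec, seed=5)
        b = bd_simulate(xinit, 2, 50, params, spec, seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.frames, tb.frames)

    def test_frame_interval_and_stride(self):
        spec, params, xinit = two_spheres_fixture()
        t = bd_simulate(xinit, 1, 10, params, spec, seed=1, frame_stride=4)[0]
        assert t.frame_interval == pytest.approx(params.dt * 4)
        assert len(t) == 10


class TestTwoSpheresFixture:
    def test_two_coarse_basins_split_at_39(self):
        spec, _, _ = two_spheres_fixture()
        # quadrature oracle on the coarsest term only: derivative sign changes
        amp, wav, phase = spec.scales[0]
        d = np.linspace(spec.domain[0] + 1e-6, spec.domain[1] - 1e-6, 20001)
        slope = amp * 2 * np.pi / wav * np.sin(
            2 * np.pi / wav * (d - spec.barrier_anchor) + phase)
        signs = np.sign(slope)
        signs[signs == 0] = 1  # exact zeros would double-count a crossing
        changes = np.flatnonzero(np.diff(signs) != 0)
        # exactly one interior stationary point: the barrier at 39
        assert len(changes) == 1
        assert abs(d[changes[0]] - 39.0) < 0.01

    def test_basin_b_heavier(self):
        spec, params, _ = two_spheres_fixture()
        pi, F = basin_ground_truth(spec, params.temperature, [39.0])
        assert pi[1] > pi[0]
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_xinit_inside_domain(self):
        spec, _, xinit = two_spheres_fixture()
        assert spec.domain[0] < xinit[0] < spec.domain[1]


class TestBasinGroundTruth:
    def test_symmetric_double_well(self):
        spec = PotentialSpec(domain=(0.0, 2.0), tilt=0.0,
                             scales=((1.0, 2.0, 0.0),), barrier_anchor=1.0)
        pi, F = basin_ground_truth(spec, 300.0, [1.0])
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-10)
        np.testing.assert_allclose(F, [0.0, 0.0], atol=1e-9)

    def test_sums_to_one_many_basins(self):
        spec, params, _ = two_spheres_fixture()
        edges = np.linspace(25, 53, 8)
        pi, _ = basin_ground_truth(spec, params.temperature, list(edges))
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_against_metropolis_oracle(self, rng):
        spec = PotentialSpec(domain=(0.0, 4.0), tilt=-0.5,
                             scales=((0.8, 4.0, 0.0),), barrier_anchor=2.0)
        kbt = KB_KCAL_PER_MOL_K * 300.0
        n = 200_000
        x = 1.0
        samples = np.empty(n)
        u_cur = potential_energy(x, spec)
        steps = rng.uniform(-0.8, 0.8, size=n)
        accept = rng.random(n)
        for i in range(n):
            xn = x + steps[i]
            un = potential_energy(xn, spec)
            if accept[i] < math.exp(min(0.0, -(un - u_cur) / kbt)):
                x, u_cur = xn, un
            samples[i] = x
        pi, _ = basin_ground_truth(spec, 300.0, [2.0])
        # the oracle is domain-restricted; condition samples on the domain
        # (the soft walls leave Boltzmann mass in the tails outside it)
        inside = samples[(samples >= 0.0) & (samples <= 4.0)]
        frac_a = np.mean(inside < 2.0)
        sigma = math.sqrt(pi[0] * pi[1] / (n / 200))  # crude neff
        assert abs(frac_a - pi[0]) < max(3 * sigma, 0.02)

    def test_bd_equilibrium_matches_quadrature(self):
        # the module's central physics check, desk-scaled
        spec = PotentialSpec(domain=(0.0, 4.0), tilt=-0.3,
                             scales=((0.6, 4.0, 0.0),), barrier_anchor=2.0)
        params = BDParams(temperature=300.0, dt=0.03, stokes_radius=5.0)
        traj = bd_simulate([0.5], k=1, m=2 * 10 ** 6, params=params, spec=spec,
                           seed=13)[0]
        x = traj.frames[10_000:, 0]
        x = x[(x >= 0.0) & (x <= 4.0)]
        pi, _ = basin_ground_truth(spec, 300.0, [2.0])
        frac_a = np.mean(x < 2.0)
        assert abs(frac_a - pi[0]) < 0.05


class TestNestedChain:
    def test_two_tier_example(self):
        spec = NestedChainSpec(tiers=((2, 0.01), (2, 0.2)))
        T, pi, parts = nested_chain(spec)
        assert T.shape == (4, 4)
        np.testing.assert_allclose(pi, 0.25)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-15)
        np.testing.assert_allclose(T, T.T, atol=1e-15)  # doubly stochastic
        assert parts[0] == [[0, 1], [2, 3]]

    def test_stationary_is_uniform_eigencheck(self):
        spec = NestedChainSpec(tiers=((2, 0.001), (3, 0.05), (2, 0.3)))
        T, pi, _ = nested_chain(spec)
        np.testing.assert_allclose(pi @ T, pi, atol=1e-14)

    def test_eigenvalue_gaps_track_escape_ratio(self):
        p_slow, p_fast = 0.001, 0.1
        spec = NestedChainSpec(tiers=((2, p_slow), (2, p_fast)))
        T, _, _ = nested_chain(spec)
        lam = np.sort(np.linalg.eigvalsh(T))[::-1]
        # slow mode decays at the slow escape rate, fast modes at the fast one
        slow_rate = 1 - lam[1]
        fast_rate = 1 - lam[2]
        assert fast_rate / slow_rate == pytest.approx(p_fast / p_slow, rel=0.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            NestedChainSpec(tiers=((2, 0.2),))
        with pytest.raises(ValueError, match="increase"):
            NestedChainSpec(tiers=((2, 0.2), (2, 0.1)))
        with pytest.raises(ValueError):
            NestedChainSpec(tiers=((1, 0.01), (2, 0.1)))

    def test_simulated_counts_match_spec(self):
        spec = NestedChainSpec(tiers=((2, 0.01), (2, 0.2)))
        T, _, _ = nested_chain(spec)
        sim = ChainSimulator(T, tau0=1.0)
        path = sim(np.array([0.0]), 1, 10 ** 6, seed=3)[0].frames[:, 0].astype(int)
        C = np.zeros((4, 4))
        np.add.at(C, (path[:-1], path[1:]), 1.0)
        emp = C / C.sum(axis=1, keepdims=True)
        assert np.max(np.abs(emp - T)) < 0.01

    def test_chain_simulator_matches_plain_numpy_oracle(self):
        # same chain sampled by the independent conftest sampler: empirical
        # distributions agree
        spec = NestedChainSpec(tiers=((2, 0.05), (2, 0.3)))
        T, _, _ = nested_chain(spec)
        sim = ChainSimulator(T, tau0=1.0)
        a = sim(np.array([0.0]), 1, 50_001, seed=5)[0].frames[:, 0].astype(int)
        b = sample_chain(T, 50_000, seed=6)
        ha = np.bincount(a, minlength=4) / len(a)
        hb = np.bincount(b, minlength=4) / len(b)
        assert np.max(np.abs(ha - hb)) < 0.03


class TestStreamChunks:
    def _write(self, tmp_path, rows, name="traj.txt"):
        p = tmp_path / name
        p.write_text("\n".join(rows) + "\n")
        return p

    def test_boundary_carry_exact_counts(self, tmp_path, rng, space1d):
        values = rng.uniform(0, 10, size=10)
        p = self._write(tmp_path, [f"{v:.6f}" for v in values])
        batches = list(stream_chunks(p, chunk_frames=4, tau0=1.0))
        assert [len(b) for b in batches] == [4, 5, 3]
        dp = DiscretizerParams(diameter=1.0)
        # chunked ingestion
        m1 = new_multiscale_msm([values[0]], space1d, 1.0, tau0=1.0)
        for b in batches:
            update_base_counts(m1, [b], dp)
        # monolithic ingestion
        from multimsm.update import Trajectory
        m2 = new_multiscale_msm([values[0]], space1d, 1.0, tau0=1.0)
        update_base_counts(m2, [Trajectory(frames=values[:, None],
                                           frame_interval=1.0)], dp)
        assert m1.levels[0].counts == m2.levels[0].counts
        assert sum(m1.levels[0].counts.values()) == 9

    def test_single_batch_when_chunk_exceeds_file(self, tmp_path, rng):
        p = self._write(tmp_path, [str(v) for v in rng.uniform(0, 1, 10)])
        batches = list(stream_chunks(p, chunk_frames=100, tau0=1.0))
        assert len(batches) == 1
        assert len(batches[0]) == 10

    def test_stride_subsampling(self, tmp_path):
        p = self._write(tmp_path, [str(float(i)) for i in range(10)])
        batches = list(stream_chunks(p, chunk_frames=100, tau0=1.0, stride=2))
        assert len(batches[0]) == 5
        np.testing.assert_allclose(batches[0].frames[:, 0], [0, 2, 4, 6, 8])

    def test_sidecar_stride(self, tmp_path):
        p = self._write(tmp_path, [str(float(i)) for i in range(10)])
        (tmp_path / "traj.txt.json").write_text('{"frame_interval_ps": 0.5}\n')
        batches = list(stream_chunks(p, chunk_frames=100, tau0=1.0))
        assert len(batches[0]) == 5

    def test_malformed_row_names_line(self, tmp_path):
        p = self._write(tmp_path, ["1.0", "2.0", "oops", "4.0"])
        with pytest.raises(ValueError, match="line 3"):
            list(stream_chunks(p, chunk_frames=2, tau0=1.0))

    def test_incompatible_interval_rejected(self, tmp_path):
        p = self._write(tmp_path, ["1.0", "2.0"])
        (tmp_path / "traj.txt.json").write_text('{"frame_interval_ps": 0.4}\n')
        with pytest.raises(ValueError, match="divide"):
            list(stream_chunks(p, chunk_frames=2, tau0=1.0))
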