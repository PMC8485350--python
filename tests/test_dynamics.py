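"""Displacement windows, diffusion estimation, survival probability."""

import numpy as np
import pytest

from poredyn import (
    AtomGroup,
    PoreRegion,
    PoreSystemSpec,
    Trajectory,
    displacement_histogram,
    estimate_diffusion,
    select_group,
    simulate_pore_system,
    survival_probability,
    windowed_displacements,
)
from poredyn.dynamics import DisplacementDistribution, _inside_matrix
from poredyn.synthetic import _pore_topology
from poredyn.util import unwrap


def _static_traj(pts, n_frames=10, box=4.0, dt=1.0):
    return Trajectory(
        coords=np.tile(pts, (n_frames, 1, 1)),
        box=np.full((n_frames, 3), box),
        times=dt * np.arange(n_frames),
    )


class TestWindowedDisplacements:
    def test_frozen_particles_have_zero_displacement(self):
        top = _pore_topology(6, 0, 0)
        pts = np.full((6, 3), 2.0)
        traj = _static_traj(pts, n_frames=21)
        dd = windowed_displacements(traj, None, AtomGroup(top, np.arange(6)), window_length=5.0, n_windows=4)
        np.testing.assert_allclose(dd.displacements, 0.0)

    def test_molecule_leaving_mid_window_excluded(self):
        top = _pore_topology(2, 0, 0)
        region = PoreRegion((2.0, 2.0), 1.0, 3.0, 1.0)
        coords = np.tile([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]], (11, 1, 1))
        coords[5, 1, 2] = 3.5  # particle 1 leaves at frame 5, then returns
        traj = Trajectory(coords=coords, box=np.full((11, 3), 4.0), times=np.arange(11.0))
        dd = windowed_displacements(traj, region, AtomGroup(top, [0, 1]), window_length=10.0, n_windows=1)
        assert dd.n_samples == 1  # only the particle that stayed inside

    def test_no_qualifying_molecule_rejected(self):
        top = _pore_topology(1, 0, 0)
        region = PoreRegion((2.0, 2.0), 1.0, 3.0, 0.1)
        traj = _static_traj(np.array([[0.2, 0.2, 0.2]]), n_frames=11)
        with pytest.raises(ValueError, match="stayed inside"):
            windowed_displacements(traj, region, AtomGroup(top, [0]), window_length=5.0, n_windows=2)

    def test_pooled_mean_matches_brownian_closed_form(self):
        d_in = 2.0e-9
        spec = PoreSystemSpec(
            D_water=d_in, box=(12.0, 12.0, 12.0), membrane_slab=None, pore_radius=0.0,
            n_waters=250, n_cations=0, n_anions=0, dt=5.0, n_steps=500, seed=21,
        )
        sys_ = simulate_pore_system(spec)
        waters = select_group(sys_.topology, role="water_oxygen")
        tau = 100.0
        dd = windowed_displacements(sys_.trajectory, None, waters, window_length=tau, n_windows=5)
        expected = 6.0 * d_in * 1e6 * tau  # <r^2> = 6 D tau, nm^2
        n_eff = dd.n_samples  # non-overlapping windows: independent samples
        se = expected * np.sqrt(2.0 / 3.0 / n_eff)  # relative sd of a chi^2_3 mean
        assert abs(dd.displacements.mean() - expected) < 3 * se


class TestDisplacementHistogram:
    def test_single_value_single_unit_bin(self):
        dd = DisplacementDistribution(window_length=100.0, displacements=np.array([0.7]))
        edges, probs = displacement_histogram(dd, bins=5)
        assert probs.sum() == pytest.approx(1.0)
        assert (probs > 0).sum() == 1

    def test_uniform_values_give_flat_histogram(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=20000)
        dd = DisplacementDistribution(window_length=1.0, displacements=vals)
        edges, probs = displacement_histogram(dd, bins=10)
        # multinomial 3-sigma band around 1/10 per bin
        se = np.sqrt(0.1 * 0.9 / len(vals))
        assert np.all(np.abs(probs - 0.1) < 3.5 * se)

    def test_probability_mass_sums_to_one(self):
        rng = np.random.default_rng(4)
        dd = DisplacementDistribution(window_length=1.0, displacements=rng.exponential(size=500))
        _, probs = displacement_histogram(dd, bins=25)
        assert probs.sum() == pytest.approx(1.0)


class TestEstimateDiffusion:
    def test_stationary_group_is_zero(self):
        top = _pore_topology(20, 0, 0)
        traj = _static_traj(np.random.default_rng(0).uniform(1, 3, (20, 3)), n_frames=200)
        d, _ = estimate_diffusion(traj, AtomGroup(top, np.arange(20)), fit_window=(10.0, 100.0))
        assert d == pytest.approx(0.0, abs=1e-15)

    def test_recovers_generator_input_within_5_percent(self, free_walkers):
        waters = select_group(free_walkers.topology, role="water_oxygen")
        d, _ = estimate_diffusion(free_walkers.trajectory, waters, fit_window=(25.0, 500.0))
        assert d == pytest.approx(free_walkers.truth.D_water, rel=0.05)

    def test_translation_and_wrap_invariance(self, free_walkers):
        waters = select_group(free_walkers.topology, role="water_oxygen")
        traj = free_walkers.trajectory
        d0, _ = estimate_diffusion(traj, waters, fit_window=(25.0, 500.0))
        shifted = Trajectory(
            coords=np.mod(traj.coords + 3.7, traj.box[:, None, :]),
            box=traj.box.copy(), times=traj.times.copy(),
        )
        d1, _ = estimate_diffusion(shifted, waters, fit_window=(25.0, 500.0))
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_axial_on_confined_matches_3d_on_free(self):
        d_in = 3.0e-9
        common = dict(D_water=d_in, n_cations=0, n_anions=0, dt=2.0, n_steps=600)
        free = simulate_pore_system(PoreSystemSpec(
            box=(10.0, 10.0, 10.0), membrane_slab=None, pore_radius=0.0, n_waters=400, seed=31, **common))
        # walkers confined to a periodic cylinder: radial motion blocked, axial free
        pore = simulate_pore_system(PoreSystemSpec(
            box=(3.0, 3.0, 12.0), membrane_slab=(0.0, 12.0), pore_radius=0.4, n_waters=400, seed=32, **common))
        g_free = select_group(free.topology, role="water_oxygen")
        g_pore = select_group(pore.topology, role="water_oxygen")
        d3, _ = estimate_diffusion(free.trajectory, g_free, mode="full_3d", fit_window=(10.0, 200.0))
        d1, _ = estimate_diffusion(pore.trajectory, g_pore, mode="axial_1d", fit_window=(10.0, 200.0))
        assert d1 == pytest.approx(d3, rel=0.10)

    def test_degenerate_fit_window_rejected(self, free_walkers):
        waters = select_group(free_walkers.topology, role="water_oxygen")
        with pytest.raises(ValueError, match="fit window"):
            estimate_diffusion(free_walkers.trajectory, waters, fit_window=(5.0, 6.0))


class TestSurvival:
    def test_origin_probability_is_one(self, pore_system):
        waters = select_group(pore_system.topology, role="water_oxygen")
        curve = survival_probability(pore_system.trajectory, pore_system.truth.region, waters)
        assert curve.probability[0] == 1.0

    def test_nonincreasing(self, pore_system):
        waters = select_group(pore_system.topology, role="water_oxygen")
        curve = survival_probability(pore_system.trajectory, pore_system.truth.region, waters)
        assert np.all(np.diff(curve.probability) <= 1e-12)

    def test_permanently_inside_waters_give_unity(self):
        top = _pore_topology(4, 0, 0)
        region = PoreRegion((2.0, 2.0), 1.0, 3.0, 1.0)
        traj = _static_traj(np.tile([2.0, 2.0, 2.0], (4, 1)), n_frames=30)
        curve = survival_probability(traj, region, AtomGroup(top, np.arange(4)))
        np.testing.assert_allclose(curve.probability, 1.0)

    def test_never_occupied_region_rejected(self):
        top = _pore_topology(2, 0, 0)
        region = PoreRegion((2.0, 2.0), 1.0, 3.0, 0.05)
        traj = _static_traj(np.tile([0.1, 0.1, 0.1], (2, 1)))
        with pytest.raises(ValueError, match="never occupied"):
            survival_probability(traj, region, AtomGroup(top, [0, 1]))

    def test_matches_direct_enumeration_oracle(self, pore_system):
        waters = select_group(pore_system.topology, role="water_oxygen")
        region = pore_system.truth.region
        traj = pore_system.trajectory
        max_lag = 40.0
        curve = survival_probability(traj, region, waters, max_lag=max_lag)
        inside = _inside_matrix(traj, region, waters)
        n_frames = len(inside)
        lag_frames = int(round(max_lag / traj.dt))
        t0_max = n_frames - lag_frames
        for lag in (0, 1, 7, 23, 40):
            vals = []
            for t0 in range(t0_max):
                n0 = inside[t0].sum()
                if n0 == 0:
                    continue
                cont = np.all(inside[t0 : t0 + lag + 1], axis=0).sum()
                vals.append(cont / n0)
            assert curve.probability[lag] == pytest.approx(np.mean(vals), abs=1e-12)


class TestUnwrap:
    def test_unwrap_recovers_free_path_through_boundary(self):
        # a walker crossing the box edge repeatedly
        true_path = np.cumsum(np.full((50, 1, 3), 0.4), axis=0)
        box = np.full((50, 3), 3.0)
        wrapped = np.mod(true_path, 3.0)
        recovered = unwrap(wrapped, box)
        np.testing.assert_allclose(recovered, true_path - true_path[0] + wrapped[0], atol=1e-12)

    def test_half_box_step_rejected(self):
        # a step of exactly half the box has two equidistant periodic images
        coords = np.zeros((3, 1, 3))
        coords[1, 0, 0] = 1.5
        with pytest.raises(ValueError, match="box/2"):
            unwrap(coords, np.full((3, 3), 3.0))
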