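"""Ion traces, entrants, RDF, coordination and selectivity."""

import numpy as np
import pytest

from poredyn import (
    AtomGroup,
    IonTrace,
    PoreRegion,
    PoreSystemSpec,
    RDFCurve,
    Trajectory,
    build_hydration_fixture,
    classify_inside,
    coordination_numbers,
    count_entrants,
    first_minimum,
    ion_pairs_for_molarity,
    ion_z_traces,
    rdf,
    select_group,
    selectivity_summary,
    simulate_pore_system,
)
from poredyn.synthetic import _pore_topology
from poredyn.util import minimum_image


def _static(pts, n_frames=1, box=4.0):
    return Trajectory(coords=np.tile(pts, (n_frames, 1, 1)), box=np.full((n_frames, 3), box), times=np.arange(float(n_frames)))


class TestIonTraces:
    def test_fixed_ion_inside_and_bulk(self):
        top = _pore_topology(0, 2, 0)
        region = PoreRegion((2.0, 2.0), 1.0, 3.0, 0.5)
        pts = np.array([[2.0, 2.0, 2.0], [0.3, 0.3, 0.3]])
        traces = ion_z_traces(_static(pts, 6), AtomGroup(top, [0, 1]), region)
        assert traces[0].inside.all()
        assert not traces[1].inside.any()
        assert traces[0].species == "cation"

    def test_inside_flags_match_classifier(self, pore_system):
        region = pore_system.truth.region
        ions = select_group(pore_system.topology, role="cation")
        traces = ion_z_traces(pore_system.trajectory, ions, region)
        for f in (0, 75, 149):
            mask = classify_inside(pore_system.trajectory.coords[f], region, ions)
            np.testing.assert_array_equal(np.array([t.inside[f] for t in traces]), mask)

    def test_entrant_count_is_distinct_ions(self):
        z = np.zeros(6)
        inside_twice = np.array([False, True, False, True, False, False])
        never = np.zeros(6, dtype=bool)
        traces = [
            IonTrace(0, "cation", z, inside_twice),
            IonTrace(1, "cation", z, never),
            IonTrace(2, "anion", z, inside_twice.copy()),
        ]
        assert count_entrants(traces) == 2
        assert count_entrants(traces, species="cation") == 1
        assert count_entrants([IonTrace(0, "cation", z, never)]) == 0

    def test_entrants_match_ground_truth(self, pore_system):
        region = pore_system.truth.region
        for role, truth_set in (("cation", pore_system.truth.entrant_cations), ("anion", pore_system.truth.entrant_anions)):
            ions = select_group(pore_system.topology, role=role)
            traces = ion_z_traces(pore_system.trajectory, ions, region)
            assert count_entrants(traces) == len(truth_set)
            assert {t.ion_id for t in traces if t.inside.any()} == truth_set

    def test_subsampling_preserves_entrants(self, pore_system):
        # keeping every other frame preserves ions that are inside on even frames
        region = pore_system.truth.region
        ions = select_group(pore_system.topology, role="cation")
        traces = ion_z_traces(pore_system.trajectory, ions, region)
        sub = [IonTrace(t.ion_id, t.species, t.z[::2], t.inside[::2]) for t in traces]
        full_on_even = sum(1 for t in traces if t.inside[::2].any())
        assert count_entrants(sub) == full_on_even


class TestRdf:
    def test_two_fixed_atoms_single_spike(self):
        top = _pore_topology(1, 1, 0)
        pts = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
        traj = _static(pts, 3)
        curve = rdf(traj, AtomGroup(top, [1]), AtomGroup(top, [0]), r_max=1.9, bin_size=0.01)
        hot = curve.g > 0
        assert hot.sum() == 1
        assert curve.r[hot][0] == pytest.approx(0.50, abs=0.011)

    def test_ideal_gas_is_unity_with_poisson_errors(self, free_walkers):
        cations = select_group(free_walkers.topology, role="cation")
        waters = select_group(free_walkers.topology, role="water_oxygen")
        traj = free_walkers.trajectory
        sub = Trajectory(coords=traj.coords[::30], box=traj.box[::30], times=traj.times[::30])
        curve = rdf(sub, cations, waters, r_max=3.0, bin_size=0.05)
        sel = curve.r > 0.2
        # Poisson 3-sigma per bin from expected shell counts
        rho = len(waters) / free_walkers.trajectory.box[0].prod()
        shell = 4 * np.pi * curve.r[sel] ** 2 * 0.05
        expected_counts = sub.n_frames * len(cations) * rho * shell
        sigma_g = 1.0 / np.sqrt(expected_counts)
        within = np.abs(curve.g[sel] - 1.0) < 3 * sigma_g
        assert within.mean() > 0.95  # a 3-sigma bound admits ~0.3% outliers
        assert curve.g[sel].mean() == pytest.approx(1.0, abs=0.02)

    def test_group_swap_symmetry(self, free_walkers):
        cations = select_group(free_walkers.topology, role="cation")
        waters = select_group(free_walkers.topology, role="water_oxygen")
        traj = free_walkers.trajectory
        sub = Trajectory(coords=traj.coords[:5], box=traj.box[:5], times=traj.times[:5])
        g_ab = rdf(sub, cations, waters, r_max=2.0, bin_size=0.05)
        g_ba = rdf(sub, waters, cations, r_max=2.0, bin_size=0.05)
        np.testing.assert_allclose(g_ab.g, g_ba.g, rtol=1e-9)

    def test_r_max_beyond_half_box_rejected(self, free_walkers):
        cations = select_group(free_walkers.topology, role="cation")
        waters = select_group(free_walkers.topology, role="water_oxygen")
        with pytest.raises(ValueError, match="half"):
            rdf(free_walkers.trajectory, cations, waters, r_max=4.5)

    def test_matches_mdanalysis_interrdf(self):
        # independent route: same frames through MDAnalysis's RDF machinery
        import warnings

        import MDAnalysis as mda
        from MDAnalysis.analysis.rdf import InterRDF

        spec = PoreSystemSpec(D_water=2.3e-9, box=(5.0, 5.0, 5.0), membrane_slab=None, pore_radius=0.0,
                              n_waters=300, n_cations=20, n_anions=0, dt=1.0, n_steps=5, seed=13)
        sys_ = simulate_pore_system(spec)
        cat = select_group(sys_.topology, role="cation")
        wat = select_group(sys_.topology, role="water_oxygen")
        ours = rdf(sys_.trajectory, cat, wat, r_max=2.0, bin_size=0.02)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(sys_.topology.n_atoms, trajectory=True)
            dims = np.hstack([sys_.trajectory.box * 10, np.full((sys_.trajectory.n_frames, 3), 90.0)])
            u.load_new(sys_.trajectory.coords * 10, dimensions=dims)  # nm -> Angstrom
            ref = InterRDF(u.atoms[cat.indices], u.atoms[wat.indices], nbins=100, range=(0.0, 20.0)).run()
        np.testing.assert_allclose(ours.g, ref.results.rdf, atol=1e-10)

    def test_pair_count_conservation(self):
        # integral of g over the box counts all target partners exactly once
        spec = PoreSystemSpec(D_water=2.3e-9, box=(4.0, 4.0, 4.0), membrane_slab=None, pore_radius=0.0,
                              n_waters=200, n_cations=10, n_anions=0, dt=1.0, n_steps=3, seed=8)
        sys_ = simulate_pore_system(spec)
        cations = select_group(sys_.topology, role="cation")
        waters = select_group(sys_.topology, role="water_oxygen")
        curve = rdf(sys_.trajectory, cations, waters, r_max=1.99, bin_size=0.01)
        rho = len(waters) / 4.0**3
        shell = 4 * np.pi * curve.r**2 * 0.01
        recovered = (curve.g * rho * shell).sum() * 4.0**3 / (4 / 3 * np.pi * 1.99**3)
        # within the r_max sphere the mean density matches the box density
        assert recovered == pytest.approx(len(waters), rel=0.05)


class TestFirstMinimum:
    def _curve(self, peak=0.23, trough=0.32):
        r = np.arange(0.0, 0.6, 0.002) + 0.001
        g = np.exp(-((r - peak) ** 2) / 0.002) * 2.5 + 1.0 - np.exp(-((r - trough) ** 2) / 0.0005) * 0.8
        return RDFCurve(r=r, g=g)

    def test_constructed_peak_and_trough(self):
        assert first_minimum(self._curve(), smoothing_window=5) == pytest.approx(0.32, abs=0.01)

    def test_window_one_is_raw_argmin_logic(self):
        assert first_minimum(self._curve(), smoothing_window=1) == pytest.approx(0.32, abs=0.01)

    def test_stable_under_small_noise(self):
        rng = np.random.default_rng(0)
        base = self._curve()
        noisy = RDFCurve(r=base.r, g=base.g * (1 + 0.01 * rng.normal(size=len(base.g))))
        assert first_minimum(noisy, smoothing_window=5) == pytest.approx(0.32, abs=0.004)  # +-2 bins

    def test_monotone_curve_rejected(self):
        r = np.linspace(0.01, 1.0, 100)
        with pytest.raises(ValueError, match="minimum"):
            first_minimum(RDFCurve(r=r, g=r * 2.0))


def brute_force_coordination(coords, box, ion_pos, oxy_idx, cutoff):
    n = 0
    for j in oxy_idx:
        if np.linalg.norm(minimum_image(coords[j] - ion_pos, box)) < cutoff:
            n += 1
    return n


class TestCoordination:
    def test_constructed_shell_count(self):
        top, coords, box = build_hydration_fixture(6, 0.235, n_far=8, r_far=0.8)
        traj = Trajectory(coords=coords[None], box=box[None], times=np.zeros(1))
        ions = select_group(top, role="cation")
        waters = select_group(top, role="water_oxygen")
        res = coordination_numbers(traj, ions, None, {"water": waters}, cutoff=0.32)
        assert res.mean_total == 6.0
        assert res.mean_by_source["water"] == 6.0

    def test_source_split_five_waters_one_carbonyl(self):
        top, coords, box = build_hydration_fixture(6, 0.235)
        # relabel one shell oxygen as a peptide carbonyl oxygen
        waters = AtomGroup(top, np.arange(1, 6))
        carbonyl = AtomGroup(top, [6])
        traj = Trajectory(coords=coords[None], box=box[None], times=np.zeros(1))
        ions = select_group(top, role="cation")
        res = coordination_numbers(traj, ions, None, {"water": waters, "carbonyl": carbonyl}, cutoff=0.32)
        assert res.mean_by_source == {"water": 5.0, "carbonyl": 1.0}
        assert res.mean_total == 6.0

    def test_empty_shell_counts_zero(self):
        top, coords, box = build_hydration_fixture(0, 0.235, n_far=5, r_far=0.9)
        traj = Trajectory(coords=coords[None], box=box[None], times=np.zeros(1))
        res = coordination_numbers(traj, select_group(top, role="cation"), None,
                                   {"water": select_group(top, role="water_oxygen")}, cutoff=0.32)
        assert res.mean_total == 0.0

    def test_matches_pairwise_oracle_on_random_frames(self, pore_system):
        ions = select_group(pore_system.topology, role="cation")
        waters = select_group(pore_system.topology, role="water_oxygen")
        traj = pore_system.trajectory
        cutoff = 0.4
        res = coordination_numbers(traj, ions, None, {"water": waters}, cutoff=cutoff)
        # recompute a few frames brute force
        obs = np.asarray(res.counts_by_source["water"]).reshape(traj.n_frames, len(ions))
        for f in (0, 60):
            for i, ion_atom in enumerate(ions.indices):
                brute = brute_force_coordination(traj.coords[f], traj.box[f], traj.coords[f, ion_atom], waters.indices, cutoff)
                assert obs[f, i] == brute

    def test_monotone_in_cutoff(self):
        top, coords, box = build_hydration_fixture(6, 0.235, n_far=8, r_far=0.8)
        traj = Trajectory(coords=coords[None], box=box[None], times=np.zeros(1))
        ions = select_group(top, role="cation")
        waters = select_group(top, role="water_oxygen")
        means = [coordination_numbers(traj, ions, None, {"w": waters}, cutoff=c).mean_total
                 for c in (0.1, 0.25, 0.5, 0.85, 1.2)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_never_inside_rejected(self):
        top, coords, box = build_hydration_fixture(3, 0.3)
        region = PoreRegion((0.1, 0.1), 0.0, 0.2, 0.05)  # far from the fixture
        traj = Trajectory(coords=coords[None], box=box[None], times=np.zeros(1))
        with pytest.raises(ValueError, match="inside"):
            coordination_numbers(traj, select_group(top, role="cation"), region,
                                 {"w": select_group(top, role="water_oxygen")}, cutoff=0.3)


class TestSelectivity:
    def test_anions_never_enter_flags_infinite(self):
        z = np.zeros(4)
        cat = [IonTrace(0, "cation", z, np.array([True, False, False, True]))]
        ani = [IonTrace(1, "anion", z, np.zeros(4, dtype=bool))]
        rep = selectivity_summary(cat, ani)
        assert rep.infinite and rep.ratio == float("inf")

    def test_equal_entrants_ratio_one(self):
        z = np.zeros(3)
        inside = np.array([True, False, False])
        rep = selectivity_summary(
            [IonTrace(0, "cation", z, inside)], [IonTrace(1, "anion", z, inside.copy())]
        )
        assert rep.ratio == 1.0 and not rep.infinite

    def test_full_anion_penalty_blocks_all_anions(self):
        spec = PoreSystemSpec(n_waters=50, n_cations=15, n_anions=15, n_steps=120, seed=6, anion_pore_penalty=1.0)
        sys_ = simulate_pore_system(spec)
        region = sys_.truth.region
        cat = ion_z_traces(sys_.trajectory, select_group(sys_.topology, role="cation"), region)
        ani = ion_z_traces(sys_.trajectory, select_group(sys_.topology, role="anion"), region)
        rep = selectivity_summary(cat, ani)
        assert rep.anion_entrants == 0 == len(sys_.truth.entrant_anions)


class TestIonicStrengthArithmetic:
    def test_physiological_nacl_in_bilayer_box(self):
        assert ion_pairs_for_molarity(0.15, (12.7, 13.4, 8.5)) == 131

    def test_zero_concentration(self):
        assert ion_pairs_for_molarity(0.0, (5.0, 5.0, 5.0)) == 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            ion_pairs_for_molarity(-0.1, (5.0, 5.0, 5.0))
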