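"""Dual-basin model construction, forces, dynamics and free energies."""

import numpy as np
import pytest

from transpath import fixtures as fx
from transpath.cgsim import (
    CgSystem,
    HillsLog,
    MetaDParams,
    SimParams,
    SimulationBlowUp,
    build_dual_basin,
    build_single_basin,
    compute_fes,
    compute_fes_1d,
    contact_map,
    cv_rmsd,
    potential_energy,
    run_dynamics,
    run_metadynamics,
)
from transpath.constants import KB
from transpath.structio import StatePair, superpose_rmsd


@pytest.fixture(scope="module")
def toy_model(toy40):
    return build_dual_basin(toy40.pair)


@pytest.fixture(scope="module")
def small_chain(rng):
    """10-residue compact chain for force checks."""
    return fx.make_toy_two_state(20, 100.0, seed=9)


class TestBuildDualBasin:
    def test_identical_states_have_no_unique_contacts(self, toy40):
        a = toy40.pair.state_a
        pair = StatePair("dup", a, a,
                         residue_map=tuple((i, i) for i in range(len(a))))
        model = build_dual_basin(pair)
        assert len(model.contacts_unique_a) == 0
        assert len(model.contacts_unique_b) == 0

    def test_contact_partition_matches_fixture_ground_truth(self, toy40,
                                                            toy_model):
        assert set(map(tuple, toy_model.contacts_unique_a)) == set(
            toy40.known_unique_contacts_a)
        assert set(map(tuple, toy_model.contacts_unique_b)) == set(
            toy40.known_unique_contacts_b)
        assert set(map(tuple, toy_model.contacts_common)) == set(
            toy40.known_common_contacts)

    def test_common_r0_is_mean_of_states(self, toy40, toy_model):
        np.testing.assert_allclose(
            toy_model.r0_common,
            (toy_model.r0_common_a + toy_model.r0_common_b) / 2)

    def test_state_a_is_stationary_for_a_side_terms(self, toy40, toy_model):
        ca, _ = toy40.pair.mapped_coords()
        _, f = potential_energy(toy_model, ca, contact_sets=("common", "a"),
                                common_r0="a", include_repulsion=False)
        assert np.abs(f).max() < 1e-3

    def test_too_few_residues_raises(self, toy40):
        a = toy40.pair.state_a
        pair = StatePair("tiny", a, a, residue_map=((0, 0), (1, 1), (2, 2)))
        with pytest.raises(ValueError):
            build_dual_basin(pair)


class TestPotentialEnergy:
    def test_contacts_at_minimum_contribute_minus_epsilon(self, toy40):
        model = build_single_basin(toy40.pair.state_a)
        coords = toy40.pair.state_a.coords
        e, _ = potential_energy(model, coords, include_repulsion=False)
        # bonded terms vanish at the reference; each contact sits at -eps
        assert e == pytest.approx(-len(model.contacts_common)
                                  * model.params.epsilon, abs=1e-9)

    def test_forces_match_finite_differences(self, small_chain):
        model = build_dual_basin(small_chain.pair)
        rng = np.random.default_rng(4)
        coords = small_chain.pair.state_a.coords + rng.normal(0, 0.01, (20, 3))
        e, f = potential_energy(model, coords)
        h = 1e-6
        for i in (0, 7, 19):
            for d in range(3):
                cp, cm = coords.copy(), coords.copy()
                cp[i, d] += h
                cm[i, d] -= h
                fd = -(potential_energy(model, cp)[0]
                       - potential_energy(model, cm)[0]) / (2 * h)
                assert f[i, d] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_translation_invariance(self, toy40, toy_model):
        ca, _ = toy40.pair.mapped_coords()
        e1, _ = potential_energy(toy_model, ca)
        e2, _ = potential_energy(toy_model, ca + np.array([1.0, -0.7, 2.0]))
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_coincident_beads_raise(self, toy_model):
        coords = np.zeros((toy_model.n_atoms, 3))
        with pytest.raises(FloatingPointError):
            potential_energy(toy_model, coords)


class TestCvRmsd:
    def test_identity_and_rigid_invariance(self, toy40):
        ca, _ = toy40.pair.mapped_coords()
        assert cv_rmsd(ca, ca) == pytest.approx(0.0, abs=1e-12)
        from scipy.spatial.transform import Rotation
        r = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        assert cv_rmsd(ca @ r.T + 5.0, ca) < 1e-10

    def test_matches_superposition_oracle(self, toy40):
        ca, cb = toy40.pair.mapped_coords()
        assert cv_rmsd(ca, cb) == pytest.approx(superpose_rmsd(ca, cb),
                                                abs=1e-12)

    def test_compiled_kernel_agrees(self, toy40, rng):
        from transpath.cgsim.kernels import rmsd_and_grad
        ca, cb = toy40.pair.mapped_coords()
        x = ca + rng.normal(0, 0.1, ca.shape)
        r, _ = rmsd_and_grad(x, cb)
        assert r == pytest.approx(superpose_rmsd(x, cb), abs=1e-10)


class TestDynamics:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_basin_stability_low_temperature(self, toy40, toy_model, seed):
        # both endpoints are metastable: short unbiased low-T runs stay in
        # their own basin (time-mean CV below 0.3 nm, never closer to the
        # other reference than to their own)
        ca, cb = toy40.pair.mapped_coords()
        system = CgSystem(toy_model, refs=[ca, cb])
        sim = SimParams(dt=0.0005, temperature=50.0, friction=2.0,
                        n_steps=10_000, frame_stride=1000)
        traj_a = run_dynamics(system, ca, sim, seed=seed)
        traj_b = run_dynamics(system, cb, sim, seed=seed + 10)
        assert traj_a.cvs[:, 0].mean() < 0.3
        assert traj_b.cvs[:, 1].mean() < 0.3
        assert np.all(traj_a.cvs[:, 0] < traj_a.cvs[:, 1])
        assert np.all(traj_b.cvs[:, 1] < traj_b.cvs[:, 0])

    def test_energy_conservation_without_friction(self, small_chain):
        model = build_dual_basin(small_chain.pair)
        system = CgSystem(model, refs=[])
        ca = small_chain.pair.state_a.coords

        def total_energy(n_steps):
            sim = SimParams(dt=0.0005, temperature=50.0, friction=0.0,
                            n_steps=n_steps, frame_stride=n_steps)
            traj = run_dynamics(system, ca, sim, seed=3)
            kin = 0.5 * model.params.mass * np.sum(traj.final_velocities ** 2)
            return traj.energies[-1] + kin

        # same seed, zero friction: the first 1000 steps coincide, so the
        # difference is pure NVE drift over the following 1000 steps
        drift = abs(total_energy(2000) - total_energy(1000))
        assert drift < 1e-3

    def test_blow_up_reported_with_step(self, toy_model, toy40):
        ca, _ = toy40.pair.mapped_coords()
        system = CgSystem(toy_model, refs=[])
        sim = SimParams(dt=0.5, temperature=300.0, friction=0.1,
                        n_steps=2000, frame_stride=100)
        with pytest.raises(SimulationBlowUp):
            run_dynamics(system, ca, sim, seed=0)

    def test_deterministic_under_seed(self, toy_model, toy40):
        ca, cb = toy40.pair.mapped_coords()
        system = CgSystem(toy_model, refs=[ca, cb])
        sim = SimParams(dt=0.0005, temperature=80.0, friction=0.5,
                        n_steps=2000, frame_stride=500)
        t1 = run_dynamics(system, ca, sim, seed=7)
        t2 = run_dynamics(system, ca, sim, seed=7)
        np.testing.assert_array_equal(t1.final_coords, t2.final_coords)


class TestMetadynamics:
    def test_hill_count(self, toy_model, toy40):
        ca, cb = toy40.pair.mapped_coords()
        system = CgSystem(toy_model, refs=[ca, cb])
        sim = SimParams(dt=0.0005, temperature=80.0, friction=0.1,
                        n_steps=10_000, frame_stride=1000)
        traj = run_metadynamics(system, ca, sim,
                                MetaDParams(stride=500, temperature=80.0),
                                seed=1)
        assert len(traj.hills) == 20

    def test_well_tempered_heights_decay_in_start_basin(self):
        dw = fx.DoubleWell1D(barrier=8.0)
        sim = SimParams(dt=0.0005, temperature=110.0, friction=2.0,
                        n_steps=100_000, frame_stride=1000)
        metad = MetaDParams(stride=500, temperature=110.0)
        traj = run_metadynamics(dw, dw.start_coords(0), sim, metad, seed=2)
        near_start = np.abs(traj.hills.centers[:, 0] + 0.5) < 0.1
        h = traj.hills.heights[near_start]
        # visit-averaged decay: later deposits in the basin are smaller
        k = len(h) // 2
        assert k >= 2
        assert h[k:].mean() < h[:k].mean()
        assert np.all(traj.hills.heights > 0)
        assert np.all(np.diff(traj.hills.steps) > 0)

    def test_no_drift_without_bias(self, toy_model, toy40):
        ca, cb = toy40.pair.mapped_coords()
        system = CgSystem(toy_model, refs=[ca, cb])
        sim = SimParams(dt=0.0005, temperature=60.0, friction=5.0,
                        n_steps=10_000, frame_stride=100)
        traj = run_dynamics(system, ca, sim, seed=4)
        # stable mean potential energy: second-half mean close to
        # first-half mean relative to its fluctuation scale
        e = traj.energies[20:]
        half = len(e) // 2
        scale = e.std() + 1e-9
        assert abs(e[half:].mean() - e[:half].mean()) < scale


class TestComputeFes:
    def test_single_hill_depth_in_large_bias_factor_limit(self):
        hills = HillsLog(steps=[500], centers=[[0.5, 0.5]],
                         widths=[[0.05, 0.05]], heights=[2.0])
        grid = np.linspace(0, 1, 41)
        fes = compute_fes(hills, grid, grid, bias_factor=1e9)
        i = np.argmin(np.abs(grid - 0.5))
        # the hill's node is the minimum (0); far plateau sits at +height
        assert fes.F[i, i] == pytest.approx(0.0, abs=1e-12)
        assert fes.F[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_far_plateau_is_global_max_of_bias(self):
        hills = HillsLog(steps=[500, 1000], centers=[[0.2, 0.2], [0.3, 0.2]],
                         widths=[[0.05, 0.05]] * 2, heights=[1.0, 0.8])
        grid = np.linspace(0, 2, 81)
        fes = compute_fes(hills, grid, grid, bias_factor=50)
        assert fes.F[-1, -1] == pytest.approx(fes.F.max(), abs=1e-9)

    def test_two_seed_agreement_on_double_well(self):
        dw = fx.DoubleWell1D(barrier=8.0)
        metad = MetaDParams(stride=500, temperature=110.0)
        sim = SimParams(dt=0.0005, temperature=110.0, friction=2.0,
                        n_steps=250_000, frame_stride=2500)
        grid = np.linspace(-0.6, 0.6, 61)
        profiles = []
        for seed, start in ((1, 0), (2, 1)):
            traj = run_metadynamics(dw, dw.start_coords(start), sim, metad,
                                    seed=seed)
            profiles.append(compute_fes_1d(traj.hills, grid)[1])
        rms = np.sqrt(np.mean((profiles[0] - profiles[1]) ** 2))
        assert rms < 2.0

    def test_grid_not_covering_hills_warns(self):
        hills = HillsLog(steps=[500], centers=[[5.0, 5.0]],
                         widths=[[0.05, 0.05]], heights=[1.0])
        with pytest.warns(UserWarning, match="outside"):
            compute_fes(hills, np.linspace(0, 1, 11), np.linspace(0, 1, 11))

    def test_hills_log_round_trip(self, tmp_path):
        hills = HillsLog(steps=[500, 1000], centers=[[0.1, 0.9], [0.2, 0.8]],
                         widths=[[0.05, 0.05]] * 2, heights=[1.0, 0.9],
                         params=MetaDParams(temperature=100.0))
        path = tmp_path / "hills.txt"
        hills.write(path)
        back = HillsLog.read(path)
        np.testing.assert_allclose(back.centers, hills.centers)
        np.testing.assert_allclose(back.heights, hills.heights)
        assert back.params.temperature == 100.0
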