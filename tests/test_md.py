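"""MD engine and trajectory estimators, checked against analytic generators."""

import numpy as np
import pytest

from polyff.md import (MDConfig, ThermoSeries, Trajectory, density_average,
                       dihedral_distribution, einstein_diffusivity,
                       heat_capacity, radius_of_gyration, rdf, run_md)
from polyff.oracle import OracleCalculator, generate_chain
from polyff.system import AtomicSystem
from polyff.units import KB


def _flat_traj(frames, dt_ps=1.0, energies=None, volumes=None, unwrapped=None):
    n = len(frames)
    e = np.zeros(n) if energies is None else np.asarray(energies, float)
    v = np.full(n, np.nan) if volumes is None else np.asarray(volumes, float)
    u = [f.positions for f in frames] if unwrapped is None else unwrapped
    return Trajectory(frames, np.arange(n) * dt_ps, e, e, v, np.zeros(n), u)


class TestRunMD:
    def test_zero_steps_leaves_state(self, dimer_chain):
        system, topo = dimer_chain
        cfg = MDConfig(ensemble="NVE", dt=0.5, n_steps=0, seed=0,
                       sample_interval=0.0005)
        traj = run_md(system, OracleCalculator(topo), cfg)
        assert len(traj.frames) == 1
        assert np.array_equal(traj.frames[0].positions, system.positions)

    def test_nve_energy_conservation_and_dt_scaling(self, dimer_chain):
        system, topo = dimer_chain
        calc = OracleCalculator(topo)
        drifts = {}
        for dt, steps in ((0.5, 400), (0.25, 800)):
            cfg = MDConfig(ensemble="NVE", dt=dt, n_steps=steps,
                           temperature=300, sample_interval=0.02, seed=3)
            traj = run_md(system, calc, cfg)
            drifts[dt] = abs(traj.total_energies[-1] - traj.total_energies[0]) \
                / system.n_atoms
        assert drifts[0.25] < 2e-3
        assert drifts[0.5] / drifts[0.25] >= 3.0

    def test_seed_reproducible(self, dimer_chain):
        system, topo = dimer_chain
        calc = OracleCalculator(topo)
        cfg = MDConfig(ensemble="NVT", dt=0.5, n_steps=50, seed=9,
                       sample_interval=0.005)
        t1 = run_md(system, calc, cfg)
        t2 = run_md(system, calc, cfg)
        assert np.array_equal(t1.frames[-1].positions, t2.frames[-1].positions)

    def test_force_blowup_aborts_with_atom(self, dimer_chain):
        system, topo = dimer_chain
        bad = system.copy()
        bad.positions[0] = bad.positions[1] + [0.2, 0, 0]
        cfg = MDConfig(ensemble="NVE", dt=0.5, n_steps=10, force_limit=100.0,
                       sample_interval=0.005)
        with pytest.raises(RuntimeError, match="atom"):
            run_md(bad, OracleCalculator(topo), cfg)

    def test_production_preset_defaults(self):
        cfg = MDConfig()
        assert cfg.dt == 0.5
        assert cfg.n_steps * cfg.dt == 1e6  # 1 ns
        assert cfg.thermostat_tau == 50.0
        assert cfg.barostat_tau == 2.5
        assert cfg.sample_interval == 0.5

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            MDConfig(dt=-1.0)
        with pytest.raises(ValueError):
            MDConfig(ensemble="NPH")


class TestDensityAverage:
    def test_trailing_window_default(self):
        frames = [AtomicSystem(["O"], [[0, 0, 0]], np.eye(3) * 10, True)
                  for _ in range(10)]
        vols = np.array([1000.0] * 2 + [500.0] * 8)
        for f, v in zip(frames, vols):
            f.cell = np.eye(3) * v ** (1 / 3)
        traj = _flat_traj(frames, volumes=vols)
        mean, series = density_average(traj, window=0.8)
        from polyff.units import ATOMIC_MASSES
        expected = ATOMIC_MASSES["O"] * 1e24 / 6.02214076e23 / 500.0
        assert abs(mean - expected) < 1e-12

    def test_constant_volume_exact(self):
        frames = [AtomicSystem(["O", "H"], [[0, 0, 0], [1, 0, 0]],
                               np.eye(3) * 8, True) for _ in range(4)]
        traj = _flat_traj(frames, volumes=np.full(4, 512.0))
        mean, _ = density_average(traj)
        mass = frames[0].masses.sum()
        assert abs(mean - mass * 1e24 / 6.02214076e23 / 512.0) < 1e-12

    def test_synthetic_series_trailing_mean(self, rng):
        vols = rng.uniform(400, 600, 20)
        frames = [AtomicSystem(["C"], [[0, 0, 0]], np.eye(3) * 8, True)
                  for _ in range(20)]
        traj = _flat_traj(frames, volumes=vols)
        mean, series = density_average(traj, window=0.5)
        assert abs(mean - series[10:].mean()) < 1e-12

    def test_cluster_trajectory_rejected(self):
        frames = [AtomicSystem(["C"], [[0, 0, 0]]) for _ in range(3)]
        with pytest.raises(ValueError):
            density_average(_flat_traj(frames))


class TestEinsteinDiffusivity:
    def test_frozen_atoms_zero(self):
        frames = [AtomicSystem(["C"] * 4, np.arange(12).reshape(4, 3) * 1.0)
                  for _ in range(10)]
        D, t, msd = einstein_diffusivity(_flat_traj(frames))
        assert abs(D) < 1e-15
        assert np.abs(msd).max() < 1e-15

    def test_brownian_walkers_recovered(self):
        """Seeded random walk with analytic MSD = 6 D t."""
        rng = np.random.default_rng(7)
        D_true = 1e-5  # cm²/s
        D_A2ps = D_true * 1e4
        n_walk, n_steps, dt = 64, 10_000, 0.1
        steps = rng.normal(scale=np.sqrt(2 * D_A2ps * dt),
                           size=(n_steps, n_walk, 3))
        tracks = np.concatenate([np.zeros((1, n_walk, 3)),
                                 np.cumsum(steps, axis=0)])[::25]
        frames = [AtomicSystem(["H"] * n_walk, p) for p in tracks]
        # early-lag window: a pure random walk has no ballistic regime and
        # long lags carry most of the statistical error
        traj = _flat_traj(frames, dt_ps=dt * 25, unwrapped=list(tracks))
        D_est, _, _ = einstein_diffusivity(traj, fit_window=(0.01, 0.1))
        assert abs(D_est / D_true - 1) < 0.10

    def test_short_trajectory_rejected(self):
        frames = [AtomicSystem(["C"], [[0, 0, 0]]) for _ in range(2)]
        with pytest.raises(ValueError):
            einstein_diffusivity(_flat_traj(frames))


class TestHeatCapacity:
    def test_constant_energy_zero(self):
        assert heat_capacity(ThermoSeries(np.full(10, 3.3), 300.0)) == 0.0

    def test_two_point_population_variance(self):
        cp = heat_capacity(ThermoSeries(np.array([0.0, 2.0]), 300.0))
        assert abs(cp - 1.0 / (KB * 300.0 ** 2)) < 1e-12

    def test_gaussian_generator_recovered(self):
        rng = np.random.default_rng(11)
        var = 9.0
        e = rng.normal(loc=50.0, scale=np.sqrt(var), size=100_000)
        cp = heat_capacity(ThermoSeries(e, 300.0))
        assert abs(cp / (var / (KB * 300.0 ** 2)) - 1) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            heat_capacity(ThermoSeries(np.array([1.0, 2.0]), -5.0))
        with pytest.raises(ValueError):
            heat_capacity(ThermoSeries(np.array([1.0]), 300.0))


class TestRDF:
    def test_ideal_gas_tends_to_one(self):
        rng = np.random.default_rng(3)
        L = 20.0
        frames = []
        for _ in range(5):
            pos = rng.uniform(0, L, size=(500, 3))
            frames.append(AtomicSystem(["O"] * 500, pos, np.eye(3) * L, True))
        traj = _flat_traj(frames, volumes=np.full(5, L ** 3))
        r, g, _ = rdf(traj, ("O", "O"), r_max=8.0, n_bins=40)
        tail = g[len(g) // 2:]
        assert abs(tail.mean() - 1.0) < 0.05

    def test_fixed_pair_single_bin(self):
        d = 3.0
        s = AtomicSystem(["O", "H"], [[0, 0, 0], [d, 0, 0]], np.eye(3) * 12, True)
        traj = _flat_traj([s], volumes=np.array([12.0 ** 3]))
        r, g, counts = rdf(traj, ("O", "H"), r_max=5.0, n_bins=25)
        nz = np.nonzero(counts)[0]
        assert len(nz) == 1
        lo, hi = nz[0] * 0.2, (nz[0] + 1) * 0.2
        assert lo <= d < hi

    def test_raw_counts_equal_brute_force(self):
        rng = np.random.default_rng(5)
        L = 15.0
        pos = rng.uniform(0, L, size=(40, 3))
        species = ["O"] * 20 + ["H"] * 20
        s = AtomicSystem(species, pos, np.eye(3) * L, True)
        traj = _flat_traj([s, s], volumes=np.full(2, L ** 3))
        r_max = 6.0
        _, _, counts = rdf(traj, ("O", "H"), r_max=r_max, n_bins=30)
        from polyff.system import minimum_image_displacement
        n_pairs = 0
        for i in range(20):
            for j in range(20, 40):
                d = np.linalg.norm(minimum_image_displacement(
                    s.cell, True, pos[i], pos[j]))
                if d < r_max:
                    n_pairs += 1
        assert counts.sum() == 2 * n_pairs  # two identical frames

    def test_rmax_beyond_half_cell_rejected(self):
        s = AtomicSystem(["O"], [[0, 0, 0]], np.eye(3) * 10, True)
        with pytest.raises(ValueError):
            rdf(_flat_traj([s], volumes=np.array([1000.0])), ("O", "O"),
                r_max=6.0)


class TestRadiusOfGyration:
    def test_coincident_atoms_zero(self):
        s = AtomicSystem(["C", "C"], [[1, 1, 1], [1, 1, 1 + 1e-13]])
        rgs, _, _, var = radius_of_gyration(_flat_traj([s]), np.array([0, 1]))
        assert rgs[0] < 1e-10

    def test_two_unit_masses_closed_form(self):
        s = AtomicSystem(["H", "H"], [[0, 0, 0], [2, 0, 0]])
        rgs, _, _, _ = radius_of_gyration(_flat_traj([s]), np.array([0, 1]))
        assert abs(rgs[0] - 1.0) < 1e-12

    def test_matches_direct_formula(self, rng):
        pos = rng.normal(size=(8, 3)) * 3
        s = AtomicSystem(list(rng.choice(["H", "C", "O"], 8)), pos)
        rgs, _, _, _ = radius_of_gyration(_flat_traj([s]), np.arange(8))
        m = s.masses
        com = m @ pos / m.sum()
        expect = np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum())
        assert abs(rgs[0] - expect) < 1e-12


class TestDihedralDistribution:
    def test_trans_chain_single_bin(self):
        pos = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
        s = AtomicSystem(["O", "C", "C", "O"], pos)
        centers, counts, skipped = dihedral_distribution(
            _flat_traj([s]), [(0, 1, 2, 3)], n_bins=72)
        assert skipped == 0
        assert counts.sum() == 1
        assert abs(abs(centers[np.argmax(counts)]) - 177.5) < 5.0

    def test_cis_geometry_zero_angle(self):
        pos = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        s = AtomicSystem(["O", "C", "C", "O"], pos)
        centers, counts, _ = dihedral_distribution(_flat_traj([s]),
                                                   [(0, 1, 2, 3)], n_bins=72)
        assert abs(centers[np.argmax(counts)]) < 5.0

    def test_histogram_mass_conserved_with_skips(self):
        good = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
        collinear = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        s1 = AtomicSystem(["O", "C", "C", "O"], good)
        s2 = AtomicSystem(["O", "C", "C", "O"], collinear)
        _, counts, skipped = dihedral_distribution(
            _flat_traj([s1, s2]), [(0, 1, 2, 3)], n_bins=36)
        assert counts.sum() == 1 and skipped == 1

    def test_chain_distribution_covers_basins(self):
        system, topo = generate_chain(10, seed=3)
        traj = _flat_traj([system])
        centers, counts, skipped = dihedral_distribution(
            traj, topo.backbone_dihedrals, n_bins=36)
        assert counts.sum() + skipped == len(topo.backbone_dihedrals)


def test_estimators_are_pure_functions(dimer_chain):
    system, topo = dimer_chain
    cfg = MDConfig(ensemble="NVT", dt=0.5, n_steps=60, seed=2,
                   sample_interval=0.005)
    traj = run_md(system, OracleCalculator(topo), cfg)
    d1 = einstein_diffusivity(traj, fit_window=(0.2, 0.8))[0]
    d2 = einstein_diffusivity(traj, fit_window=(0.2, 0.8))[0]
    assert d1 == d2
    c1 = heat_capacity(ThermoSeries(traj.total_energies, 300.0))
    c2 = heat_capacity(ThermoSeries(traj.total_energies, 300.0))
    assert c1 == c2
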