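"""The QRNN energy model: Qeq charges, Coulomb/dispersion terms, analytic
forces, symmetries, and the batched-evaluation equivalence."""

import numpy as np
import pytest

from polyff import autodiff as ad
from polyff.batch import SystemBatch
from polyff.descriptors import DescriptorConfig
from polyff.model import (DispersionParams, QRNNHyper, QRNNModel,
                          coulomb_energy, dipole_moment, dispersion_energy,
                          predict_electronegativities, recursive_charges,
                          solve_qeq)
from polyff.system import AtomicSystem
from polyff.units import KE_COULOMB

from conftest import random_cluster


class TestSolveQeq:
    def test_two_identical_atoms_neutral(self):
        q = solve_qeq([0.5, 0.5], [100.0, 100.0], [0.8, 0.8],
                      [[0, 0, 0], [2, 0, 0]], total_charge=0)
        assert np.abs(q).max() < 1e-12

    def test_two_identical_atoms_cation(self):
        q = solve_qeq([0.5, 0.5], [100.0, 100.0], [0.8, 0.8],
                      [[0, 0, 0], [2, 0, 0]], total_charge=1)
        assert np.allclose(q, [0.5, 0.5], atol=1e-12)

    def test_local_mode_closed_form(self):
        # E = χ2 q2 + (q1² + q2²)/2, Σq = 0 → q = (0.5, -0.5)
        q = solve_qeq([0.0, 1.0], [1.0, 1.0], [0.8, 0.8],
                      [[0, 0, 0], [2, 0, 0]], total_charge=0, mode="local")
        assert np.allclose(q, [0.5, -0.5], atol=1e-12)

    def test_full_mode_minimizes_constrained_energy(self, rng):
        """The returned charges beat random feasible perturbations."""
        n = 5
        pos = random_cluster(rng, n).positions
        chi = rng.normal(size=n)
        J = np.full(n, 150.0)
        gamma = np.full(n, 0.8)
        q = solve_qeq(chi, J, gamma, pos, total_charge=0)
        assert abs(q.sum()) < 1e-10

        def energy(qv):
            e = chi @ qv + 0.5 * (J * qv ** 2).sum()
            for i in range(n):
                for j in range(i + 1, n):
                    r = np.linalg.norm(pos[j] - pos[i])
                    gij = np.sqrt(gamma[i] ** 2 + gamma[j] ** 2)
                    from scipy.special import erf
                    e += KE_COULOMB * qv[i] * qv[j] * erf(r / (np.sqrt(2) * gij)) / r
            return e

        e0 = energy(q)
        for _ in range(20):
            dq = rng.normal(size=n) * 0.01
            dq -= dq.mean()  # stay on the constraint surface
            assert energy(q + dq) >= e0 - 1e-9


class TestCoulomb:
    def test_null_charges(self):
        assert coulomb_energy([0, 0], [[0, 0, 0], [1, 0, 0]]) == 0

    def test_single_atom(self):
        assert coulomb_energy([1.0], [[0, 0, 0]]) == 0

    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_energy([1.0, -1.0], [[0, 0, 0], [1, 0, 0]])
        assert abs(e + KE_COULOMB) < 1e-10

    def test_coincident_charges_raise(self):
        with pytest.raises(ValueError):
            coulomb_energy([1.0, 1.0], [[0, 0, 0], [1e-9, 0, 0]])


class TestDispersion:
    def test_single_atom_zero(self):
        assert dispersion_energy(AtomicSystem(["C"], [[0, 0, 0]])) == 0

    def test_far_pair_reaches_asymptote(self):
        params = DispersionParams()
        s = AtomicSystem(["C", "C"], [[0, 0, 0], [20.0, 0, 0]])
        c6, _ = params.pair("C", "C")
        e = dispersion_energy(s, params)
        assert abs(e / (-c6 / 20.0 ** 6) - 1) < 1e-3

    def test_close_pair_damped(self):
        params = DispersionParams()
        s = AtomicSystem(["C", "C"], [[0, 0, 0], [0.1, 0, 0]])
        c6, r0 = params.pair("C", "C")
        assert abs(dispersion_energy(s, params)) < 1e-3 * c6 / r0 ** 6

    def test_missing_pair_parameters(self):
        params = DispersionParams(c6={"H": 1.0}, r0={"H": 1.0})
        s = AtomicSystem(["C", "C"], [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="dispersion"):
            dispersion_energy(s, params)


class TestDipole:
    def test_zero_charges(self):
        assert np.allclose(dipole_moment([0, 0], [[0, 0, 0], [1, 0, 0]]), 0)

    def test_origin_invariance_for_neutral(self, rng):
        pos = rng.normal(size=(6, 3))
        q = rng.normal(size=6)
        q -= q.mean()
        mu1 = dipole_moment(q, pos)
        mu2 = dipole_moment(q, pos + 17.3)
        assert np.abs(mu1 - mu2).max() < 1e-12

    def test_unit_dipole(self):
        mu = dipole_moment([1.0, -1.0], [[1, 0, 0], [0, 0, 0]])
        assert np.allclose(mu, [1, 0, 0], atol=1e-12)


class TestElectronegativityHead:
    def test_zero_weight_network_gives_bias(self, desk_model, rng):
        model = desk_model.copy()
        for e in model.descriptor.element_order:
            last = model.params["chi"][e][-1]
            last["v"][:] = 1e-12
            last["g"][:] = 0.0
            last["b"][:] = 3.5
        cluster = random_cluster(rng, 6)
        from polyff.descriptors import compute_aev
        aev = compute_aev(cluster, model.descriptor)
        chi = predict_electronegativities(aev, model, cluster.species)
        assert np.allclose(chi, 3.5 * model.hyper.chi_scale, atol=1e-9)

    def test_symmetry_equivalent_atoms_equal_chi(self, desk_model):
        s = AtomicSystem(["O", "H", "H"],
                         [[0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
        from polyff.descriptors import compute_aev
        chi = predict_electronegativities(compute_aev(s, desk_model.descriptor),
                                          desk_model, s.species)
        assert abs(chi[1] - chi[2]) < 1e-12


class TestRecursion:
    def test_iterations_one_matches_plain_qeq_features(self, desk_model, rng):
        cluster = random_cluster(rng, 7)
        qs = recursive_charges(cluster, desk_model, iterations=1)
        assert len(qs) == 1
        q2 = recursive_charges(cluster, desk_model, iterations=2)
        assert np.allclose(qs[0], q2[0], atol=1e-12)

    def test_default_is_two_iterations(self, desk_model):
        assert desk_model.hyper.qeq_iterations == 2

    def test_zeroed_charge_features_give_fixed_point(self, rng):
        """If the χ network ignores the charge-weighted block, the second
        Qeq solve reproduces the first exactly."""
        cfg = DescriptorConfig.desk_scale()
        model = QRNNModel(cfg, QRNNHyper(chi_hidden=(8,), energy_hidden=(8,)),
                          seed=3)
        for e in cfg.element_order:
            first = model.params["chi"][e][0]
            first["v"][:, cfg.length:] = 0.0  # charge-feature columns
        cluster = random_cluster(rng, 8)
        q1, q2 = recursive_charges(cluster, model, iterations=2)
        assert np.abs(q2 - q1).max() < 1e-12

    def test_invalid_iterations(self, desk_model, rng):
        with pytest.raises(ValueError):
            recursive_charges(random_cluster(rng, 4), desk_model, iterations=0)


class TestEnergyAndForces:
    def test_breakdown_sums_exactly(self, desk_model, rng):
        out = desk_model.evaluate(random_cluster(rng, 10))
        assert out.E_total == out.E_short + out.E_coulomb + out.E_dispersion

    def test_charge_conservation(self, desk_model, rng):
        for _ in range(5):
            s = random_cluster(rng, int(rng.integers(3, 12)))
            s.total_charge = int(rng.integers(-1, 2))
            out = desk_model.evaluate(s, forces=False)
            assert abs(out.charges.sum() - s.total_charge) < 1e-10
            assert abs(out.charges_iter1.sum() - s.total_charge) < 1e-10

    def test_net_force_vanishes_for_cluster(self, desk_model, rng):
        out = desk_model.evaluate(random_cluster(rng, 9))
        assert np.abs(out.forces.sum(axis=0)).max() < 1e-8

    def test_forces_match_finite_differences(self, desk_model, rng):
        s = random_cluster(rng, 8)
        out = desk_model.evaluate(s)
        h = 1e-4
        for i in range(0, 8, 3):
            for k in range(3):
                pp, pm = s.positions.copy(), s.positions.copy()
                pp[i, k] += h
                pm[i, k] -= h
                ep = desk_model.evaluate(AtomicSystem(s.species, pp), forces=False).E_total
                em = desk_model.evaluate(AtomicSystem(s.species, pm), forces=False).E_total
                assert abs(-(ep - em) / (2 * h) - out.forces[i, k]) < 1e-3

    def test_translation_invariance(self, desk_model, rng):
        s = random_cluster(rng, 8)
        e0 = desk_model.evaluate(s, forces=False).E_total
        moved = AtomicSystem(s.species, s.positions + [3.1, -7.2, 0.4])
        assert abs(desk_model.evaluate(moved, forces=False).E_total - e0) < 1e-9

    def test_rotation_covariance_of_forces(self, desk_model, rng):
        s = random_cluster(rng, 8)
        out = desk_model.evaluate(s)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        rot = AtomicSystem(s.species, s.positions @ Q.T)
        out_r = desk_model.evaluate(rot)
        assert abs(out_r.E_total - out.E_total) < 1e-8
        assert np.abs(out_r.forces - out.forces @ Q.T).max() < 1e-8

    def test_energy_smooth_across_cutoff(self, desk_model):
        """No jump as an atom crosses the radial cutoff."""
        rc = desk_model.descriptor.radial_cutoff
        es = []
        for x in np.arange(rc - 2e-4, rc + 2e-4, 1e-4):
            s = AtomicSystem(["C", "O"], [[0, 0, 0], [x, 0, 0]])
            es.append(desk_model.evaluate(s, forces=False).E_total)
        assert np.abs(np.diff(es)).max() < 1e-4


class TestBatchedEvaluation:
    def test_matches_single_system_path(self, desk_model, rng):
        systems = [random_cluster(rng, int(n)) for n in (4, 9, 13)]
        sb = SystemBatch(systems, desk_model)
        out = sb.forward(QRNNModel.params_t(desk_model.params), need_forces=True)
        for b, s in enumerate(systems):
            single = desk_model.evaluate(s)
            assert abs(single.E_total - out["E"].numpy()[b]) < 1e-10
            sl = slice(sb.offsets[b], sb.offsets[b + 1])
            assert np.abs(single.forces - out["forces"].numpy()[sl]).max() < 1e-9
            assert np.abs(single.charges - out["charges"].numpy()[sl]).max() < 1e-11
            assert np.abs(single.dipole - out["dipoles"].numpy()[b]).max() < 1e-11

    def test_rejects_periodic_systems(self, desk_model):
        s = AtomicSystem(["H"], [[0, 0, 0]], np.eye(3) * 20, pbc=True)
        with pytest.raises(ValueError):
            SystemBatch([s], desk_model)


def test_model_save_load_round_trip(tmp_path, desk_model, rng):
    p = tmp_path / "model.json"
    desk_model.save(p)
    back = QRNNModel.load(p)
    assert back.parameter_hash() == desk_model.parameter_hash()
    s = random_cluster(rng, 6)
    assert abs(back.evaluate(s, forces=False).E_total
               - desk_model.evaluate(s, forces=False).E_total) < 1e-12
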