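"""Structure records, extended-XYZ round trips, and periodic geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyff.system import (AtomicSystem, minimum_image_displacement,
                           molecule_partition, read_extxyz, write_extxyz,
                           guess_bonds, find_backbone_dihedrals,
                           save_dataset, load_dataset, Dataset, LabeledSample)


class TestAtomicSystem:
    def test_rejects_pbc_without_invertible_cell(self):
        with pytest.raises(ValueError):
            AtomicSystem(["H"], [[0, 0, 0]], cell=np.zeros((3, 3)), pbc=True)

    def test_rejects_nonfinite_positions(self):
        with pytest.raises(ValueError):
            AtomicSystem(["H"], [[np.nan, 0, 0]])

    def test_center_of_mass_weighting(self):
        s = AtomicSystem(["O", "H"], [[0, 0, 0], [1, 0, 0]])
        com = s.center_of_mass()
        assert 0 < com[0] < 0.5  # pulled toward the heavy oxygen


class TestExtxyz:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        assert read_extxyz(p) == []

    def test_round_trip_with_labels(self, tmp_path, rng):
        pos = rng.normal(size=(10, 3)) * 3
        s = AtomicSystem(list(rng.choice(["H", "C", "O"], 10)), pos)
        labels = {"energy": -12.5, "forces": rng.normal(size=(10, 3)),
                  "charges": rng.normal(size=10) * 0.3}
        p = tmp_path / "frame.xyz"
        write_extxyz([(s, labels)], p)
        [(s2, l2)] = read_extxyz(p)
        assert s2.species == s.species
        assert np.abs(s2.positions - pos).max() < 1e-12
        assert abs(l2["energy"] - labels["energy"]) < 1e-12
        assert np.abs(l2["forces"] - labels["forces"]).max() < 1e-12
        assert np.abs(l2["charges"] - labels["charges"]).max() < 1e-12

    def test_periodic_cell_round_trip(self, tmp_path):
        cell = np.array([[10.0, 0, 0], [1.0, 9.0, 0], [0, 0.5, 11.0]])
        s = AtomicSystem(["C", "O"], [[1, 1, 1], [2, 2, 2]], cell, pbc=True)
        p = tmp_path / "cell.xyz"
        write_extxyz([(s, {})], p)
        [(s2, _)] = read_extxyz(p)
        assert s2.pbc
        assert np.abs(s2.cell - cell).max() < 1e-12

    def test_frame_without_lattice_is_nonperiodic(self, tmp_path):
        p = tmp_path / "plain.xyz"
        p.write_text("1\ncomment line\nH 0.0 0.0 0.0\n")
        [(s, _)] = read_extxyz(p)
        assert not s.pbc and s.cell is None

    def test_minimal_frame_is_three_lines(self, tmp_path):
        s = AtomicSystem(["H"], [[0, 0, 0]])
        p = tmp_path / "one.xyz"
        write_extxyz([(s, {})], p)
        assert len(p.read_text().strip().splitlines()) == 3

    def test_writes_are_byte_identical(self, tmp_path, rng):
        s = AtomicSystem(list(rng.choice(["H", "O"], 5)), rng.normal(size=(5, 3)))
        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        write_extxyz([(s, {})], p1)
        write_extxyz([(s, {})], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("notanumber\ncomment\n")
        with pytest.raises(ValueError, match="line 1"):
            read_extxyz(p)

    def test_multi_frame_order_preserved(self, tmp_path):
        frames = [(AtomicSystem(["H"], [[float(k), 0, 0]]), {"energy": float(k)})
                  for k in range(4)]
        p = tmp_path / "multi.xyz"
        write_extxyz(frames, p)
        back = read_extxyz(p)
        assert [l["energy"] for _, l in back] == [0.0, 1.0, 2.0, 3.0]


class TestMoleculePartition:
    def test_single_chain_is_one_molecule(self):
        s = AtomicSystem(["C"] * 10, np.arange(30).reshape(10, 3) * 1.0)
        mol, m = molecule_partition(s, [(i, i + 1) for i in range(9)])
        assert m == 1 and set(mol) == {0}

    def test_two_disjoint_chains(self):
        s = AtomicSystem(["C"] * 10, np.arange(30).reshape(10, 3) * 1.0)
        bonds = [(i, i + 1) for i in range(4)] + [(i, i + 1) for i in range(5, 9)]
        mol, m = molecule_partition(s, bonds)
        assert m == 2
        assert set(mol[:5]) == {0} and set(mol[5:]) == {1}

    def test_matches_union_find_oracle_on_random_graph(self, rng):
        n = 50
        s = AtomicSystem(["C"] * n, rng.normal(size=(n, 3)))
        bonds = [tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(40)]
        mol, m = molecule_partition(s, bonds)
        # independent oracle: iterative label propagation to fixpoint
        labels = np.arange(n)
        changed = True
        while changed:
            changed = False
            for i, j in bonds:
                lo = min(labels[i], labels[j])
                if labels[i] != lo or labels[j] != lo:
                    labels[labels == labels[i]] = lo
                    labels[labels == labels[j]] = lo
                    changed = True
        assert m == len(set(labels))
        for i in range(n):
            for j in range(n):
                assert (mol[i] == mol[j]) == (labels[i] == labels[j])

    def test_invariant_to_bond_permutation(self, rng):
        n = 20
        s = AtomicSystem(["C"] * n, rng.normal(size=(n, 3)))
        bonds = [(0, 1), (1, 2), (5, 6), (6, 7), (10, 11)]
        mol1, _ = molecule_partition(s, bonds)
        perm = list(bonds)
        rng.shuffle(perm)
        mol2, _ = molecule_partition(s, perm)
        assert np.array_equal(mol1, mol2)

    def test_out_of_range_bond_raises(self):
        s = AtomicSystem(["C"], [[0, 0, 0]])
        with pytest.raises(ValueError):
            molecule_partition(s, [(0, 5)])


class TestMinimumImage:
    def test_wraps_across_cubic_boundary(self):
        d = minimum_image_displacement(np.eye(3) * 10, True,
                                       np.zeros(3), np.array([9.9, 0, 0]))
        assert np.allclose(d, [-0.1, 0, 0], atol=1e-12)

    def test_enumeration_oracle_triclinic(self, rng):
        """Fractional rounding equals 27-image enumeration inside its
        validity regime (separations below half the minimum cell width)."""
        from polyff.descriptors import _cell_widths
        cell = np.array([[8.0, 0, 0], [2.0, 7.0, 0], [1.0, 1.5, 9.0]])
        half_width = 0.5 * _cell_widths(cell).min()
        checked = 0
        for _ in range(200):
            r1 = rng.uniform(0, 8, 3)
            r2 = rng.uniform(0, 8, 3)
            d = minimum_image_displacement(cell, True, r1, r2)
            # brute force over 27 periodic images
            best = np.inf
            for a in (-1, 0, 1):
                for b in (-1, 0, 1):
                    for c in (-1, 0, 1):
                        img = r2 - r1 + np.array([a, b, c]) @ cell
                        best = min(best, np.linalg.norm(img))
            if best < half_width:
                assert abs(np.linalg.norm(d) - best) < 1e-10
                checked += 1
        assert checked > 20  # the regime was actually exercised

    def test_nonperiodic_plain_difference(self):
        d = minimum_image_displacement(None, False, np.zeros(3),
                                       np.array([100.0, 0, 0]))
        assert np.allclose(d, [100, 0, 0])

    def test_identity(self):
        r = np.array([3.0, 4.0, 5.0])
        assert np.allclose(minimum_image_displacement(np.eye(3) * 10, True, r, r), 0)

    def test_singular_cell_raises(self):
        with pytest.raises(ValueError):
            minimum_image_displacement(np.zeros((3, 3)), True,
                                       np.zeros(3), np.ones(3))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_minimum_image_never_longer_than_direct(self, seed):
        rng = np.random.default_rng(seed)
        cell = np.diag(rng.uniform(5, 15, 3)) + rng.uniform(-1, 1, (3, 3)) * 0.5
        if abs(np.linalg.det(cell)) < 1.0:
            return
        r1, r2 = rng.uniform(-20, 20, (2, 3))
        d = minimum_image_displacement(cell, True, r1, r2)
        assert np.linalg.norm(d) <= np.linalg.norm(r2 - r1) + 1e-9


class TestTopologyHelpers:
    def test_guess_bonds_recovers_chain_bonds(self, dimer_chain):
        system, topo = dimer_chain
        guessed = {tuple(sorted(b)) for b in guess_bonds(system)}
        true = {tuple(sorted(b)) for b in topo.bonds}
        assert guessed == true

    def test_backbone_dihedrals_are_occo(self, dimer_chain):
        system, topo = dimer_chain
        assert len(topo.backbone_dihedrals) == 2
        for (a, b, c, d) in topo.backbone_dihedrals:
            assert [system.species[x] for x in (a, b, c, d)] == ["O", "C", "C", "O"]


def test_hdf5_dataset_round_trip(tmp_path, tiny_dataset):
    p = tmp_path / "data.h5"
    save_dataset(tiny_dataset, p)
    back = load_dataset(p)
    assert len(back) == len(tiny_dataset)
    for a, b in zip(tiny_dataset.samples, back.samples):
        assert a.system.species == b.system.species
        assert np.abs(a.system.positions - b.system.positions).max() < 1e-12
        assert abs(a.energy - b.energy) < 1e-12
        assert np.abs(a.forces - b.forces).max() < 1e-12
        assert a.provenance == b.provenance
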