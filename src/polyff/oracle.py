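"""Synthetic reference oracle: structure generators and an analytic labeler.

The oracle plays the role of the reference electronic-structure theory in
the workflow: it builds ethylene-glycol-type oligomer chains
H(OCH₂CH₂)ₙOH and packed liquid cells, and labels any structure with an
analytic energy, exact forces, conformation-dependent per-atom reference
charges, and the resulting dipole.  Its functional form (harmonic bonds and
angles, cosine backbone torsions, Lennard-Jones and fixed-charge Coulomb
with 1-2/1-3/1-4 exclusions) deliberately overlaps the class of functions
the learned potential can represent, so that desk-scale label recovery is a
meaningful end-to-end test.  The parameters are shipped constants and make
no claim of chemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .system import (AtomicSystem, LabeledSample, Topology, CONFORMATIONAL,
                     find_backbone_dihedrals, minimum_image_table)
from .units import ATOMIC_MASSES, KE_COULOMB


@dataclass
class OracleParams:
    """Force-field constants of the analytic labeler (non-physical)."""

    # harmonic bonds: (element pair) -> (k_b kcal/mol/Å², r0 Å)
    bonds: dict = field(default_factory=lambda: {
        ("H", "O"): (520.0, 0.96), ("C", "O"): (320.0, 1.43),
        ("C", "C"): (310.0, 1.54), ("C", "H"): (340.0, 1.09)})
    # harmonic angles: k_θ kcal/mol/rad², θ0 rad
    angle_k: float = 50.0
    angle_theta0: float = np.deg2rad(109.5)
    # backbone cosine torsion V = k (1 + cos(n φ))
    dihedral_k: float = 0.5
    dihedral_n: int = 3
    # Lennard-Jones per element (Lorentz-Berthelot combination)
    lj_eps: dict = field(default_factory=lambda: {"H": 0.03, "C": 0.07, "O": 0.17})
    lj_sigma: dict = field(default_factory=lambda: {"H": 2.5, "C": 3.5, "O": 3.1})
    # fixed base charges by atom role, e (neutral per molecule for any n)
    base_charges: dict = field(default_factory=lambda: {
        "O_hydroxyl": -0.45, "H_hydroxyl": 0.30, "O_ether": -0.30,
        "C": 0.15, "H_C": 0.00})
    # geometry-dependent charge response amplitude, e
    charge_response: float = 0.1
    charge_response_bound: float = 0.3
    nonbonded_cutoff: float = 9.0   # Å, periodic systems


# -- geometry helpers -------------------------------------------------------

def _place_atom(a, b, c, bond, angle, dihedral):
    """Natural-extension placement of atom D from internal coordinates
    (D-c bond length, D-c-b angle, D-c-b-a dihedral)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear chain: pick any perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(bc @ probe) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, probe)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(dihedral),
                        bond * np.sin(angle) * np.sin(dihedral)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def signed_dihedral(p0, p1, p2, p3) -> float:
    """IUPAC signed dihedral angle in degrees, range (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate (collinear) dihedral geometry")
    b1u = b1 / np.linalg.norm(b1)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b1u
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# -- chain generation -------------------------------------------------------

_BOND_LENGTHS = {("H", "O"): 0.96, ("O", "H"): 0.96, ("O", "C"): 1.43,
                 ("C", "O"): 1.43, ("C", "C"): 1.54, ("C", "H"): 1.09}


def generate_chain(n_monomers: int, seed: int = 0, max_retries: int = 200):
    """Idealized H(OCH₂CH₂)ₙOH chain with randomized backbone dihedrals.

    The backbone grows by a self-avoiding random walk: each new heavy atom
    draws a torsion from the gauche/trans basins (with jitter) and is
    rejected on close contact with earlier atoms.  Atom count is 7n+3,
    bond count 7n+2.

    Returns ``(AtomicSystem, Topology)``.
    """
    if n_monomers < 1:
        raise ValueError("need at least one monomer")
    master = np.random.default_rng(seed)
    last_err = None
    for _ in range(30):
        try:
            system, topo = _grow_chain(n_monomers, master, max_retries)
        except RuntimeError as exc:
            last_err = exc
            continue
        # reject hard clashes (attached hydrogens are placed after the
        # backbone walk and can still collide across the chain), then
        # relieve the remaining soft contacts by a short relaxation
        excl = _exclusion_pairs(system.n_atoms, topo.bonds)
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(system.positions))
        ok = True
        for i in range(system.n_atoms):
            for j in range(i + 1, system.n_atoms):
                if (i, j) not in excl and d[i, j] < 0.9:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            system = _relax(system, topo)
            system.positions -= system.center_of_mass()
            return system, topo
    raise RuntimeError(f"self-avoiding chain generation failed: {last_err}")


def _relax(system: AtomicSystem, topo: Topology, max_steps: int = 150,
           f_tol: float = 20.0) -> AtomicSystem:
    """Deterministic steepest-descent contact relief."""
    calc = OracleCalculator(topo)
    out = calc.evaluate(system, forces=True)
    e, f = out.E_total, out.forces
    step = 1e-4
    sys_t = system
    for _ in range(max_steps):
        if np.abs(f).max() < f_tol:
            break
        trial = AtomicSystem(sys_t.species, sys_t.positions + step * f,
                             sys_t.cell, sys_t.pbc, sys_t.total_charge)
        out_t = calc.evaluate(trial, forces=True)
        if out_t.E_total < e:
            sys_t, e, f = trial, out_t.E_total, out_t.forces
            step *= 1.5
        else:
            step *= 0.4
            if step < 1e-9:
                break
    return sys_t


def _methylene_h(nb_prev, c, nb_next):
    """The two tetrahedral hydrogens of a backbone CH₂ carbon."""
    u1 = nb_prev - c
    u1 /= np.linalg.norm(u1)
    u2 = nb_next - c
    u2 /= np.linalg.norm(u2)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(109.5) / 2
    return [c + 1.09 * (np.cos(half) * bis + sgn * np.sin(half) * perp)
            for sgn in (+1, -1)]


def _grow_chain(n_monomers: int, rng, max_retries: int):
    """One attempt at a self-avoiding chain; raises on growth failure.

    Each accepted backbone atom fixes the methylene hydrogens of its
    predecessor, which join the obstacle set — so steric rejection sees the
    full chain, not just the backbone.
    """
    # backbone: H O C C (O C C)*(n-1) O H
    bb_species = ["H", "O"] + ["C", "C", "O"] * n_monomers + ["H"]
    theta = np.deg2rad(109.5)
    pos = [np.zeros(3)]
    pos.append(np.array([0.96, 0.0, 0.0]))
    b01 = _BOND_LENGTHS[(bb_species[1], bb_species[2])]
    pos.append(pos[1] + np.array([b01 * np.cos(np.pi - theta),
                                  b01 * np.sin(np.pi - theta), 0.0]))
    basins = np.deg2rad([180.0, 60.0, -60.0])
    h_pos: list[tuple[int, np.ndarray]] = []   # (carbon backbone index, xyz)
    n_backtracks = 0
    k = 3
    while k < len(bb_species):
        bond = _BOND_LENGTHS[(bb_species[k - 1], bb_species[k])]
        placed = False
        for _ in range(max_retries):
            phi = rng.choice(basins) + rng.normal(scale=np.deg2rad(12.0))
            cand = _place_atom(pos[k - 3], pos[k - 2], pos[k - 1], bond, theta, phi)
            # heavy atoms: skip bonded (1-2) and angle-constrained (1-3)
            prev = np.array(pos[:k - 2])
            if len(prev) and np.linalg.norm(prev - cand, axis=1).min() <= 1.7:
                continue
            # earlier hydrogens (1-4 H of the previous carbon excepted)
            hs = [p for ci, p in h_pos if ci <= k - 3]
            if hs and np.linalg.norm(np.array(hs) - cand, axis=1).min() <= 1.4:
                continue
            new_h = []
            if bb_species[k - 1] == "C":
                cand_h = _methylene_h(pos[k - 2], pos[k - 1], cand)
                obstacles = pos[:k - 3] + [p for ci, p in h_pos if ci <= k - 3]
                clash = False
                for h in cand_h:
                    if obstacles and np.linalg.norm(
                            np.array(obstacles) - h, axis=1).min() <= 1.4:
                        clash = True
                        break
                if clash:
                    continue
                new_h = [(k - 1, h) for h in cand_h]
            pos.append(cand)
            h_pos.extend(new_h)
            placed = True
            break
        if placed:
            k += 1
            continue
        # dead end: back out a few steps and try a different route
        n_backtracks += 1
        if n_backtracks > 100 or k <= 8:
            raise RuntimeError(f"self-avoiding growth failed at backbone atom {k}")
        undo = min(5, k - 4)
        del pos[-undo:]
        k -= undo
        h_pos = [(ci, p) for ci, p in h_pos if ci < k - 1]
    bb_pos = np.array(pos)

    # assemble full atom list: hydroxyl H, O, then CH2-CH2 units
    species: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    bb_index: list[int] = []

    def add(sym, xyz):
        species.append(sym)
        coords.append(np.asarray(xyz, dtype=float))
        return len(species) - 1

    prev_idx = None
    for k, sym in enumerate(bb_species):
        idx = add(sym, bb_pos[k])
        bb_index.append(idx)
        if prev_idx is not None:
            bonds.append((prev_idx, idx))
        prev_idx = idx
        if sym == "C":
            for h in _methylene_h(bb_pos[k - 1], bb_pos[k], bb_pos[k + 1]):
                hidx = add("H", h)
                bonds.append((idx, hidx))

    system = AtomicSystem(species, np.array(coords))
    system.positions -= system.center_of_mass()
    mol = np.zeros(system.n_atoms, dtype=int)
    topo = Topology(bonds, mol, find_backbone_dihedrals(species, bonds))
    return system, topo


def chain_mass(n_monomers: int) -> float:
    """Molar mass of H(OCH₂CH₂)ₙOH, g/mol."""
    return ((2 * n_monomers) * ATOMIC_MASSES["C"]
            + (4 * n_monomers + 2) * ATOMIC_MASSES["H"]
            + (n_monomers + 1) * ATOMIC_MASSES["O"])


def build_liquid_cell(n_chains: int, n_monomers: int, target_density: float = 0.5,
                      seed: int = 0, min_contact: float = 1.2,
                      max_retries: int = 500):
    """Pack chains into a cubic periodic cell at the target density (g/cm³).

    Chains are built independently, randomly rotated, and inserted at random
    positions subject to a minimum-image contact threshold.

    Returns ``(AtomicSystem, Topology)``.
    """
    if target_density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    total_mass = n_chains * chain_mass(n_monomers)          # g/mol
    vol_cm3 = total_mass / 6.02214076e23 / target_density
    L = (vol_cm3 * 1e24) ** (1.0 / 3.0)                     # Å
    cell = np.eye(3) * L

    species: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    mol = []
    dihedrals: list[tuple[int, int, int, int]] = []
    placed_pos = np.zeros((0, 3))
    for c in range(n_chains):
        sys_c, topo_c = generate_chain(n_monomers, seed=int(rng.integers(2 ** 31)))
        ok = False
        for _ in range(max_retries):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            R = _quat_to_rot(q)
            shift = rng.uniform(0, L, size=3)
            cand = sys_c.positions @ R.T + shift
            if len(placed_pos) == 0:
                ok = True
                break
            d = cand[:, None, :] - placed_pos[None, :, :]
            frac = d @ np.linalg.inv(cell)
            frac -= np.round(frac)
            dmin = np.linalg.norm(frac @ cell, axis=-1).min()
            if dmin > min_contact:
                ok = True
                break
        if not ok:
            raise RuntimeError("packing failed — try a lower target density")
        offset = len(species)
        species.extend(sys_c.species)
        coords.extend(cand)
        bonds.extend((i + offset, j + offset) for i, j in topo_c.bonds)
        dihedrals.extend(tuple(x + offset for x in q4) for q4 in topo_c.backbone_dihedrals)
        mol.extend([c] * sys_c.n_atoms)
        placed_pos = np.vstack([placed_pos, cand])

    system = AtomicSystem(species, np.array(coords), cell, pbc=True)
    topo = Topology(bonds, np.array(mol), dihedrals)
    return system, topo


def _quat_to_rot(q):
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def liquid_cell_preset(n_monomers: int, seed: int = 0, target_atoms: int = 1500,
                       target_density: float = 0.5):
    """Cell with ≈``target_atoms`` atoms at the stated density (the classical
    benchmark convention; the long-chain preset uses ≈8000 atoms)."""
    per_chain = 7 * n_monomers + 3
    n_chains = max(1, round(target_atoms / per_chain))
    return build_liquid_cell(n_chains, n_monomers, target_density, seed)


# -- atom roles and charges -------------------------------------------------

def atom_roles(species: list[str], bonds) -> list[str]:
    adj: dict[int, list[int]] = {i: [] for i in range(len(species))}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    roles = []
    for i, s in enumerate(species):
        if s == "C":
            roles.append("C")
        elif s == "O":
            has_h = any(species[j] == "H" for j in adj[i])
            roles.append("O_hydroxyl" if has_h else "O_ether")
        else:
            bonded_o = any(species[j] == "O" for j in adj[i])
            roles.append("H_hydroxyl" if bonded_o else "H_C")
    return roles


def reference_charges(system: AtomicSystem, topology: Topology,
                      params: OracleParams) -> np.ndarray:
    """Base charges plus a bounded bond-strain response, re-centered so each
    molecule stays exactly neutral (emulating conformation-dependent
    tight-binding charges)."""
    roles = atom_roles(system.species, topology.bonds)
    q = np.array([params.base_charges[r] for r in roles])
    resp = np.zeros(system.n_atoms)
    for i, j in topology.bonds:
        key = tuple(sorted((system.species[i], system.species[j])))
        _, r0 = params.bonds[key]
        d = np.linalg.norm(minimum_image_table(system.cell, system.pbc,
                           system.positions[[i, j]])[0, 1])
        s = params.charge_response * (r0 / d - 1.0)
        resp[i] += s
        resp[j] += s
    resp = np.clip(resp, -params.charge_response_bound, params.charge_response_bound)
    for m in range(topology.n_molecules):
        atoms = topology.molecule_atoms(m)
        resp[atoms] -= resp[atoms].mean()
    return q + resp


# -- analytic energy and forces --------------------------------------------

def _exclusion_pairs(n_atoms: int, bonds) -> set[tuple[int, int]]:
    """1-2, 1-3 and 1-4 pairs of the bond graph (excluded from nonbonded)."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excl = set()

    def mark(a, b):
        excl.add((min(a, b), max(a, b)))

    for i, j in bonds:
        mark(i, j)
        for k in adj[i]:
            if k != j:
                mark(k, j)
        for k in adj[j]:
            if k != i:
                mark(i, k)
        for k in adj[i]:
            for l in adj[j]:
                if k != j and l != i and k != l:
                    mark(k, l)
    return excl


class OracleCalculator:
    """Analytic bonded + LJ + Coulomb calculator for a fixed topology.

    Satisfies the same calculator contract as the learned model: ``evaluate
    (system, forces=True)`` returns an object with ``E_total`` and
    ``forces``.  Forces are exact gradients of the analytic energy.
    """

    def __init__(self, topology: Topology, params: OracleParams | None = None):
        self.topology = topology
        self.params = params or OracleParams()
        self._excl = None
        self._charges_cache = None

    def _nonbonded_lists(self, system: AtomicSystem):
        if self._excl is None:
            self._excl = _exclusion_pairs(system.n_atoms, self.topology.bonds)
        n = system.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        keep = np.array([(a, b) not in self._excl for a, b in zip(iu, ju)])
        return iu[keep], ju[keep]

    def base_charges(self, system: AtomicSystem) -> np.ndarray:
        if self._charges_cache is None:
            roles = atom_roles(system.species, self.topology.bonds)
            self._charges_cache = np.array(
                [self.params.base_charges[r] for r in roles])
        return self._charges_cache

    def energy_t(self, pos: ad.Tensor, system: AtomicSystem) -> ad.Tensor:
        p = self.params
        topo = self.topology
        terms = []

        def pairdisp(ii, jj):
            d = ad.add(ad.take(pos, (jj,)), ad.neg(ad.take(pos, (ii,))))
            if system.pbc:
                # constant image shifts from the current geometry
                raw = system.positions[jj] - system.positions[ii]
                inv = np.linalg.inv(system.cell)
                image = -np.round(raw @ inv)
                if np.any(image):
                    d = ad.add(d, ad.Tensor(image @ system.cell))
            return d

        # bonds
        bi = np.array([b[0] for b in topo.bonds])
        bj = np.array([b[1] for b in topo.bonds])
        kb = np.empty(len(bi))
        r0 = np.empty(len(bi))
        for idx, (i, j) in enumerate(zip(bi, bj)):
            key = tuple(sorted((system.species[i], system.species[j])))
            if key not in p.bonds:
                raise ValueError(f"missing bond parameters for {key}")
            kb[idx], r0[idx] = p.bonds[key]
        d = pairdisp(bi, bj)
        r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
        terms.append(ad.tsum(ad.mul(ad.Tensor(kb),
                                    ad.power(ad.add(r, ad.Tensor(-r0)), 2.0))))

        # angles (i-j-k with j the apex)
        angles = []
        adj: dict[int, list[int]] = {i: [] for i in range(system.n_atoms)}
        for i, j in topo.bonds:
            adj[i].append(j)
            adj[j].append(i)
        for j in range(system.n_atoms):
            nbs = sorted(adj[j])
            for a in range(len(nbs)):
                for b in range(a + 1, len(nbs)):
                    angles.append((nbs[a], j, nbs[b]))
        if angles:
            ai = np.array([a[0] for a in angles])
            aj = np.array([a[1] for a in angles])
            ak = np.array([a[2] for a in angles])
            d1 = pairdisp(aj, ai)
            d2 = pairdisp(aj, ak)
            r1 = ad.power(ad.tsum(ad.mul(d1, d1), axis=1), 0.5)
            r2 = ad.power(ad.tsum(ad.mul(d2, d2), axis=1), 0.5)
            cosq = ad.mul(ad.tsum(ad.mul(d1, d2), axis=1),
                          ad.power(ad.mul(r1, r2), -1.0))
            th = ad.tarccos(ad.mul(cosq, 0.999999))
            terms.append(ad.tsum(ad.mul(p.angle_k,
                                        ad.power(ad.add(th, -p.angle_theta0), 2.0))))

        # backbone torsions: k (1 + cos 3φ) via the Chebyshev identity
        if topo.backbone_dihedrals:
            q4 = np.array(topo.backbone_dihedrals)
            b0 = pairdisp(q4[:, 1], q4[:, 0])
            b1 = pairdisp(q4[:, 1], q4[:, 2])
            b2 = pairdisp(q4[:, 2], q4[:, 3])
            n1 = _cross_t(b0, b1)
            n2 = _cross_t(ad.neg(b1), b2)
            nn1 = ad.power(ad.tsum(ad.mul(n1, n1), axis=1), 0.5)
            nn2 = ad.power(ad.tsum(ad.mul(n2, n2), axis=1), 0.5)
            cphi = ad.mul(ad.tsum(ad.mul(n1, n2), axis=1),
                          ad.power(ad.mul(nn1, nn2), -1.0))
            if p.dihedral_n == 3:
                cosn = ad.add(ad.mul(4.0, ad.power(cphi, 3.0)), ad.mul(-3.0, cphi))
            elif p.dihedral_n == 2:
                cosn = ad.add(ad.mul(2.0, ad.mul(cphi, cphi)), -1.0)
            else:
                cosn = cphi
            terms.append(ad.tsum(ad.mul(p.dihedral_k, ad.add(1.0, cosn))))

        # nonbonded LJ + Coulomb over non-excluded pairs
        iu, ju = self._nonbonded_lists(system)
        if len(iu):
            if system.pbc:
                raw = system.positions[ju] - system.positions[iu]
                inv = np.linalg.inv(system.cell)
                frac = raw @ inv
                frac -= np.round(frac)
                within = np.linalg.norm(frac @ system.cell, axis=1) < p.nonbonded_cutoff
                iu, ju = iu[within], ju[within]
            d = pairdisp(iu, ju)
            r2 = ad.tsum(ad.mul(d, d), axis=1)
            eps = np.sqrt([p.lj_eps[system.species[i]] * p.lj_eps[system.species[j]]
                           for i, j in zip(iu, ju)])
            sig = np.array([0.5 * (p.lj_sigma[system.species[i]] + p.lj_sigma[system.species[j]])
                            for i, j in zip(iu, ju)])
            s6 = ad.power(ad.mul(r2, ad.Tensor(1.0 / sig ** 2)), -3.0)
            terms.append(ad.tsum(ad.mul(ad.mul(4.0, ad.Tensor(eps)),
                                        ad.add(ad.mul(s6, s6), ad.neg(s6)))))
            qv = self.base_charges(system)
            qq = qv[iu] * qv[ju]
            rinv = ad.power(r2, -0.5)
            terms.append(ad.mul(KE_COULOMB, ad.tsum(ad.mul(ad.Tensor(qq), rinv))))

        total = terms[0]
        for t in terms[1:]:
            total = ad.add(total, t)
        return total

    def evaluate(self, system: AtomicSystem, forces: bool = True):
        pos = ad.Tensor(system.positions, requires_grad=forces)
        e = self.energy_t(pos, system)
        f = None
        if forces:
            f = -ad.grad(e, pos).numpy()
        from .model import EnergyBreakdown
        q = reference_charges(system, self.topology, self.params)
        m = system.masses
        com = m @ system.positions / m.sum()
        return EnergyBreakdown(E_short=e.item(), E_coulomb=0.0, E_dispersion=0.0,
                               E_total=e.item(), forces=f, charges=q,
                               charges_iter1=q,
                               dipole=q @ (system.positions - com))


def _cross_t(a: ad.Tensor, b: ad.Tensor) -> ad.Tensor:
    ax, ay, az = a[:, 0], a[:, 1], a[:, 2]
    bx, by, bz = b[:, 0], b[:, 1], b[:, 2]
    return ad.stack([ad.add(ad.mul(ay, bz), ad.neg(ad.mul(az, by))),
                     ad.add(ad.mul(az, bx), ad.neg(ad.mul(ax, bz))),
                     ad.add(ad.mul(ax, by), ad.neg(ad.mul(ay, bx)))], axis=1)


def oracle_label(system: AtomicSystem, topology: Topology,
                 params: OracleParams | None = None,
                 provenance: str = CONFORMATIONAL,
                 round_id: int = 0) -> LabeledSample:
    """Label a structure with analytic energy, exact forces, reference
    charges, and the dipole of those charges."""
    params = params or OracleParams()
    calc = OracleCalculator(topology, params)
    out = calc.evaluate(system, forces=True)
    q = reference_charges(system, topology, params)
    m = system.masses
    com = m @ system.positions / m.sum()
    dip = q @ (system.positions - com)
    return LabeledSample(system.copy(), out.E_total, out.forces, dip, q,
                         provenance, round_id)
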