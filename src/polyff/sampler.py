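"""Training-pool construction from trajectories.

Pools are built from three ingredients: N-molecule clusters extracted
around a center molecule (nearest neighbors by center-of-mass distance),
conformational perturbations (non-equilibrium bonds, angles, torsions, and
density scalings), and "decomposed" samples in which a covalent bond is
stretched far beyond equilibrium so the labeler can teach the model to
destabilize unphysical geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import (AtomicSystem, Topology, CONFORMATIONAL, DECOMPOSED,
                     minimum_image_displacement)


@dataclass
class ClusterSample:
    """Unlabeled pool record: geometry + topology + provenance tag."""

    system: AtomicSystem
    topology: Topology
    provenance: str = CONFORMATIONAL


@dataclass
class PerturbationMagnitudes:
    bond: float = 0.15               # Å
    angle: float = 15.0              # deg
    dihedral: float = 60.0           # deg
    density_scale: tuple = (0.85, 1.15)


@dataclass
class SamplingPlan:
    """What to draw from the trajectories.

    ``cluster_caps`` maps oligomer length (monomers per chain) to the
    maximum molecules per cluster — 8 for monomers, 6 for dimers, 4 for
    trimers by default, reflecting the cost ceiling of reference labeling.
    """

    cluster_caps: dict = field(default_factory=lambda: {1: 8, 2: 6, 3: 4})
    n_conformational: int = 100
    n_decomposed: int = 50
    magnitudes: PerturbationMagnitudes = field(default_factory=PerturbationMagnitudes)
    seed: int = 0

    def cap_for(self, n_monomers: int) -> int:
        return self.cluster_caps.get(n_monomers, min(self.cluster_caps.values()))


# -- topology utilities -----------------------------------------------------

def _sub_topology(topology: Topology, molecules: list[int]) -> tuple[np.ndarray, Topology]:
    atoms = np.concatenate([topology.molecule_atoms(m) for m in molecules])
    remap = {int(a): i for i, a in enumerate(atoms)}
    bonds = [(remap[i], remap[j]) for i, j in topology.bonds
             if i in remap and j in remap]
    mol_of = np.empty(len(atoms), dtype=int)
    for new_id, m in enumerate(molecules):
        for a in topology.molecule_atoms(m):
            mol_of[remap[int(a)]] = new_id
    dihedrals = [tuple(remap[x] for x in q) for q in topology.backbone_dihedrals
                 if all(x in remap for x in q)]
    return atoms, Topology(bonds, mol_of, dihedrals)


def _adjacency(n: int, bonds) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _fragment(n: int, bonds, cut: tuple[int, int], side: int) -> np.ndarray:
    """Atoms reachable from ``side`` after removing bond ``cut``."""
    cut = (min(cut), max(cut))
    adj = _adjacency(n, [b for b in bonds
                         if (min(b), max(b)) != cut])
    seen = {side}
    stack = [side]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if b not in seen:
                seen.add(b)
                stack.append(b)
    return np.array(sorted(seen))


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# -- operations -------------------------------------------------------------

def unwrap_molecules(system: AtomicSystem, topology: Topology) -> np.ndarray:
    """Positions with each molecule made whole (bonds never cross the cell
    boundary); the first atom of each molecule anchors the image choice."""
    pos = system.positions.copy()
    if not system.pbc:
        return pos
    adj = _adjacency(system.n_atoms, topology.bonds)
    for m in range(topology.n_molecules):
        atoms = topology.molecule_atoms(m)
        root = int(atoms[0])
        seen = {root}
        stack = [root]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    d = minimum_image_displacement(system.cell, True, pos[a], system.positions[b])
                    pos[b] = pos[a] + d
                    stack.append(b)
    return pos


def extract_cluster(frame: AtomicSystem, topology: Topology,
                    center_molecule: int, n_molecules: int):
    """Center molecule plus its n-1 nearest neighbors (minimum-image COM
    distance), unwrapped into a whole, translation-normalized, non-periodic
    cluster.

    Returns ``(AtomicSystem, Topology)`` for the cluster.
    """
    M = topology.n_molecules
    if not (0 <= center_molecule < M):
        raise ValueError(f"invalid molecule id {center_molecule}")
    if n_molecules > M:
        raise ValueError("cluster larger than the number of molecules")
    pos = unwrap_molecules(frame, topology)
    masses = frame.masses
    coms = np.array([
        np.average(pos[topology.molecule_atoms(m)], axis=0,
                   weights=masses[topology.molecule_atoms(m)])
        for m in range(M)])
    d = np.array([np.linalg.norm(minimum_image_displacement(
        frame.cell, frame.pbc, coms[center_molecule], coms[m])) for m in range(M)])
    d[center_molecule] = -1.0  # center always first
    chosen = list(np.argsort(d, kind="stable")[:n_molecules])
    atoms, sub_topo = _sub_topology(topology, chosen)

    out_pos = []
    for rank, m in enumerate(chosen):
        mol_atoms = topology.molecule_atoms(m)
        shift = minimum_image_displacement(frame.cell, frame.pbc,
                                           coms[center_molecule], coms[m])
        out_pos.append(pos[mol_atoms] - coms[m] + coms[center_molecule] + shift
                       if frame.pbc else pos[mol_atoms])
    out_pos = np.vstack(out_pos)
    cluster = AtomicSystem([frame.species[int(a)] for a in atoms], out_pos)
    cluster.positions -= cluster.center_of_mass()
    return cluster, sub_topo


def perturb_conformation(cluster: AtomicSystem, topology: Topology,
                         magnitudes: PerturbationMagnitudes | None = None,
                         seed: int = 0) -> AtomicSystem:
    """Random non-equilibrium deformation of a cluster.

    Torsions and a random subset of angles are rotated first (length
    preserving), then every bond is stretched within ±``magnitudes.bond``,
    and finally molecular COM separations are scaled by a density factor.
    Seed-reproducible; zero magnitudes return the input coordinates.
    """
    mags = magnitudes or PerturbationMagnitudes()
    rng = np.random.default_rng(seed)
    n = cluster.n_atoms
    pos = cluster.positions.copy()
    bonds = topology.bonds

    # torsion rotations about each backbone central bond
    for (a, b, c, d) in topology.backbone_dihedrals:
        delta = np.deg2rad(rng.uniform(-mags.dihedral, mags.dihedral))
        if delta == 0.0:
            continue
        frag = _fragment(n, bonds, (b, c), c)
        axis = pos[c] - pos[b]
        R = _rotation(axis, delta)
        pos[frag] = (pos[frag] - pos[b]) @ R.T + pos[b]

    # angle bends on a random subset of bond-angle triples
    adj = _adjacency(n, bonds)
    triples = [(i, j, k) for j in range(n) for ii, i in enumerate(sorted(adj[j]))
               for k in sorted(adj[j])[ii + 1:]]
    for (i, j, k) in triples:
        if rng.random() > 0.3:
            continue
        delta = np.deg2rad(rng.uniform(-mags.angle, mags.angle))
        axis = np.cross(pos[i] - pos[j], pos[k] - pos[j])
        if np.linalg.norm(axis) < 1e-8:
            continue
        frag = _fragment(n, bonds, (j, k), k)
        R = _rotation(axis, delta)
        pos[frag] = (pos[frag] - pos[j]) @ R.T + pos[j]

    # bond stretches (after the rotations, so bounds hold exactly)
    for (i, j) in bonds:
        delta = rng.uniform(-mags.bond, mags.bond)
        vec = pos[j] - pos[i]
        r = np.linalg.norm(vec)
        frag = _fragment(n, bonds, (i, j), j)
        pos[frag] += vec / r * delta

    # density scaling of COM separations
    lo, hi = mags.density_scale
    scale = rng.uniform(lo, hi)
    if scale != 1.0 and topology.n_molecules > 1:
        masses = cluster.masses
        center = masses @ pos / masses.sum()
        for m in range(topology.n_molecules):
            atoms = topology.molecule_atoms(m)
            com = np.average(pos[atoms], axis=0, weights=masses[atoms])
            pos[atoms] += (scale - 1.0) * (com - center)
    return AtomicSystem(cluster.species, pos)


def decompose_cluster(cluster: AtomicSystem, topology: Topology,
                      seed: int = 0) -> ClusterSample:
    """Stretch 1-2 random covalent bonds to 1.5-3x their current length by
    displacing the smaller fragment along the bond vector.  Atom count is
    unchanged; the result is tagged ``decomposed``.
    """
    if not topology.bonds:
        raise ValueError("cluster has no bonds to decompose")
    rng = np.random.default_rng(seed)
    pos = cluster.positions.copy()
    n = cluster.n_atoms
    n_break = int(rng.integers(1, 3))
    picks = rng.choice(len(topology.bonds), size=min(n_break, len(topology.bonds)),
                       replace=False)
    for bidx in picks:
        i, j = topology.bonds[int(bidx)]
        frag_j = _fragment(n, topology.bonds, (i, j), j)
        frag_i = _fragment(n, topology.bonds, (i, j), i)
        moving, anchor = ((frag_j, i) if len(frag_j) <= len(frag_i)
                          else (frag_i, j))
        a, b = (i, j) if anchor == i else (j, i)
        vec = pos[b] - pos[a]
        r = np.linalg.norm(vec)
        factor = rng.uniform(1.5, 3.0)
        pos[moving] += vec / r * (factor - 1.0) * r
    out = AtomicSystem(cluster.species, pos)
    return ClusterSample(out, topology, DECOMPOSED)


def delete_fragment_variant(cluster: AtomicSystem, topology: Topology,
                            seed: int = 0) -> ClusterSample:
    """Alternative decomposition that removes the smaller fragment entirely
    (changes atom count; off the default path)."""
    rng = np.random.default_rng(seed)
    i, j = topology.bonds[int(rng.integers(len(topology.bonds)))]
    frag_j = _fragment(cluster.n_atoms, topology.bonds, (i, j), j)
    frag_i = _fragment(cluster.n_atoms, topology.bonds, (i, j), i)
    drop = set(map(int, frag_j if len(frag_j) <= len(frag_i) else frag_i))
    keep = [a for a in range(cluster.n_atoms) if a not in drop]
    remap = {a: k for k, a in enumerate(keep)}
    bonds = [(remap[a], remap[b]) for a, b in topology.bonds
             if a in remap and b in remap]
    mol_of, _ = None, None
    from .system import molecule_partition
    out = AtomicSystem([cluster.species[a] for a in keep], cluster.positions[keep])
    mol, _count = molecule_partition(out, bonds)
    dihedrals = [tuple(remap[x] for x in q) for q in topology.backbone_dihedrals
                 if all(x in remap for x in q)]
    return ClusterSample(out, Topology(bonds, mol, dihedrals), DECOMPOSED)


def _min_nonbonded_distance(system: AtomicSystem, topology: Topology) -> float:
    n = system.n_atoms
    if n < 2:
        return np.inf
    from scipy.spatial.distance import squareform, pdist
    d = squareform(pdist(system.positions))
    np.fill_diagonal(d, np.inf)
    for i, j in topology.bonds:
        d[i, j] = d[j, i] = np.inf
    return float(d.min())


def build_training_pool(trajectories, plan: SamplingPlan,
                        min_contact: float = 1.4,
                        max_retries: int = 50) -> list[ClusterSample]:
    """Draw the planned number of conformational and decomposed cluster
    samples from ``trajectories`` (a list of ``(frame, topology,
    n_monomers)`` tuples).  Candidates with nonbonded contacts below
    ``min_contact`` are redrawn (they would dominate any squared-error
    objective).  Deterministic under the plan seed.
    """
    if not trajectories:
        raise ValueError("no trajectory frames supplied")
    rng = np.random.default_rng(plan.seed)
    pool: list[ClusterSample] = []

    def draw_cluster():
        frame, topo, n_mono = trajectories[int(rng.integers(len(trajectories)))]
        cap = min(plan.cap_for(n_mono), topo.n_molecules)
        n_mol = int(rng.integers(1, cap + 1))
        center = int(rng.integers(topo.n_molecules))
        return extract_cluster(frame, topo, center, n_mol)

    def draw_valid(make):
        for _ in range(max_retries):
            sample = make()
            if _min_nonbonded_distance(sample.system, sample.topology) >= min_contact:
                return sample
        raise RuntimeError("could not draw a contact-free sample; "
                           "loosen min_contact or the perturbation magnitudes")

    for _ in range(plan.n_conformational):
        def make():
            cluster, topo = draw_cluster()
            pert = perturb_conformation(cluster, topo, plan.magnitudes,
                                        seed=int(rng.integers(2 ** 31)))
            return ClusterSample(pert, topo, CONFORMATIONAL)
        pool.append(draw_valid(make))
    for _ in range(plan.n_decomposed):
        def make():
            cluster, topo = draw_cluster()
            pert = perturb_conformation(cluster, topo, plan.magnitudes,
                                        seed=int(rng.integers(2 ** 31)))
            return decompose_cluster(pert, topo, seed=int(rng.integers(2 ** 31)))
        pool.append(draw_valid(make))
    return pool
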