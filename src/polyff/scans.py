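"""Model-validation probes: rigid pair-separation scans and torsion scans.

A pair scan extracts two neighboring molecules, rigidly translates one
along the line of the two centers of mass from 75% to 300% of the initial
COM separation, and evaluates the energy at each step with every supplied
calculator — the position of each curve's minimum is a proxy for the
density the calculator will produce, its gradient a proxy for dynamics.
A torsion scan rigidly rotates the distal fragment about a backbone bond
in fixed angular steps and reports relative energies and barrier heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sampler import _fragment, _rotation, extract_cluster
from .system import AtomicSystem, Topology


@dataclass
class PairScanProtocol:
    d_min_fraction: float = 0.75
    d_max_fraction: float = 3.0
    n_steps: int = 500               # tetramer preset: 300

    def __post_init__(self):
        if not (0 < self.d_min_fraction < 1 < self.d_max_fraction):
            raise ValueError("need d_min_fraction < 1 < d_max_fraction")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")

    @classmethod
    def tetramer_preset(cls) -> "PairScanProtocol":
        return cls(n_steps=300)


@dataclass
class ScanResult:
    abscissa: np.ndarray                     # Å (pair) or deg (torsion)
    energies: dict                           # name -> absolute energies
    relative: dict = field(init=False)       # name -> energies - min
    minima: dict = field(init=False)         # name -> abscissa of minimum
    barriers: dict = field(default_factory=dict)  # torsion scans only
    failed_steps: dict = field(default_factory=dict)

    def __post_init__(self):
        self.relative = {}
        self.minima = {}
        for name, e in self.energies.items():
            e = np.asarray(e, dtype=float)
            finite = np.isfinite(e)
            emin = np.nanmin(e[finite]) if finite.any() else np.nan
            self.relative[name] = e - emin
            self.minima[name] = (float(self.abscissa[np.nanargmin(np.where(finite, e, np.inf))])
                                 if finite.any() else np.nan)


def molecule_com(system: AtomicSystem, topology: Topology, mol: int) -> np.ndarray:
    atoms = topology.molecule_atoms(mol)
    m = system.masses[atoms]
    return m @ system.positions[atoms] / m.sum()


def select_neighbor_pair(frame: AtomicSystem, topology: Topology, seed: int = 0):
    """A random molecule and its nearest neighbor by COM distance.

    Returns ``(mol_a, mol_b, d_com)``; seed-reproducible.
    """
    M = topology.n_molecules
    if M < 2:
        raise ValueError("need at least two molecules")
    rng = np.random.default_rng(seed)
    a = int(rng.integers(M))
    from .system import minimum_image_displacement
    com_a = molecule_com(frame, topology, a)
    best, best_d = None, np.inf
    for m in range(M):
        if m == a:
            continue
        d = np.linalg.norm(minimum_image_displacement(
            frame.cell, frame.pbc, com_a, molecule_com(frame, topology, m)))
        if d < best_d:
            best, best_d = m, d
    return a, best, float(best_d)


def extract_pair(frame: AtomicSystem, topology: Topology, mol_a: int, mol_b: int):
    """Unwrapped two-molecule cluster containing ``mol_a`` (first) and its
    partner; returns ``(cluster, cluster_topology)``."""
    cluster, topo = extract_cluster(frame, topology, mol_a, 2)
    # extract_cluster picks nearest neighbors; ensure the requested partner
    if topo.n_molecules != 2:
        raise ValueError("pair extraction did not yield two molecules")
    return cluster, topo


def pair_scan(cluster: AtomicSystem, topology: Topology, calculators: dict,
              protocol: PairScanProtocol | None = None) -> ScanResult:
    """Rigidly translate molecule 1 along the COM-COM line.

    The grid is ``n_steps`` points inclusive of both endpoints
    ``d_min_fraction·d_COM`` and ``d_max_fraction·d_COM``.  A calculator
    failure at a step flags that step and the scan continues.
    """
    protocol = protocol or PairScanProtocol()
    if topology.n_molecules != 2:
        raise ValueError("pair scan requires exactly two molecules")
    atoms0 = topology.molecule_atoms(0)
    atoms1 = topology.molecule_atoms(1)
    com0 = molecule_com(cluster, topology, 0)
    com1 = molecule_com(cluster, topology, 1)
    d0 = np.linalg.norm(com1 - com0)
    axis = (com1 - com0) / d0
    grid = np.linspace(protocol.d_min_fraction * d0, protocol.d_max_fraction * d0,
                       protocol.n_steps)
    energies = {name: np.full(protocol.n_steps, np.nan) for name in calculators}
    failed = {name: [] for name in calculators}
    for k, d in enumerate(grid):
        pos = cluster.positions.copy()
        pos[atoms1] += (d - d0) * axis
        conf = AtomicSystem(cluster.species, pos)
        for name, calc in calculators.items():
            try:
                energies[name][k] = calc.evaluate(conf, forces=False).E_total
            except Exception:
                failed[name].append(k)
    return ScanResult(grid, energies,
                      failed_steps={n: f for n, f in failed.items() if f})


def torsion_scan(molecule: AtomicSystem, topology: Topology,
                 quadruple: tuple[int, int, int, int], calculators: dict,
                 step_deg: float = 5.0) -> ScanResult:
    """Rigid rotation of the distal fragment about the central bond of a
    dihedral, in fixed steps covering 360° (e.g. 5° steps → 72
    configurations).  Reports relative energies and barrier heights (each
    local maximum minus the preceding local minimum) per calculator.
    """
    a, b, c, d = quadruple
    n = molecule.n_atoms
    frag = _fragment(n, topology.bonds, (b, c), c)
    if len(frag) == n:
        raise ValueError("central bond lies on a ring; rotation splits nothing")
    n_conf = int(round(360.0 / step_deg))
    angles = np.arange(n_conf) * step_deg
    energies = {name: np.full(n_conf, np.nan) for name in calculators}
    failed = {name: [] for name in calculators}
    axis = molecule.positions[c] - molecule.positions[b]
    for k, ang in enumerate(angles):
        R = _rotation(axis, np.deg2rad(ang))
        pos = molecule.positions.copy()
        pos[frag] = (pos[frag] - pos[b]) @ R.T + pos[b]
        conf = AtomicSystem(molecule.species, pos)
        for name, calc in calculators.items():
            try:
                energies[name][k] = calc.evaluate(conf, forces=False).E_total
            except Exception:
                failed[name].append(k)
    result = ScanResult(angles, energies,
                        failed_steps={n_: f for n_, f in failed.items() if f})
    for name, e in result.relative.items():
        result.barriers[name] = _barrier_heights(np.asarray(e))
    return result


def _barrier_heights(e: np.ndarray) -> list[float]:
    """Local max minus preceding local min on the periodic curve."""
    n = len(e)
    is_max = [(e[i] > e[(i - 1) % n]) and (e[i] >= e[(i + 1) % n]) for i in range(n)]
    is_min = [(e[i] < e[(i - 1) % n]) and (e[i] <= e[(i + 1) % n]) for i in range(n)]
    barriers = []
    for i in range(n):
        if not is_max[i]:
            continue
        j = (i - 1) % n
        while not is_min[j] and j != i:
            j = (j - 1) % n
        barriers.append(float(e[i] - e[j]))
    return barriers
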