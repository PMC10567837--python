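"""Structure data model, extended-XYZ I/O, periodic geometry, molecule bookkeeping.

The universal structure record is :class:`AtomicSystem`; labeled training
records wrap it in :class:`LabeledSample`.  All structure files use the
extended-XYZ dialect written by :func:`write_extxyz` (``Properties=`` column
spec plus ``Lattice``/``energy``/``charge`` key-value pairs on the comment
line), and large labeled sets live in an HDF5 container.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import ATOMIC_MASSES, COVALENT_RADII, SUPPORTED_ELEMENTS

CONFORMATIONAL = "conformational"
DECOMPOSED = "decomposed"


@dataclass
class AtomicSystem:
    """A molecular structure: element symbols, Cartesian positions (Å),
    optional periodic cell (rows are lattice vectors, Å), total charge (e)."""

    species: list[str]
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: bool = False
    total_charge: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape != (len(self.species), 3):
            raise ValueError("positions must be (N, 3) matching species length")
        if len(self.species) < 1:
            raise ValueError("need at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=np.float64).reshape(3, 3)
        if self.pbc:
            if self.cell is None:
                raise ValueError("pbc requires a cell")
            if abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValueError("periodic cell must be invertible")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.species])

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return m @ self.positions / m.sum()

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(list(self.species), self.positions.copy(),
                            None if self.cell is None else self.cell.copy(),
                            self.pbc, self.total_charge)

    def volume(self) -> float:
        if self.cell is None:
            raise ValueError("non-periodic system has no volume")
        return float(abs(np.linalg.det(self.cell)))


@dataclass
class Topology:
    """Bond list (unordered index pairs), per-atom molecule ids, and the
    backbone O-C-C-O dihedral quadruples of glycol-type chains."""

    bonds: list[tuple[int, int]]
    molecule_of: np.ndarray
    backbone_dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_of.max()) + 1 if len(self.molecule_of) else 0

    def molecule_atoms(self, mol_id: int) -> np.ndarray:
        return np.nonzero(self.molecule_of == mol_id)[0]


@dataclass
class LabeledSample:
    """An AtomicSystem plus its reference labels.

    energy kcal/mol; forces kcal/mol/Å; dipole e·Å; ref_charges e.
    ``provenance`` records how the geometry was produced (conformational
    sampling vs deliberate decomposition)."""

    system: AtomicSystem
    energy: float
    forces: np.ndarray
    dipole: Optional[np.ndarray] = None
    ref_charges: Optional[np.ndarray] = None
    provenance: str = CONFORMATIONAL
    round_id: int = 0

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=np.float64)
        if self.forces.shape != (self.system.n_atoms, 3):
            raise ValueError("forces shape must be (N, 3)")
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=np.float64).reshape(3)
        if self.ref_charges is not None:
            self.ref_charges = np.asarray(self.ref_charges, dtype=np.float64)
            if self.ref_charges.shape != (self.system.n_atoms,):
                raise ValueError("ref_charges length must be N")


@dataclass
class Dataset:
    samples: list[LabeledSample]
    split_assignment: Optional[np.ndarray] = None  # "train"/"val" per sample

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, which: str) -> "Dataset":
        if self.split_assignment is None:
            raise ValueError("dataset has no split assignment")
        keep = [s for s, w in zip(self.samples, self.split_assignment) if w == which]
        return Dataset(keep)


# -- extended XYZ -----------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def read_extxyz(path) -> list[tuple[AtomicSystem, dict]]:
    """Read all frames of an extended-XYZ file.

    Returns ``(system, labels)`` per frame with labels drawn from the
    comment line (``energy``, ``charge``, ``Lattice``) and per-atom columns
    (``forces``, ``charges``) when present.
    """
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nline = 0
    while i < len(lines):
        if lines[i].strip() == "" and all(l.strip() == "" for l in lines[i:]):
            break
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"malformed frame header at line {i + 1}: {lines[i]!r}") from exc
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0 and i + 1 + natoms > len(lines):
            raise ValueError(f"frame at line {i + 1} declares {natoms} atoms but file ends early")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        kv = _parse_comment(comment)
        cell = None
        pbc = False
        if "Lattice" in kv:
            cell = np.fromstring(kv["Lattice"], sep=" ").reshape(3, 3)
            pbc = True
        # column layout from Properties, default species + pos
        props = kv.get("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        cols = [(fields[j], fields[j + 1], int(fields[j + 2]))
                for j in range(0, len(fields), 3)]
        species, rows = [], []
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            species.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        rows = np.array(rows) if rows else np.zeros((0, 0))
        offset = 0
        data = {}
        for name, kind, width in cols:
            if kind == "S":
                continue
            data[name] = rows[:, offset:offset + width]
            offset += width
        system = AtomicSystem(species, data["pos"], cell, pbc,
                              int(float(kv.get("charge", 0))))
        labels: dict = {}
        if "energy" in kv:
            labels["energy"] = float(kv["energy"])
        if "forces" in data:
            labels["forces"] = data["forces"]
        if "charges" in data:
            labels["charges"] = data["charges"][:, 0]
        records.append((system, labels))
        i += 2 + natoms
        nline += 1
    return records


def write_extxyz(records, path) -> None:
    """Write frames to extended XYZ; accepts ``AtomicSystem`` or
    ``(AtomicSystem, labels)`` entries.  Fixed float format (%.12f for
    positions) keeps repeated writes byte-identical."""
    if isinstance(records, AtomicSystem) or isinstance(records, tuple):
        records = [records]
    if not records:
        raise ValueError("no records to write")
    out_lines = []
    for rec in records:
        system, labels = rec if isinstance(rec, tuple) else (rec, {})
        labels = labels or {}
        n = system.n_atoms
        props = "species:S:1:pos:R:3"
        if "forces" in labels:
            props += ":forces:R:3"
        if "charges" in labels:
            props += ":charges:R:1"
        kv = [f"Properties={props}"]
        if system.pbc and system.cell is not None:
            flat = " ".join(f"{x:.12f}" for x in system.cell.ravel())
            kv.append(f'Lattice="{flat}"')
        if "energy" in labels:
            kv.append(f"energy={labels['energy']:.12f}")
        if system.total_charge:
            kv.append(f"charge={system.total_charge}")
        out_lines.append(str(n))
        out_lines.append(" ".join(kv))
        forces = labels.get("forces")
        charges = labels.get("charges")
        for j in range(n):
            row = f"{system.species[j]} " + " ".join(f"{x:.12f}" for x in system.positions[j])
            if forces is not None:
                row += " " + " ".join(f"{x:.12f}" for x in np.asarray(forces)[j])
            if charges is not None:
                row += f" {np.asarray(charges)[j]:.12f}"
            out_lines.append(row)
    with open(path, "w") as fh:
        fh.write("\n".join(out_lines) + "\n")


# -- molecule bookkeeping ---------------------------------------------------

def molecule_partition(system: AtomicSystem, bonds: Sequence[tuple[int, int]]):
    """Connected components of the bond graph.

    Returns ``(molecule_of, n_molecules)`` with molecule ids dense in
    ``0..M-1`` ordered by each component's smallest atom index.
    """
    n = system.n_atoms
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    order = {}
    mol = np.empty(n, dtype=int)
    for i in range(n):
        r = roots[i]
        if r not in order:
            order[r] = len(order)
        mol[i] = order[r]
    return mol, len(order)


def guess_bonds(system: AtomicSystem, scale: float = 1.2) -> list[tuple[int, int]]:
    """Distance-based bond guess: bonded iff r < scale * (r_cov_i + r_cov_j).

    H-H pairs are never bonded (avoids spurious contacts in packed cells).
    """
    n = system.n_atoms
    bonds = []
    radii = np.array([COVALENT_RADII[s] for s in system.species])
    for i in range(n):
        for j in range(i + 1, n):
            if system.species[i] == "H" and system.species[j] == "H":
                continue
            d = np.linalg.norm(minimum_image_displacement(
                system.cell, system.pbc, system.positions[i], system.positions[j]))
            if d < scale * (radii[i] + radii[j]):
                bonds.append((i, j))
    return bonds


# -- periodic geometry ------------------------------------------------------

def minimum_image_displacement(cell, pbc: bool, r1, r2) -> np.ndarray:
    """Displacement r2 - r1 wrapped to the nearest periodic image.

    Uses fractional-coordinate rounding; valid when interaction ranges are
    below half the smallest cell width.
    """
    d = np.asarray(r2, dtype=float) - np.asarray(r1, dtype=float)
    if not pbc:
        return d
    cell = np.asarray(cell, dtype=float)
    if abs(np.linalg.det(cell)) < 1e-10:
        raise ValueError("singular cell")
    frac = d @ np.linalg.inv(cell)
    frac -= np.round(frac)
    return frac @ cell


def minimum_image_table(cell, pbc: bool, positions: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image displacement array, shape (N, N, 3)."""
    pos = np.asarray(positions, dtype=float)
    d = pos[None, :, :] - pos[:, None, :]
    if not pbc:
        return d
    cell = np.asarray(cell, dtype=float)
    inv = np.linalg.inv(cell)
    frac = d @ inv
    frac -= np.round(frac)
    return frac @ cell


def find_backbone_dihedrals(species: list[str], bonds) -> list[tuple[int, int, int, int]]:
    """Enumerate O-C-C-O quadruples along the bond graph (backbone torsions
    of ethylene-glycol-type chains)."""
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    quads = []
    for b in range(len(species)):
        if species[b] != "C":
            continue
        for c in adj.get(b, ()):
            if c <= b or species[c] != "C":
                continue
            for a in adj.get(b, ()):
                if a == c or species[a] != "O":
                    continue
                for d in adj.get(c, ()):
                    if d == b or species[d] != "O":
                        continue
                    quads.append((a, b, c, d))
    return quads


# -- HDF5 dataset container -------------------------------------------------

def save_dataset(dataset: Dataset, path) -> None:
    """Store a labeled dataset as HDF5 groups /samples/<i>/{...}."""
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group("samples")
        for i, s in enumerate(dataset.samples):
            g = grp.create_group(str(i))
            g.create_dataset("species", data=np.array(s.system.species, dtype="S2"))
            g.create_dataset("positions", data=s.system.positions)
            if s.system.cell is not None:
                g.create_dataset("cell", data=s.system.cell)
            g.attrs["pbc"] = s.system.pbc
            g.attrs["total_charge"] = s.system.total_charge
            g.attrs["energy"] = s.energy
            g.attrs["provenance"] = s.provenance
            g.attrs["round_id"] = s.round_id
            g.create_dataset("forces", data=s.forces)
            if s.dipole is not None:
                g.create_dataset("dipole", data=s.dipole)
            if s.ref_charges is not None:
                g.create_dataset("ref_charges", data=s.ref_charges)


def load_dataset(path) -> Dataset:
    import h5py

    samples = []
    with h5py.File(path, "r") as fh:
        grp = fh["samples"]
        for key in sorted(grp, key=int):
            g = grp[key]
            species = [s.decode() for s in g["species"][...]]
            cell = g["cell"][...] if "cell" in g else None
            system = AtomicSystem(species, g["positions"][...], cell,
                                  bool(g.attrs["pbc"]), int(g.attrs["total_charge"]))
            samples.append(LabeledSample(
                system, float(g.attrs["energy"]), g["forces"][...],
                g["dipole"][...] if "dipole" in g else None,
                g["ref_charges"][...] if "ref_charges" in g else None,
                str(g.attrs["provenance"]), int(g.attrs["round_id"])))
    return Dataset(samples)
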