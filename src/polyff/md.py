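"""Molecular dynamics over any calculator, plus trajectory property estimators.

The engine is a velocity-Verlet core with a Nosé–Hoover thermostat (NVT)
and, for NPT, isotropic Berendsen-type cell scaling driven by a
finite-difference virial pressure — a documented simplification of the
extended-Lagrangian barostats used for production equilibration.  Per-atom
periodic image counters are carried along so mean-squared displacements are
exact under wrapping.

Estimators: windowed density averages, Einstein self-diffusivity from MSD,
fluctuation heat capacity c_p = (⟨E²⟩-⟨E⟩²)/(k_B T²), radial distribution
functions, radius of gyration, and signed-dihedral distributions.  All are
pure functions of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .oracle import signed_dihedral
from .system import AtomicSystem, Topology
from .units import KB, KCAL_MOL_PER_GMOL_TO_A_FS2 as ACC

# kcal/mol/Å³ -> atm
PRESSURE_TO_ATM = 4184.0 / (6.02214076e23 * 1e-30 * 101325.0)


@dataclass
class MDConfig:
    """Integration settings.  Production presets follow the reference
    protocol: dt 0.5 fs, thermostat time constant 50 fs, barostat time
    constant 2.5 ps, trajectory sampling every 0.5 ps, 1 ns total."""

    ensemble: str = "NVE"            # NVE | NVT | NPT
    dt: float = 0.5                  # fs
    n_steps: int = 2_000_000         # 1 ns at 0.5 fs
    temperature: float = 300.0       # K
    pressure: float = 1.0            # atm
    thermostat_tau: float = 50.0     # fs
    barostat_tau: float = 2.5        # ps
    sample_interval: float = 0.5     # ps
    seed: int = 0
    force_limit: float = 1e4         # kcal/mol/Å abort threshold
    compressibility: float = 4.5e-5  # atm⁻¹, Berendsen scaling factor

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble {self.ensemble}")
        if self.ensemble in ("NVT", "NPT") and self.thermostat_tau <= 0:
            raise ValueError("thermostat time constant must be positive")
        if self.ensemble == "NPT" and self.barostat_tau <= 0:
            raise ValueError("barostat time constant must be positive")


@dataclass
class Trajectory:
    frames: list[AtomicSystem]
    times: np.ndarray                # ps
    potential_energies: np.ndarray   # kcal/mol
    total_energies: np.ndarray       # kcal/mol
    volumes: np.ndarray              # Å³ (nan for clusters)
    temperatures: np.ndarray         # K
    unwrapped: list[np.ndarray]      # positions with image flags applied

    def __post_init__(self):
        n = len(self.frames)
        for arr in (self.times, self.potential_energies, self.total_energies,
                    self.volumes, self.temperatures):
            if len(arr) != n:
                raise ValueError("trajectory series lengths differ")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def masses(self) -> np.ndarray:
        return self.frames[0].masses


@dataclass
class ThermoSeries:
    """Energy series for fluctuation estimates."""

    energies: np.ndarray             # kcal/mol
    temperature: float               # K
    boltzmann: float = KB            # kcal/mol/K


def kinetic_energy(masses, velocities) -> float:
    """Kinetic energy, kcal/mol (velocities in Å/fs)."""
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2) / ACC)


def instantaneous_temperature(masses, velocities) -> float:
    n_dof = 3 * len(masses) - 3
    return 2.0 * kinetic_energy(masses, velocities) / (n_dof * KB)


def _maxwell_boltzmann(masses, T, rng):
    v = rng.normal(size=(len(masses), 3)) * np.sqrt(KB * T * ACC / masses)[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()  # zero COM drift
    return v


def _virial_pressure(system: AtomicSystem, calculator, e_pot: float,
                     T_inst: float, h: float = 1e-5) -> float:
    """Instantaneous pressure (atm) via a central-difference strain
    derivative of the potential energy plus the ideal kinetic part."""
    V = system.volume()
    es = []
    for s in (1.0 + h, 1.0 - h):
        scaled = AtomicSystem(system.species, system.positions * s,
                              system.cell * s, True, system.total_charge)
        es.append(calculator.evaluate(scaled, forces=False).E_total)
    dE_dV = (es[0] - es[1]) / (V * ((1 + h) ** 3 - (1 - h) ** 3))
    n = system.n_atoms
    p_kcal = n * KB * T_inst / V - dE_dV
    return p_kcal * PRESSURE_TO_ATM


def run_md(system: AtomicSystem, calculator, config: MDConfig) -> Trajectory:
    """Integrate and sample a trajectory.

    ``calculator`` follows the calculator contract (``evaluate(system,
    forces=True)`` with ``E_total`` and ``forces``).  Initial velocities are
    Maxwell-Boltzmann at the target temperature, seed-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    sys_t = system.copy()
    masses = sys_t.masses
    vel = _maxwell_boltzmann(masses, config.temperature, rng)
    n_dof = 3 * sys_t.n_atoms - 3
    Q = n_dof * KB * config.temperature * (config.thermostat_tau) ** 2  # NH mass
    xi = 0.0
    unwrap_offset = np.zeros_like(sys_t.positions)

    out = calculator.evaluate(sys_t, forces=True)
    forces = out.forces
    e_pot = out.E_total

    sample_every = max(1, int(round(config.sample_interval * 1000.0 / config.dt)))
    frames, times, e_pots, e_tots, vols, temps, unwrapped = [], [], [], [], [], [], []

    def record(step):
        ke = kinetic_energy(masses, vel)
        frames.append(sys_t.copy())
        times.append(step * config.dt / 1000.0)
        e_pots.append(e_pot)
        e_tots.append(e_pot + ke)
        vols.append(sys_t.volume() if sys_t.pbc else np.nan)
        temps.append(instantaneous_temperature(masses, vel))
        unwrapped.append(sys_t.positions + unwrap_offset)

    record(0)
    dt = config.dt
    for step in range(1, config.n_steps + 1):
        if config.ensemble in ("NVT", "NPT"):
            # implicit Nosé–Hoover velocity-Verlet splitting
            acc = forces / masses[:, None] * ACC
            vel = vel + 0.5 * dt * (acc - xi * vel)
            dx = dt * vel
        else:
            acc = forces / masses[:, None] * ACC
            vel = vel + 0.5 * dt * acc
            dx = dt * vel
        sys_t.positions = sys_t.positions + dx
        if sys_t.pbc:
            frac = sys_t.positions @ np.linalg.inv(sys_t.cell)
            wrap = np.floor(frac)
            if np.any(wrap):
                shift = wrap @ sys_t.cell
                sys_t.positions -= shift
                unwrap_offset += shift

        out = calculator.evaluate(sys_t, forces=True)
        forces = out.forces
        e_pot = out.E_total
        fmax = np.abs(forces).max()
        if fmax > config.force_limit:
            atom = int(np.argmax(np.abs(forces).max(axis=1)))
            raise RuntimeError(f"force blow-up at step {step}: atom {atom} "
                               f"|F| = {fmax:.3g} kcal/mol/Å")

        acc = forces / masses[:, None] * ACC
        if config.ensemble in ("NVT", "NPT"):
            ke = kinetic_energy(masses, vel)
            xi = xi + dt * (2.0 * ke - n_dof * KB * config.temperature) / Q
            vel = (vel + 0.5 * dt * acc) / (1.0 + 0.5 * dt * xi)
        else:
            vel = vel + 0.5 * dt * acc

        if config.ensemble == "NPT":
            T_inst = instantaneous_temperature(masses, vel)
            p_inst = _virial_pressure(sys_t, calculator, e_pot, T_inst)
            mu = (1.0 - config.compressibility * dt / (config.barostat_tau * 1000.0)
                  * (config.pressure - p_inst)) ** (1.0 / 3.0)
            mu = min(max(mu, 0.98), 1.02)  # guard against shocks
            sys_t.positions = sys_t.positions * mu
            sys_t.cell = sys_t.cell * mu
            unwrap_offset *= mu

        if step % sample_every == 0:
            record(step)

    return Trajectory(frames, np.array(times), np.array(e_pots),
                      np.array(e_tots), np.array(vols), np.array(temps),
                      unwrapped)


def minimize(system: AtomicSystem, calculator, max_steps: int = 500,
             f_tol: float = 1e-4, **_legacy) -> AtomicSystem:
    """Geometry relaxation (L-BFGS on the calculator's energy/forces);
    used to prepare packed cells before dynamics and to find stationary
    points.  ``f_tol`` is the max force component at convergence."""
    from scipy.optimize import minimize as _scipy_min

    sys_t = system.copy()
    shape = sys_t.positions.shape

    def fun(x):
        trial = sys_t.copy()
        trial.positions = x.reshape(shape)
        out = calculator.evaluate(trial, forces=True)
        return out.E_total, -out.forces.ravel()

    res = _scipy_min(fun, sys_t.positions.ravel(), jac=True, method="L-BFGS-B",
                     options={"maxiter": max_steps, "gtol": f_tol,
                              "ftol": 1e-14})
    sys_t.positions = res.x.reshape(shape)
    return sys_t


# -- estimators -------------------------------------------------------------

def density_average(trajectory: Trajectory, window: float = 0.8):
    """Mass density averaged over the trailing ``window`` fraction of the
    run (default last 80%, the convention used for 1 ns runs averaged over
    their last 800 ps).  Returns ``(mean g/cm³, series g/cm³)``."""
    if np.any(~np.isfinite(trajectory.volumes)):
        raise ValueError("density requires a periodic (volume-bearing) trajectory")
    mass = trajectory.masses.sum()           # g/mol
    series = mass * 1e24 / 6.02214076e23 / trajectory.volumes
    n = len(series)
    start = n - max(1, int(round(window * n)))
    return float(series[start:].mean()), series


def einstein_diffusivity(trajectory: Trajectory, fit_window=(0.2, 0.8),
                         groups: Optional[Sequence[np.ndarray]] = None):
    """Self-diffusivity from the Einstein relation, MSD(t) = 6 D t.

    MSD is averaged over time origins and over ``groups`` (default: each
    molecule... each atom when no grouping is given), using unwrapped
    coordinates.  The slope is fitted by least squares on the lag range
    ``fit_window`` (fractions of the maximum lag).  Returns ``(D cm²/s,
    lags ps, msd Å²)``.
    """
    n_frames = len(trajectory.frames)
    if n_frames < 4:
        raise ValueError("trajectory too short for a diffusivity fit")
    masses = trajectory.masses
    if groups is None:
        tracks = np.stack(trajectory.unwrapped)           # (F, N, 3)
    else:
        tracks = np.stack([
            np.stack([np.average(u[g], axis=0, weights=masses[g]) for g in groups])
            for u in trajectory.unwrapped])               # (F, G, 3)
    max_lag = n_frames - 1
    # every time origin contributes, but at most 512 distinct lags are
    # evaluated (enough resolution for a slope fit at any trajectory length)
    lags = np.unique(np.linspace(1, max_lag, min(max_lag, 512)).astype(int))
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = tracks[lag:] - tracks[:-lag]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
    dt = trajectory.times[1] - trajectory.times[0]        # ps
    t = lags * dt
    lo = int(round(fit_window[0] * len(lags)))
    hi = max(lo + 2, int(round(fit_window[1] * len(lags))))
    A = np.vstack([t[lo:hi], np.ones(hi - lo)]).T
    slope, _ = np.linalg.lstsq(A, msd[lo:hi], rcond=None)[0]
    D_A2_ps = slope / 6.0
    return D_A2_ps * 1e-4, t, msd                         # Å²/ps -> cm²/s


def heat_capacity(thermo: ThermoSeries) -> float:
    """Fluctuation heat capacity (⟨E²⟩-⟨E⟩²)/(k_B T²), population moments.

    Units: kcal/mol/K for energies in kcal/mol.  Divide by the total mass
    for a specific heat.
    """
    if thermo.temperature <= 0:
        raise ValueError("temperature must be positive")
    e = np.asarray(thermo.energies, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least two energy samples")
    var = float(np.mean(e * e) - np.mean(e) ** 2)
    return var / (thermo.boltzmann * thermo.temperature ** 2)


def rdf(trajectory: Trajectory, species_pair: tuple[str, str], r_max: float,
        n_bins: int = 100):
    """Shell-normalized radial distribution function g(r) for an element
    pair, averaged over frames (periodic frames only).

    Returns ``(r_centers, g, raw_counts)``.
    """
    frame0 = trajectory.frames[0]
    if not frame0.pbc:
        raise ValueError("rdf requires periodic frames")
    sa, sb = species_pair
    ia = np.array([i for i, s in enumerate(frame0.species) if s == sa])
    ib = np.array([i for i, s in enumerate(frame0.species) if s == sb])
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"no atoms of species {species_pair}")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    n_frames = len(trajectory.frames)
    for frame in trajectory.frames:
        L_half = 0.5 * min(np.linalg.norm(frame.cell, axis=1))
        if r_max >= L_half:
            raise ValueError("r_max must be below half the cell width")
        inv = np.linalg.inv(frame.cell)
        d = frame.positions[ib][None, :, :] - frame.positions[ia][:, None, :]
        frac = d @ inv
        frac -= np.round(frac)
        r = np.linalg.norm(frac @ frame.cell, axis=-1)
        if sa == sb:
            iu = np.triu_indices(len(ia), k=1)
            r = r[iu]
            mult = 2.0
        else:
            r = r.ravel()
            r = r[r > 1e-9]
            mult = 1.0
        h, _ = np.histogram(r, bins=edges)
        counts += mult * h
    V = np.mean([f.volume() for f in trajectory.frames])
    rho_b = len(ib) / V
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = n_frames * len(ia) * rho_b * shell
    if sa == sb:
        norm = n_frames * len(ia) * (len(ia) - 1) / V * shell
    g = counts / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g, counts


def radius_of_gyration(trajectory: Trajectory, chain_atoms: np.ndarray,
                       n_bins: int = 50):
    """Mass-weighted radius of gyration of one chain per frame.

    Returns ``(rg_series Å, histogram, bin_edges, variance)``; the variance
    across frames measures chain flexibility.
    """
    chain_atoms = np.asarray(chain_atoms, dtype=int)
    masses = trajectory.masses[chain_atoms]
    rgs = []
    for u in trajectory.unwrapped:
        r = u[chain_atoms]
        com = masses @ r / masses.sum()
        rgs.append(np.sqrt(masses @ np.sum((r - com) ** 2, axis=1) / masses.sum()))
    rgs = np.array(rgs)
    hist, edges = np.histogram(rgs, bins=n_bins)
    return rgs, hist, edges, float(rgs.var())


def dihedral_distribution(trajectory: Trajectory,
                          quadruples: Sequence[tuple[int, int, int, int]],
                          n_bins: int = 72):
    """Histogram of signed backbone dihedrals over (-180°, 180°].

    Degenerate (collinear) geometries are skipped and counted.  Returns
    ``(bin_centers, histogram, n_skipped)``.
    """
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    skipped = 0
    for u in trajectory.unwrapped:
        for (a, b, c, d) in quadruples:
            try:
                ang = signed_dihedral(u[a], u[b], u[c], u[d])
            except ValueError:
                skipped += 1
                continue
            k = min(np.searchsorted(edges, ang, side="left") - 1, n_bins - 1)
            counts[max(k, 0)] += 1
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, counts, skipped
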