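"""Behler–Parrinello-type atomic environment vectors (AEVs).

Radial symmetry functions are Gaussian shells smoothed by a cosine cutoff,
summed per neighbor element; angular functions follow the ANI form with
shifted angular sections.  A charge-weighted radial variant multiplies each
neighbor contribution by that neighbor's partial charge, giving the energy
head a handle on the electrostatic environment.

All descriptor math runs on :mod:`polyff.autodiff` tensors so that energy
models built on top of it have exact analytic forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .system import AtomicSystem
from .units import SUPPORTED_ELEMENTS


@dataclass
class DescriptorConfig:
    radial_cutoff: float = 5.2          # Å
    angular_cutoff: float = 3.5         # Å
    radial_shifts: tuple = field(default_factory=tuple)   # μ_R, Å
    radial_eta: float = 16.0            # η_R, Å⁻²
    angular_shifts: tuple = field(default_factory=tuple)  # μ_A, Å
    angular_sections: tuple = field(default_factory=tuple)  # θ_s, rad
    angular_eta: float = 8.0            # η_A, Å⁻²
    zeta: float = 32.0
    element_order: tuple = SUPPORTED_ELEMENTS

    def __post_init__(self):
        if not self.radial_shifts:
            self.radial_shifts = tuple(np.linspace(0.8, self.radial_cutoff, 16,
                                                   endpoint=False))
        if not self.angular_shifts:
            self.angular_shifts = tuple(np.linspace(0.8, self.angular_cutoff, 4,
                                                    endpoint=False))
        if not self.angular_sections:
            self.angular_sections = tuple(np.linspace(0.0, np.pi, 8,
                                                      endpoint=False) + np.pi / 16)
        if self.angular_cutoff > self.radial_cutoff:
            raise ValueError("angular cutoff must not exceed radial cutoff")
        if np.any(np.diff(self.radial_shifts) <= 0) or np.any(np.diff(self.angular_shifts) <= 0):
            raise ValueError("shifts must be strictly increasing")
        if min(self.radial_eta, self.angular_eta, self.zeta) <= 0:
            raise ValueError("widths must be positive")

    @classmethod
    def desk_scale(cls) -> "DescriptorConfig":
        """Compact configuration used in tests and small training runs:
        full radial resolution (cheap) but a reduced angular block, with
        widths matched to the coarser shell spacing."""
        return cls(angular_shifts=tuple(np.linspace(0.8, 3.5, 4, endpoint=False)),
                   angular_sections=tuple(np.linspace(0, np.pi, 4, endpoint=False) + np.pi / 8),
                   angular_eta=2.0, zeta=16.0)

    # -- layout -------------------------------------------------------------
    @property
    def n_elements(self) -> int:
        return len(self.element_order)

    @property
    def n_element_pairs(self) -> int:
        n = self.n_elements
        return n * (n + 1) // 2

    @property
    def radial_length(self) -> int:
        return self.n_elements * len(self.radial_shifts)

    @property
    def angular_length(self) -> int:
        return self.n_element_pairs * len(self.angular_shifts) * len(self.angular_sections)

    @property
    def length(self) -> int:
        return self.radial_length + self.angular_length

    def element_index(self, species) -> np.ndarray:
        lookup = {e: i for i, e in enumerate(self.element_order)}
        try:
            return np.array([lookup[s] for s in species], dtype=int)
        except KeyError as exc:
            raise ValueError(f"element {exc.args[0]} not in element_order") from exc

    def pair_block(self) -> np.ndarray:
        """(n_elem, n_elem) unordered-pair block index table."""
        n = self.n_elements
        tbl = np.zeros((n, n), dtype=int)
        k = 0
        for a in range(n):
            for b in range(a, n):
                tbl[a, b] = tbl[b, a] = k
                k += 1
        return tbl

    def to_dict(self) -> dict:
        return {
            "radial_cutoff": self.radial_cutoff, "angular_cutoff": self.angular_cutoff,
            "radial_shifts": list(self.radial_shifts), "radial_eta": self.radial_eta,
            "angular_shifts": list(self.angular_shifts),
            "angular_sections": list(self.angular_sections),
            "angular_eta": self.angular_eta, "zeta": self.zeta,
            "element_order": list(self.element_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        d = dict(d)
        for key in ("radial_shifts", "angular_shifts", "angular_sections", "element_order"):
            d[key] = tuple(d[key])
        return cls(**d)


def build_pairs(system: AtomicSystem, cutoff: float):
    """Directed neighbor pairs within ``cutoff``.

    Returns ``(pi, pj, shift)`` where ``shift`` is the constant Cartesian
    periodic-image offset so that the differentiable displacement is
    ``pos[pj] - pos[pi] + shift``.  Under PBC the cutoff must be below half
    the minimum cell width (minimum-image convention).
    """
    pos = system.positions
    n = system.n_atoms
    d = pos[None, :, :] - pos[:, None, :]
    shift = np.zeros_like(d)
    if system.pbc:
        widths = _cell_widths(system.cell)
        if cutoff >= 0.5 * widths.min():
            raise ValueError(
                f"cutoff {cutoff} Å exceeds half the minimum cell width "
                f"{0.5 * widths.min():.3f} Å")
        inv = np.linalg.inv(system.cell)
        frac = d @ inv
        image = -np.round(frac)
        shift = image @ system.cell
        d = d + shift
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    mask = r < cutoff
    pi, pj = np.nonzero(mask)
    close = r[mask] < 1e-6
    if np.any(close):
        a, b = pi[close][0], pj[close][0]
        raise ValueError(f"atoms {a} and {b} overlap (r < 1e-6 Å)")
    return pi, pj, shift[mask]


def _cell_widths(cell: np.ndarray) -> np.ndarray:
    """Perpendicular widths of a (possibly triclinic) cell."""
    vol = abs(np.linalg.det(cell))
    cross = np.cross(np.roll(cell, -1, axis=0), np.roll(cell, -2, axis=0))
    return vol / np.linalg.norm(cross, axis=1)


def _cutoff_fn(r: ad.Tensor, rc: float) -> ad.Tensor:
    inside = r.data < rc
    val = ad.mul(0.5, ad.add(ad.tcos(ad.mul(r, np.pi / rc)), 1.0))
    return ad.where(inside, val, ad.Tensor(np.zeros_like(r.data)))


class AEVCache:
    """Pair structure and radial terms of one evaluation, reusable for
    charge-weighting without recomputing geometry."""

    __slots__ = ("n", "pi", "pj", "rows", "radial_contrib", "config", "empty")

    def __init__(self, n, pi, pj, rows, radial_contrib, config, empty):
        self.n, self.pi, self.pj = n, pi, pj
        self.rows, self.radial_contrib = rows, radial_contrib
        self.config, self.empty = config, empty


def aev_with_cache(positions: ad.Tensor, system: AtomicSystem,
                   config: DescriptorConfig):
    """Differentiable AEVs ``(N, length)`` plus a cache for charge-weighting."""
    n = system.n_atoms
    elem = config.element_index(system.species)
    pi, pj, shift = build_pairs(system, config.radial_cutoff)
    n_rs = len(config.radial_shifts)

    if len(pi) == 0:
        zeros = ad.Tensor(np.zeros((n, config.length)))
        return zeros, AEVCache(n, pi, pj, None, None, config, True)

    disp = ad.add(ad.take(positions, (pj,)), ad.neg(ad.take(positions, (pi,))))
    if np.any(shift):
        disp = ad.add(disp, ad.Tensor(shift))
    r = ad.power(ad.tsum(ad.mul(disp, disp), axis=1), 0.5)

    # radial block: Gaussian shells × cosine cutoff, summed per neighbor element
    mu = np.asarray(config.radial_shifts)
    rcol = ad.reshape(r, (-1, 1))
    gauss = ad.texp(ad.mul(-config.radial_eta,
                           ad.power(ad.add(rcol, ad.Tensor(-mu[None, :])), 2.0)))
    fc = ad.reshape(_cutoff_fn(r, config.radial_cutoff), (-1, 1))
    radial_contrib = ad.mul(gauss, fc)                      # (P, n_rs)
    rows = pi * config.n_elements + elem[pj]
    radial_flat = ad.scatter((n * config.n_elements, n_rs), (rows,), radial_contrib)
    radial = ad.reshape(radial_flat, (n, config.radial_length))

    # angular block over neighbor pairs inside the angular cutoff
    ang_mask = r.data < config.angular_cutoff
    angular = _angular_block(positions, system, config, elem,
                             pi[ang_mask], pj[ang_mask], shift[ang_mask], n)
    aev = ad.concat([radial, angular], axis=1)
    return aev, AEVCache(n, pi, pj, rows, radial_contrib, config, False)


def cw_radial_from_cache(cache: AEVCache, charges: ad.Tensor) -> ad.Tensor:
    """Charge-weighted radial AEV using a previously computed cache."""
    config = cache.config
    if cache.empty:
        return ad.Tensor(np.zeros((cache.n, config.radial_length)))
    qj = ad.reshape(ad.take(charges, (cache.pj,)), (-1, 1))
    cw_contrib = ad.mul(cache.radial_contrib, qj)
    cw_flat = ad.scatter((cache.n * config.n_elements, len(config.radial_shifts)),
                         (cache.rows,), cw_contrib)
    return ad.reshape(cw_flat, (cache.n, config.radial_length))


def aev_tensors(positions: ad.Tensor, system: AtomicSystem, config: DescriptorConfig,
                charges: ad.Tensor | None = None):
    """Differentiable AEVs for every atom.

    Returns ``(aev, cw_radial)`` — the full AEV ``(N, length)`` and, when
    ``charges`` is given, the charge-weighted radial block
    ``(N, radial_length)`` (otherwise ``None``).
    """
    aev, cache = aev_with_cache(positions, system, config)
    cw = cw_radial_from_cache(cache, charges) if charges is not None else None
    return aev, cw


def _angular_block(positions, system, config, elem, pi, pj, shift, n):
    n_as, n_sec = len(config.angular_shifts), len(config.angular_sections)
    width = n_as * n_sec
    out_shape = (n * config.n_element_pairs, width)
    # enumerate neighbor pairs (j, k) per center i from the directed pair list
    t_center, t_a, t_b = [], [], []
    order = np.argsort(pi, kind="stable")
    pi_s, idx_s = pi[order], order
    bounds = np.searchsorted(pi_s, np.arange(n + 1))
    for i in range(n):
        lo, hi = bounds[i], bounds[i + 1]
        if hi - lo < 2:
            continue
        members = idx_s[lo:hi]
        a, b = np.triu_indices(len(members), k=1)
        t_center.append(np.full(len(a), i))
        t_a.append(members[a])
        t_b.append(members[b])
    if not t_center:
        return ad.Tensor(np.zeros((n, config.angular_length)))
    t_center = np.concatenate(t_center)
    t_a = np.concatenate(t_a)        # indices into the pair arrays
    t_b = np.concatenate(t_b)

    dj = ad.add(ad.take(positions, (pj[t_a],)), ad.neg(ad.take(positions, (t_center,))))
    dk = ad.add(ad.take(positions, (pj[t_b],)), ad.neg(ad.take(positions, (t_center,))))
    if np.any(shift):
        dj = ad.add(dj, ad.Tensor(shift[t_a]))
        dk = ad.add(dk, ad.Tensor(shift[t_b]))
    rj = ad.power(ad.tsum(ad.mul(dj, dj), axis=1), 0.5)
    rk = ad.power(ad.tsum(ad.mul(dk, dk), axis=1), 0.5)
    cosq = ad.mul(ad.tsum(ad.mul(dj, dk), axis=1), ad.power(ad.mul(rj, rk), -1.0))
    # scale keeps arccos away from the |cos|=1 derivative singularity
    theta = ad.tarccos(ad.mul(cosq, 0.95))

    sections = np.asarray(config.angular_sections)
    ang = ad.power(ad.mul(ad.add(ad.tcos(ad.add(ad.reshape(theta, (-1, 1)),
                                                ad.Tensor(-sections[None, :]))), 1.0), 0.5),
                   config.zeta)
    ang = ad.mul(ang, 2.0)                                   # 2·((1+cos)/2)^ζ
    ravg = ad.mul(ad.add(rj, rk), 0.5)
    mu_a = np.asarray(config.angular_shifts)
    rad = ad.texp(ad.mul(-config.angular_eta,
                         ad.power(ad.add(ad.reshape(ravg, (-1, 1)),
                                         ad.Tensor(-mu_a[None, :])), 2.0)))
    fc = ad.mul(_cutoff_fn(rj, config.angular_cutoff), _cutoff_fn(rk, config.angular_cutoff))
    contrib = ad.mul(ad.mul(ad.reshape(rad, (-1, n_as, 1)),
                            ad.reshape(ang, (-1, 1, n_sec))),
                     ad.reshape(fc, (-1, 1, 1)))
    contrib = ad.reshape(contrib, (-1, width))
    blk = config.pair_block()
    rows = t_center * config.n_element_pairs + blk[elem[pj[t_a]], elem[pj[t_b]]]
    flat = ad.scatter(out_shape, (rows,), contrib)
    return ad.reshape(flat, (n, config.angular_length))


# -- plain-numpy convenience wrappers --------------------------------------

def compute_aev(system: AtomicSystem, config: DescriptorConfig | None = None) -> np.ndarray:
    """Per-atom AEV matrix, shape (N, config.length)."""
    config = config or DescriptorConfig()
    with ad.no_grad():
        aev, _ = aev_tensors(ad.Tensor(system.positions), system, config)
    return aev.numpy()


def charge_weighted_aev(system: AtomicSystem, charges: np.ndarray,
                        config: DescriptorConfig | None = None) -> np.ndarray:
    """Charge-weighted radial AEV: each neighbor term scaled by q_j.

    Linear (degree 1 homogeneous) in the charges.
    """
    config = config or DescriptorConfig()
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (system.n_atoms,):
        raise ValueError("charges length must equal atom count")
    with ad.no_grad():
        _, cw = aev_tensors(ad.Tensor(system.positions), system, config,
                            charges=ad.Tensor(charges))
    return cw.numpy()
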