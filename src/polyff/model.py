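"""The charge-recursive neural-network (QRNN) potential.

Per-element feed-forward networks predict atomic electronegativities from
AEVs; a charge-equilibration (Qeq) solve turns these into partial charges
under total-charge conservation; the charges are fed back as features
(charge-weighted radial AEV) for a second electronegativity pass — the
recursion, fixed at two iterations.  Final charges enter an atomic energy
network together with the AEV, and the total energy adds a long-range
Coulomb term over those charges and a damped pairwise dispersion term:

    E_total = Σ_i E_i(AEV_i, q_i, qAEV_i) + E_coulomb(q, r) + E_dispersion(r)

Forces are the exact analytic negative gradient of E_total, differentiated
through the Qeq linear solve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import erf as _np_erf, erfc as _np_erfc

from . import autodiff as ad
from .descriptors import (AEVCache, DescriptorConfig, aev_with_cache,
                          build_pairs, cw_radial_from_cache)
from .system import AtomicSystem
from .units import KE_COULOMB, SUPPORTED_ELEMENTS


# -- parameter containers ---------------------------------------------------

def _init_mlp(rng, sizes):
    """Weight-normalized linear layers: w = g * v / ||v||_row."""
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        v = rng.normal(scale=1.0 / np.sqrt(fan_in), size=(fan_out, fan_in))
        g = np.linalg.norm(v, axis=1)
        b = np.zeros(fan_out)
        layers.append({"v": v, "g": g, "b": b})
    return layers


def _mlp_forward(layers, x: ad.Tensor, alpha: float = 1.0) -> ad.Tensor:
    for li, layer in enumerate(layers):
        v, g, b = layer["v"], layer["g"], layer["b"]
        norm = ad.power(ad.tsum(ad.mul(v, v), axis=1), 0.5)
        w = ad.mul(v, ad.reshape(ad.mul(g, ad.power(norm, -1.0)), (-1, 1)))
        x = ad.add(ad.matmul(x, ad.transpose(w)), b)
        if li < len(layers) - 1:
            x = ad.celu(x, alpha)
    return x


# D2-style dispersion defaults (kcal·Å⁶/mol, Å); shipped constants, tunable.
_C6_DEFAULT = {"H": 33.5, "C": 418.2, "O": 167.3}
_R0_DEFAULT = {"H": 1.001, "C": 1.452, "O": 1.342}


@dataclass
class DispersionParams:
    """Pairwise -C6/r⁶ dispersion with Chai–Head-Gordon damping
    f(r) = [1 + a (r/R0)^-12]^-1; per-element C6 combined geometrically,
    R0 by arithmetic sum of the two radii."""

    c6: dict = field(default_factory=lambda: dict(_C6_DEFAULT))
    r0: dict = field(default_factory=lambda: dict(_R0_DEFAULT))
    a: float = 6.0
    cutoff: float = 10.0  # Å, periodic sums only

    def pair(self, e1: str, e2: str) -> tuple[float, float]:
        try:
            return (float(np.sqrt(self.c6[e1] * self.c6[e2])),
                    float(self.r0[e1] + self.r0[e2]))
        except KeyError as exc:
            raise ValueError(f"missing dispersion parameters for element {exc.args[0]}")


@dataclass
class QRNNHyper:
    """Architecture hyperparameters (layer widths, output scales, Qeq mode,
    Wolf damping).  ``energy_scale``/``chi_scale`` set the natural output
    range of the freshly initialized heads (kcal/mol per atom and
    kcal/mol/e) so optimization starts in the right order of magnitude."""

    chi_hidden: tuple = (32, 32)
    energy_hidden: tuple = (32, 32)
    activation_alpha: float = 1.0   # CELU α
    energy_scale: float = 5.0       # kcal/mol per atom
    chi_scale: float = 50.0         # kcal/mol/e
    qeq_mode: str = "full"          # "full" | "local" (diagonal-only Qeq)
    qeq_iterations: int = 2
    coulomb_kernel: str = "smeared"  # "smeared" (Qeq-consistent) | "bare"
    wolf_alpha: float = 0.2         # Å⁻¹, periodic Coulomb damping
    coulomb_cutoff: float = 10.0    # Å, periodic sums only


class QRNNModel:
    """Evaluatable QRNN potential (the calculator contract).

    ``params`` is a nested dict of numpy arrays; :meth:`evaluate` runs the
    model on an :class:`AtomicSystem` and returns an
    :class:`EnergyBreakdown`.
    """

    def __init__(self, descriptor: DescriptorConfig | None = None,
                 hyper: QRNNHyper | None = None,
                 dispersion: DispersionParams | None = None,
                 params: dict | None = None, seed: int = 0):
        self.descriptor = descriptor or DescriptorConfig()
        self.hyper = hyper or QRNNHyper()
        self.dispersion = dispersion or DispersionParams()
        self.params = params if params is not None else self._init_params(seed)

    # -- parameters ---------------------------------------------------------
    def _init_params(self, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        cfg = self.descriptor
        chi_in = cfg.length + cfg.radial_length          # AEV + charge-weighted AEV
        en_in = cfg.length + 1 + cfg.radial_length       # AEV + q_i + charge-weighted
        params: dict = {"chi": {}, "energy": {}, "logJ": {}, "loggamma": {},
                        "e0": {}}
        for e in cfg.element_order:
            params["chi"][e] = _init_mlp(rng, (chi_in, *self.hyper.chi_hidden, 1))
            params["energy"][e] = _init_mlp(rng, (en_in, *self.hyper.energy_hidden, 1))
            # hardness ~ 250 kcal/mol/e², width ~ 0.8 Å: chemically scaled starts
            params["logJ"][e] = np.array(np.log(250.0))
            params["loggamma"][e] = np.array(np.log(0.8))
            params["e0"][e] = np.array(0.0)
        return params

    def flat_params(self):
        """Deterministic (path, array) traversal for optimizers."""
        out = []

        def walk(prefix, node):
            if isinstance(node, dict):
                for k in sorted(node):
                    walk(prefix + (k,), node[k])
            elif isinstance(node, list):
                for i, item in enumerate(node):
                    walk(prefix + (i,), item)
            else:
                out.append((prefix, node))

        walk((), self.params)
        return out

    def set_flat_params(self, values):
        for (path, _), new in zip(self.flat_params(), values):
            node = self.params
            for key in path[:-1]:
                node = node[key]
            node[path[-1]] = np.asarray(new)

    def copy(self) -> "QRNNModel":
        import copy as _copy
        return QRNNModel(self.descriptor, self.hyper, self.dispersion,
                         _copy.deepcopy(self.params))

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        def enc(node):
            if isinstance(node, dict):
                return {k: enc(v) for k, v in node.items()}
            if isinstance(node, list):
                return [enc(v) for v in node]
            return np.asarray(node).tolist()

        bundle = {
            "format": "polyff-qrnn-1",
            "units": {"length": "angstrom", "energy": "kcal/mol", "charge": "e"},
            "descriptor": self.descriptor.to_dict(),
            "hyper": {"chi_hidden": list(self.hyper.chi_hidden),
                      "energy_hidden": list(self.hyper.energy_hidden),
                      "activation_alpha": self.hyper.activation_alpha,
                      "energy_scale": self.hyper.energy_scale,
                      "chi_scale": self.hyper.chi_scale,
                      "qeq_mode": self.hyper.qeq_mode,
                      "qeq_iterations": self.hyper.qeq_iterations,
                      "coulomb_kernel": self.hyper.coulomb_kernel,
                      "wolf_alpha": self.hyper.wolf_alpha,
                      "coulomb_cutoff": self.hyper.coulomb_cutoff},
            "dispersion": {"c6": self.dispersion.c6, "r0": self.dispersion.r0,
                           "a": self.dispersion.a, "cutoff": self.dispersion.cutoff},
            "params": enc(self.params),
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)

    @classmethod
    def load(cls, path) -> "QRNNModel":
        with open(path) as fh:
            bundle = json.load(fh)

        def dec(node):
            if isinstance(node, dict):
                return {k: dec(v) for k, v in node.items()}
            if isinstance(node, list) and node and isinstance(node[0], dict):
                return [dec(v) for v in node]
            return np.asarray(node)

        h = bundle["hyper"]
        hyper = QRNNHyper(tuple(h["chi_hidden"]), tuple(h["energy_hidden"]),
                          float(h["activation_alpha"]), float(h["energy_scale"]),
                          float(h["chi_scale"]), h["qeq_mode"],
                          int(h["qeq_iterations"]), h["coulomb_kernel"],
                          float(h["wolf_alpha"]), float(h["coulomb_cutoff"]))
        disp = DispersionParams(bundle["dispersion"]["c6"], bundle["dispersion"]["r0"],
                                bundle["dispersion"]["a"], bundle["dispersion"]["cutoff"])
        return cls(DescriptorConfig.from_dict(bundle["descriptor"]), hyper, disp,
                   dec(bundle["params"]))

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, system: AtomicSystem, forces: bool = True) -> "EnergyBreakdown":
        pos = ad.Tensor(system.positions, requires_grad=forces)
        out = qrnn_forward(pos, system, self.params_t(self.params), self)
        f = None
        if forces:
            g = ad.grad(out["E_total"], pos)
            f = -g.numpy()
        return EnergyBreakdown(
            E_short=out["E_short"].item(), E_coulomb=out["E_coulomb"].item(),
            E_dispersion=out["E_dispersion"].item(), E_total=out["E_total"].item(),
            forces=f, charges=out["charges"].numpy().copy(),
            charges_iter1=out["charges_iter1"].numpy().copy(),
            dipole=out["dipole"].numpy().copy())

    @staticmethod
    def params_t(params, requires_grad: bool = False):
        def wrap(node):
            if isinstance(node, dict):
                return {k: wrap(v) for k, v in node.items()}
            if isinstance(node, list):
                return [wrap(v) for v in node]
            return ad.Tensor(node, requires_grad=requires_grad)
        return wrap(params)

    def parameter_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for _, arr in self.flat_params():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


@dataclass
class EnergyBreakdown:
    E_short: float
    E_coulomb: float
    E_dispersion: float
    E_total: float
    forces: Optional[np.ndarray]
    charges: np.ndarray
    charges_iter1: np.ndarray
    dipole: np.ndarray


# -- forward pass -----------------------------------------------------------

def _per_atom_net(nets_t, feats: ad.Tensor, elem_idx: np.ndarray,
                  element_order, alpha: float = 1.0,
                  scale: float = 1.0) -> ad.Tensor:
    """Apply each element's network to its atoms; returns (N,) outputs."""
    n = len(elem_idx)
    parts = []
    for ei, e in enumerate(element_order):
        atoms = np.nonzero(elem_idx == ei)[0]
        if len(atoms) == 0:
            continue
        sub = ad.take(feats, (atoms,))
        out = _mlp_forward(nets_t[e], sub, alpha)
        parts.append((atoms, ad.reshape(out, (-1,))))
    total = ad.Tensor(np.zeros(n))
    for atoms, vals in parts:
        total = ad.add(total, ad.scatter((n,), (atoms,), vals))
    return total if scale == 1.0 else ad.mul(total, scale)


def predict_electronegativities(aevs: np.ndarray, model: QRNNModel,
                                species: list[str]) -> np.ndarray:
    """Plain-numpy electronegativity head on precomputed features.

    Features may be the bare AEV (iteration 1); the charge-weighted block is
    then implicitly zero.
    """
    cfg = model.descriptor
    feats = np.asarray(aevs, dtype=float)
    want = cfg.length + cfg.radial_length
    if feats.shape[1] == cfg.length:
        feats = np.hstack([feats, np.zeros((feats.shape[0], cfg.radial_length))])
    elif feats.shape[1] != want:
        raise ValueError(f"feature width {feats.shape[1]} does not match network "
                         f"input {want}")
    elem_idx = cfg.element_index(species)
    with ad.no_grad():
        chi = _per_atom_net(QRNNModel.params_t(model.params)["chi"],
                            ad.Tensor(feats), elem_idx, cfg.element_order,
                            model.hyper.activation_alpha, model.hyper.chi_scale)
    return chi.numpy()


def _qeq_matrix(pos: ad.Tensor, system: AtomicSystem, J_atoms: ad.Tensor,
                gamma_atoms: ad.Tensor, mode: str, wolf_alpha: float,
                cutoff: float):
    """Qeq system matrix: diag(J) plus the smeared Coulomb kernel.

    The kernel between Gaussian charges of widths γ_i, γ_j is
    k_e erf(r / (√2 γ_ij)) / r with γ_ij = sqrt(γ_i² + γ_j²).  Periodic
    systems use minimum-image pairs within the Coulomb cutoff, shifted to
    vanish at the cutoff (Wolf-style); clusters use all pairs.
    """
    n = system.n_atoms
    A = ad.scatter((n, n), (np.arange(n), np.arange(n)), J_atoms)
    if mode == "local" or n == 1:
        return A
    if system.pbc:
        pi, pj, shift = build_pairs(system, cutoff)
        keep = pi < pj
        pi, pj, shift = pi[keep], pj[keep], shift[keep]
        if len(pi) == 0:
            return A
        d = ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,))))
        d = ad.add(d, ad.Tensor(shift))
    else:
        iu, ju = np.triu_indices(n, k=1)
        pi, pj = iu, ju
        d = ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,))))
    r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
    gij = ad.power(ad.add(ad.power(ad.take(gamma_atoms, (pi,)), 2.0),
                          ad.power(ad.take(gamma_atoms, (pj,)), 2.0)), 0.5)
    kern = ad.mul(KE_COULOMB,
                  ad.mul(ad.terf(ad.mul(r, ad.power(ad.mul(gij, np.sqrt(2.0)), -1.0))),
                         ad.power(r, -1.0)))
    if system.pbc:
        # shift the kernel to zero at the cutoff for continuity
        kshift = ad.mul(KE_COULOMB,
                        ad.mul(ad.terf(ad.mul(cutoff, ad.power(ad.mul(gij, np.sqrt(2.0)), -1.0))),
                               1.0 / cutoff))
        kern = ad.add(kern, ad.neg(kshift))
    A = ad.add(A, ad.scatter((n, n), (pi, pj), kern))
    A = ad.add(A, ad.scatter((n, n), (pj, pi), kern))
    return A


def qeq_charges_t(chi: ad.Tensor, J_atoms: ad.Tensor, gamma_atoms: ad.Tensor,
                  pos: ad.Tensor, system: AtomicSystem, mode: str = "full",
                  wolf_alpha: float = 0.2, cutoff: float = 10.0) -> ad.Tensor:
    """Constrained Qeq solve as one (N+1) linear system with a Lagrange
    multiplier enforcing Σq = total charge."""
    n = system.n_atoms
    A = _qeq_matrix(pos, system, J_atoms, gamma_atoms, mode, wolf_alpha, cutoff)
    ones_col = ad.Tensor(np.ones((n, 1)))
    top = ad.concat([A, ones_col], axis=1)
    bottom = ad.Tensor(np.concatenate([np.ones(n), [0.0]])[None, :])
    M = ad.concat([top, bottom], axis=0)
    rhs = ad.concat([ad.neg(chi), ad.Tensor([float(system.total_charge)])], axis=0)
    try:
        sol = ad.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Qeq matrix — consider larger hardness J") from exc
    return ad.take(sol, (slice(0, n),))


def solve_qeq(chi, J, gamma, positions, cell=None, pbc=False, total_charge=0,
              mode: str = "full") -> np.ndarray:
    """Standalone numpy Qeq solve.

    ``chi`` per-atom electronegativity (kcal/mol/e), ``J`` per-atom hardness
    (kcal/mol/e²), ``gamma`` per-atom Gaussian width (Å).  Minimizes
    Σ_i (χ_i q_i + ½ J_i q_i²) + Σ_{i<j} k_e q_i q_j erf(r_ij/(√2 γ_ij))/r_ij
    subject to Σ q = total_charge.  ``mode="local"`` drops the off-diagonal
    Coulomb coupling.
    """
    chi = np.asarray(chi, dtype=float)
    n = len(chi)
    species = ["H"] * n  # element labels are irrelevant here
    system = AtomicSystem(species, np.asarray(positions, dtype=float).reshape(n, 3),
                          cell, pbc, int(total_charge))
    with ad.no_grad():
        q = qeq_charges_t(ad.Tensor(chi), ad.Tensor(np.broadcast_to(np.asarray(J, dtype=float), (n,)).copy()),
                          ad.Tensor(np.broadcast_to(np.asarray(gamma, dtype=float), (n,)).copy()),
                          ad.Tensor(system.positions), system, mode=mode)
    return q.numpy()


def coulomb_energy_t(q: ad.Tensor, pos: ad.Tensor, system: AtomicSystem,
                     wolf_alpha: float = 0.2, cutoff: float = 10.0) -> ad.Tensor:
    """Long-range Coulomb energy of point charges.

    Clusters: direct sum k_e Σ_{i<j} q_i q_j / r_ij.  Periodic systems: Wolf
    damped-shifted sum (a documented approximation of the Ewald limit).
    """
    n = system.n_atoms
    if n < 2:
        return ad.Tensor(0.0)
    if not system.pbc:
        iu, ju = np.triu_indices(n, k=1)
        d = ad.add(ad.take(pos, (ju,)), ad.neg(ad.take(pos, (iu,))))
        r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
        if np.any(r.data < 1e-6):
            raise ValueError("coincident charged atoms in Coulomb sum")
        qq = ad.mul(ad.take(q, (iu,)), ad.take(q, (ju,)))
        return ad.mul(KE_COULOMB, ad.tsum(ad.mul(qq, ad.power(r, -1.0))))
    pi, pj, shift = build_pairs(system, cutoff)
    keep = pi < pj
    pi, pj, shift = pi[keep], pj[keep], shift[keep]
    a = wolf_alpha
    self_term = ad.mul(-KE_COULOMB * (_np_erfc(a * cutoff) / (2 * cutoff) + a / np.sqrt(np.pi)),
                       ad.tsum(ad.mul(q, q)))
    if len(pi) == 0:
        return self_term
    d = ad.add(ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,)))), ad.Tensor(shift))
    r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
    if np.any(r.data < 1e-6):
        raise ValueError("coincident charged atoms in Coulomb sum")
    qq = ad.mul(ad.take(q, (pi,)), ad.take(q, (pj,)))
    # erfc via erf (keeps the op set minimal): erfc(x) = 1 - erf(x)
    erfc_r = ad.add(1.0, ad.neg(ad.terf(ad.mul(r, a))))
    pair = ad.add(ad.mul(erfc_r, ad.power(r, -1.0)), -_np_erfc(a * cutoff) / cutoff)
    return ad.add(ad.mul(KE_COULOMB, ad.tsum(ad.mul(qq, pair))), self_term)


def coulomb_energy(q, positions, cell=None, pbc=False, wolf_alpha=0.2,
                   cutoff=10.0) -> float:
    q = np.asarray(q, dtype=float)
    pos = np.asarray(positions, dtype=float)
    system = AtomicSystem(["H"] * len(q), pos, cell, pbc)
    with ad.no_grad():
        e = coulomb_energy_t(ad.Tensor(q), ad.Tensor(pos), system, wolf_alpha, cutoff)
    return e.item()


def smeared_coulomb_energy_t(q: ad.Tensor, pos: ad.Tensor, system: AtomicSystem,
                             gamma_atoms: ad.Tensor, wolf_alpha: float = 0.2,
                             cutoff: float = 10.0) -> ad.Tensor:
    """Electrostatic energy of Gaussian-smeared charges — the same kernel
    the Qeq functional minimizes, k_e erf(r/(√2 γ_ij))/r, finite as r → 0.
    Periodic systems add Wolf damped-shifted screening beyond the smearing
    range."""
    n = system.n_atoms
    if n < 2:
        return ad.Tensor(0.0)
    if system.pbc:
        pi, pj, shift = build_pairs(system, cutoff)
        keep = pi < pj
        pi, pj, shift = pi[keep], pj[keep], shift[keep]
        if len(pi) == 0:
            return ad.Tensor(0.0)
        d = ad.add(ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,)))),
                   ad.Tensor(shift))
    else:
        pi, pj = np.triu_indices(n, k=1)
        d = ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,))))
    r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
    gij = ad.power(ad.add(ad.power(ad.take(gamma_atoms, (pi,)), 2.0),
                          ad.power(ad.take(gamma_atoms, (pj,)), 2.0)), 0.5)
    kern = ad.mul(ad.terf(ad.mul(r, ad.power(ad.mul(gij, np.sqrt(2.0)), -1.0))),
                  ad.power(r, -1.0))
    if system.pbc:
        a = wolf_alpha
        erfc_r = ad.add(1.0, ad.neg(ad.terf(ad.mul(r, a))))
        # smeared minus bare, plus Wolf-screened bare: short-range smearing
        # with damped-shifted long range
        kern = ad.add(ad.add(kern, ad.neg(ad.power(r, -1.0))),
                      ad.add(ad.mul(erfc_r, ad.power(r, -1.0)),
                             -_np_erfc(a * cutoff) / cutoff))
    qq = ad.mul(ad.take(q, (pi,)), ad.take(q, (pj,)))
    return ad.mul(KE_COULOMB, ad.tsum(ad.mul(qq, kern)))


def dispersion_energy_t(pos: ad.Tensor, system: AtomicSystem,
                        params: DispersionParams) -> ad.Tensor:
    """E = -Σ_{i<j} C6_ij/r⁶ · [1 + a (r/R0_ij)^-12]^-1."""
    n = system.n_atoms
    if n < 2:
        return ad.Tensor(0.0)
    if system.pbc:
        pi, pj, shift = build_pairs(system, params.cutoff)
        keep = pi < pj
        pi, pj, shift = pi[keep], pj[keep], shift[keep]
        if len(pi) == 0:
            return ad.Tensor(0.0)
        d = ad.add(ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,)))),
                   ad.Tensor(shift))
    else:
        pi, pj = np.triu_indices(n, k=1)
        d = ad.add(ad.take(pos, (pj,)), ad.neg(ad.take(pos, (pi,))))
    c6 = np.empty(len(pi))
    r0 = np.empty(len(pi))
    for k in range(len(pi)):
        c6[k], r0[k] = params.pair(system.species[pi[k]], system.species[pj[k]])
    r2 = ad.tsum(ad.mul(d, d), axis=1)
    r6 = ad.power(r2, 3.0)
    r12_ratio = ad.mul(ad.power(ad.mul(r2, ad.Tensor(1.0 / r0 ** 2)), -6.0), params.a)
    damp = ad.power(ad.add(1.0, r12_ratio), -1.0)
    return ad.neg(ad.tsum(ad.mul(ad.mul(ad.Tensor(c6), ad.power(r6, -1.0)), damp)))


def dispersion_energy(system: AtomicSystem, params: DispersionParams | None = None) -> float:
    params = params or DispersionParams()
    with ad.no_grad():
        e = dispersion_energy_t(ad.Tensor(system.positions), system, params)
    return e.item()


def dipole_moment(q, positions, masses=None) -> np.ndarray:
    """μ = Σ q_i (r_i - r_com), e·Å, origin at the center of mass."""
    q = np.asarray(q, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if masses is None:
        com = pos.mean(axis=0)
    else:
        m = np.asarray(masses, dtype=float)
        com = m @ pos / m.sum()
    return q @ (pos - com)


def qrnn_forward(pos: ad.Tensor, system: AtomicSystem, params_t: dict,
                 model: QRNNModel) -> dict:
    """Full differentiable QRNN evaluation; returns Tensors."""
    cfg = model.descriptor
    hyper = model.hyper
    elem_idx = cfg.element_index(system.species)
    n = system.n_atoms

    aev, cache = aev_with_cache(pos, system, cfg)
    J_atoms = ad.take(ad.stack([ad.texp(params_t["logJ"][e]) for e in cfg.element_order]),
                      (elem_idx,))
    gamma_atoms = ad.take(ad.stack([ad.texp(params_t["loggamma"][e])
                                    for e in cfg.element_order]), (elem_idx,))

    # iteration 1: plain AEV -> χ -> q(1)
    zeros_cw = ad.Tensor(np.zeros((n, cfg.radial_length)))
    chi1 = _per_atom_net(params_t["chi"], ad.concat([aev, zeros_cw], axis=1),
                         elem_idx, cfg.element_order, hyper.activation_alpha,
                         hyper.chi_scale)
    q = qeq_charges_t(chi1, J_atoms, gamma_atoms, pos, system, hyper.qeq_mode,
                      hyper.wolf_alpha, hyper.coulomb_cutoff)
    q_iters = [q]
    # subsequent iterations: augment features with the charge-weighted AEV
    for _ in range(hyper.qeq_iterations - 1):
        cw = cw_radial_from_cache(cache, q)
        chi = _per_atom_net(params_t["chi"], ad.concat([aev, cw], axis=1),
                            elem_idx, cfg.element_order, hyper.activation_alpha,
                            hyper.chi_scale)
        q = qeq_charges_t(chi, J_atoms, gamma_atoms, pos, system, hyper.qeq_mode,
                          hyper.wolf_alpha, hyper.coulomb_cutoff)
        q_iters.append(q)

    # atomic energies on (AEV, q_i, charge-weighted AEV)
    cw_final = cw_radial_from_cache(cache, q)
    feats = ad.concat([aev, ad.reshape(q, (-1, 1)), cw_final], axis=1)
    atomic_e = _per_atom_net(params_t["energy"], feats, elem_idx,
                             cfg.element_order, hyper.activation_alpha,
                             hyper.energy_scale)
    e0_atoms = ad.take(ad.stack([params_t["e0"][e] for e in cfg.element_order]),
                       (elem_idx,))
    E_short = ad.add(ad.tsum(atomic_e), ad.tsum(e0_atoms))

    if hyper.coulomb_kernel == "smeared":
        E_coul = smeared_coulomb_energy_t(q, pos, system, gamma_atoms,
                                          hyper.wolf_alpha, hyper.coulomb_cutoff)
    else:
        E_coul = coulomb_energy_t(q, pos, system, hyper.wolf_alpha,
                                  hyper.coulomb_cutoff)
    E_disp = dispersion_energy_t(pos, system, model.dispersion)
    E_total = ad.add(ad.add(E_short, E_coul), E_disp)

    m = system.masses
    com = m @ system.positions / m.sum()
    rel = ad.add(pos, ad.Tensor(-com[None, :]))
    dipole = ad.matmul(q, rel)

    return {"E_short": E_short, "E_coulomb": E_coul, "E_dispersion": E_disp,
            "E_total": E_total, "charges": q, "charges_iter1": q_iters[0],
            "dipole": dipole}


def recursive_charges(system: AtomicSystem, model: QRNNModel,
                      iterations: int | None = None):
    """Charges from each Qeq iteration (default two, the QRNN recursion).

    Returns a list ``[q_iter1, q_iter2, ...]``.
    """
    iters = iterations if iterations is not None else model.hyper.qeq_iterations
    if iters < 1:
        raise ValueError("iterations must be >= 1")
    saved = model.hyper.qeq_iterations
    model.hyper.qeq_iterations = iters
    try:
        with ad.no_grad():
            out = qrnn_forward(ad.Tensor(system.positions), system,
                               QRNNModel.params_t(model.params), model)
    finally:
        model.hyper.qeq_iterations = saved
    if iters == 1:
        return [out["charges"].numpy()]
    return [out["charges_iter1"].numpy(), out["charges"].numpy()]


def total_energy_and_forces(system: AtomicSystem, model: QRNNModel) -> EnergyBreakdown:
    """Energy breakdown with analytic forces (negative exact gradient)."""
    return model.evaluate(system, forces=True)
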