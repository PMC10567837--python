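"""Batched QRNN evaluation over many (non-periodic) cluster geometries.

Training and committee scoring evaluate thousands of small clusters; doing
so one graph per cluster is dominated by per-op overhead.  This module
concatenates a batch of clusters into flat atom/pair/triple index arrays
(built once per batch, since the geometries are fixed) and runs a single
differentiable forward pass.  Charge equilibration becomes one
block-diagonal linear system with one charge-conservation constraint per
cluster, so no charge flows between samples.

The result is numerically identical to evaluating each system with
:func:`polyff.model.qrnn_forward`; a regression test asserts the agreement.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .descriptors import DescriptorConfig, _cutoff_fn
from .model import QRNNModel
from .system import AtomicSystem
from .units import KE_COULOMB


class SystemBatch:
    """Precomputed index structure for a list of cluster geometries."""

    def __init__(self, systems: list[AtomicSystem], model: QRNNModel):
        if any(s.pbc for s in systems):
            raise ValueError("batched evaluation supports clusters only")
        cfg = model.descriptor
        self.config = cfg
        self.model = model
        self.systems = systems
        self.B = len(systems)
        counts = np.array([s.n_atoms for s in systems])
        self.n_atoms = counts
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self.offsets = offsets
        self.N = int(offsets[-1])
        self.sample_id = np.repeat(np.arange(self.B), counts)
        self.positions0 = np.vstack([s.positions for s in systems])
        self.species = [sp for s in systems for sp in s.species]
        self.elem_idx = cfg.element_index(self.species)
        self.total_charges = np.array([float(s.total_charge) for s in systems])
        masses = np.concatenate([s.masses for s in systems])
        self.masses = masses
        self.com_per_atom = np.vstack([
            np.repeat(s.center_of_mass()[None, :], s.n_atoms, axis=0)
            for s in systems])

        # directed radial pairs within each sample
        pi_all, pj_all = [], []
        for b, s in enumerate(systems):
            n = s.n_atoms
            if n < 2:
                continue
            d = s.positions[None, :, :] - s.positions[:, None, :]
            r = np.linalg.norm(d, axis=-1)
            np.fill_diagonal(r, np.inf)
            ii, jj = np.nonzero(r < cfg.radial_cutoff)
            if np.any(r[ii, jj] < 1e-6):
                k = np.argmin(r[ii, jj])
                raise ValueError(f"atoms {ii[k]} and {jj[k]} of sample {b} overlap")
            pi_all.append(ii + offsets[b])
            pj_all.append(jj + offsets[b])
        self.pi = np.concatenate(pi_all) if pi_all else np.zeros(0, dtype=int)
        self.pj = np.concatenate(pj_all) if pj_all else np.zeros(0, dtype=int)
        self.rows = self.pi * cfg.n_elements + self.elem_idx[self.pj]

        # angular triples (pair-list indices) for pairs inside angular cutoff
        r0 = np.linalg.norm(self.positions0[self.pj] - self.positions0[self.pi], axis=1)
        ang = np.nonzero(r0 < cfg.angular_cutoff)[0]
        t_center, t_a, t_b = [], [], []
        order = np.argsort(self.pi[ang], kind="stable")
        ang_sorted = ang[order]
        centers = self.pi[ang_sorted]
        bounds = np.searchsorted(centers, np.arange(self.N + 1))
        blk = cfg.pair_block()
        for i in range(self.N):
            lo, hi = bounds[i], bounds[i + 1]
            if hi - lo < 2:
                continue
            members = ang_sorted[lo:hi]
            a, b = np.triu_indices(len(members), k=1)
            t_center.append(np.full(len(a), i))
            t_a.append(members[a])
            t_b.append(members[b])
        if t_center:
            self.t_center = np.concatenate(t_center)
            self.t_a = np.concatenate(t_a)
            self.t_b = np.concatenate(t_b)
            self.ang_rows = (self.t_center * cfg.n_element_pairs
                             + blk[self.elem_idx[self.pj[self.t_a]],
                                   self.elem_idx[self.pj[self.t_b]]])
        else:
            self.t_center = self.t_a = self.t_b = np.zeros(0, dtype=int)
            self.ang_rows = np.zeros(0, dtype=int)

        # undirected within-sample pairs for Qeq / Coulomb / dispersion
        qi, qj = [], []
        for b, s in enumerate(systems):
            n = s.n_atoms
            if n < 2:
                continue
            ii, jj = np.triu_indices(n, k=1)
            qi.append(ii + offsets[b])
            qj.append(jj + offsets[b])
        self.qi = np.concatenate(qi) if qi else np.zeros(0, dtype=int)
        self.qj = np.concatenate(qj) if qj else np.zeros(0, dtype=int)
        self.pair_sample = self.sample_id[self.qi] if len(self.qi) else np.zeros(0, dtype=int)

        # padded batched Qeq layout: one (n_b+1)-system per sample, stacked
        # into (B, m, m) with identity padding rows
        self.local_index = np.concatenate([np.arange(c) for c in counts]).astype(int)
        self.qeq_m = int(counts.max()) + 1
        m = self.qeq_m
        const = np.zeros((self.B, m, m))
        for b, n in enumerate(counts):
            const[b, n, :n] = 1.0       # constraint row Σq = Q
            const[b, :n, n] = 1.0       # Lagrange-multiplier column
            for k in range(n + 1, m):
                const[b, k, k] = 1.0    # padding
        self.qeq_const = const
        self.qeq_rhs_const = np.zeros((self.B, m))
        for b, n in enumerate(counts):
            self.qeq_rhs_const[b, n] = self.total_charges[b]

        disp = model.dispersion
        self.c6 = np.array([disp.pair(self.species[i], self.species[j])[0]
                            for i, j in zip(self.qi, self.qj)])
        self.r0_disp = np.array([disp.pair(self.species[i], self.species[j])[1]
                                 for i, j in zip(self.qi, self.qj)])

    # -- forward ------------------------------------------------------------
    def _aev(self, pos: ad.Tensor):
        cfg = self.config
        n_rs = len(cfg.radial_shifts)
        if len(self.pi) == 0:
            aev = ad.Tensor(np.zeros((self.N, cfg.length)))
            return aev, None
        disp = ad.add(ad.take(pos, (self.pj,)), ad.neg(ad.take(pos, (self.pi,))))
        r = ad.power(ad.tsum(ad.mul(disp, disp), axis=1), 0.5)
        mu = np.asarray(cfg.radial_shifts)
        gauss = ad.texp(ad.mul(-cfg.radial_eta,
                               ad.power(ad.add(ad.reshape(r, (-1, 1)),
                                               ad.Tensor(-mu[None, :])), 2.0)))
        fc = ad.reshape(_cutoff_fn(r, cfg.radial_cutoff), (-1, 1))
        radial_contrib = ad.mul(gauss, fc)
        radial = ad.reshape(ad.scatter((self.N * cfg.n_elements, n_rs),
                                       (self.rows,), radial_contrib),
                            (self.N, cfg.radial_length))
        angular = self._angular(pos)
        return ad.concat([radial, angular], axis=1), radial_contrib

    def _angular(self, pos: ad.Tensor):
        cfg = self.config
        if len(self.t_center) == 0:
            return ad.Tensor(np.zeros((self.N, cfg.angular_length)))
        n_as, n_sec = len(cfg.angular_shifts), len(cfg.angular_sections)
        dj = ad.add(ad.take(pos, (self.pj[self.t_a],)),
                    ad.neg(ad.take(pos, (self.t_center,))))
        dk = ad.add(ad.take(pos, (self.pj[self.t_b],)),
                    ad.neg(ad.take(pos, (self.t_center,))))
        rj = ad.power(ad.tsum(ad.mul(dj, dj), axis=1), 0.5)
        rk = ad.power(ad.tsum(ad.mul(dk, dk), axis=1), 0.5)
        cosq = ad.mul(ad.tsum(ad.mul(dj, dk), axis=1), ad.power(ad.mul(rj, rk), -1.0))
        theta = ad.tarccos(ad.mul(cosq, 0.95))
        sections = np.asarray(cfg.angular_sections)
        angf = ad.mul(ad.power(ad.mul(ad.add(ad.tcos(ad.add(ad.reshape(theta, (-1, 1)),
                                                            ad.Tensor(-sections[None, :]))),
                                             1.0), 0.5), cfg.zeta), 2.0)
        ravg = ad.mul(ad.add(rj, rk), 0.5)
        mu_a = np.asarray(cfg.angular_shifts)
        rad = ad.texp(ad.mul(-cfg.angular_eta,
                             ad.power(ad.add(ad.reshape(ravg, (-1, 1)),
                                             ad.Tensor(-mu_a[None, :])), 2.0)))
        fc = ad.mul(_cutoff_fn(rj, cfg.angular_cutoff), _cutoff_fn(rk, cfg.angular_cutoff))
        contrib = ad.mul(ad.mul(ad.reshape(rad, (-1, n_as, 1)),
                                ad.reshape(angf, (-1, 1, n_sec))),
                         ad.reshape(fc, (-1, 1, 1)))
        contrib = ad.reshape(contrib, (-1, n_as * n_sec))
        flat = ad.scatter((self.N * cfg.n_element_pairs, n_as * n_sec),
                          (self.ang_rows,), contrib)
        return ad.reshape(flat, (self.N, cfg.angular_length))

    def _cw(self, radial_contrib, charges: ad.Tensor):
        cfg = self.config
        if radial_contrib is None:
            return ad.Tensor(np.zeros((self.N, cfg.radial_length)))
        qj = ad.reshape(ad.take(charges, (self.pj,)), (-1, 1))
        flat = ad.scatter((self.N * cfg.n_elements, len(cfg.radial_shifts)),
                          (self.rows,), ad.mul(radial_contrib, qj))
        return ad.reshape(flat, (self.N, cfg.radial_length))

    def _per_atom_net(self, nets_t, feats, scale: float = 1.0):
        cfg = self.config
        alpha = self.model.hyper.activation_alpha
        total = ad.Tensor(np.zeros(self.N))
        for ei, e in enumerate(cfg.element_order):
            atoms = np.nonzero(self.elem_idx == ei)[0]
            if len(atoms) == 0:
                continue
            from .model import _mlp_forward
            out = _mlp_forward(nets_t[e], ad.take(feats, (atoms,)), alpha)
            total = ad.add(total, ad.scatter((self.N,), (atoms,),
                                             ad.reshape(out, (-1,))))
        return total if scale == 1.0 else ad.mul(total, scale)

    def _qeq(self, chi, J_atoms, gamma_atoms, pair_kern):
        """Padded batched Qeq: one (n_b+1) constrained system per sample,
        solved as a single stacked linear solve."""
        m = self.qeq_m
        sid, la = self.sample_id, self.local_index
        var = ad.scatter((self.B, m, m), (sid, la, la), J_atoms)
        if pair_kern is not None and self.model.hyper.qeq_mode != "local":
            li, lj = la[self.qi], la[self.qj]
            ps = self.pair_sample
            var = ad.add(var, ad.scatter((self.B, m, m), (ps, li, lj), pair_kern))
            var = ad.add(var, ad.scatter((self.B, m, m), (ps, lj, li), pair_kern))
        M = ad.add(var, ad.Tensor(self.qeq_const))
        rhs = ad.add(ad.scatter((self.B, m), (sid, la), ad.neg(chi)),
                     ad.Tensor(self.qeq_rhs_const))
        sol = ad.solve_batched(M, rhs)
        return ad.take(sol, (sid, la))

    def forward(self, params_t, need_forces: bool = False,
                create_graph: bool = False, positions: ad.Tensor | None = None):
        """Batched QRNN forward pass.

        Returns a dict of Tensors: per-sample energies ``E`` (B,), per-atom
        ``charges`` (N,), per-sample ``dipoles`` (B, 3), and (optionally)
        per-atom ``forces`` (N, 3).
        """
        model = self.model
        cfg = self.config
        pos = positions if positions is not None else ad.Tensor(
            self.positions0, requires_grad=need_forces)

        aev, radial_contrib = self._aev(pos)
        J_atoms = ad.take(ad.stack([ad.texp(params_t["logJ"][e])
                                    for e in cfg.element_order]), (self.elem_idx,))
        gamma_atoms = ad.take(ad.stack([ad.texp(params_t["loggamma"][e])
                                        for e in cfg.element_order]), (self.elem_idx,))
        # pairwise smeared kernel, shared by both Qeq iterations
        pair_kern = None
        rinv = None
        if len(self.qi) and model.hyper.qeq_mode != "local":
            d = ad.add(ad.take(pos, (self.qj,)), ad.neg(ad.take(pos, (self.qi,))))
            r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
            rinv = ad.power(r, -1.0)
            gij = ad.power(ad.add(ad.power(ad.take(gamma_atoms, (self.qi,)), 2.0),
                                  ad.power(ad.take(gamma_atoms, (self.qj,)), 2.0)), 0.5)
            pair_kern = ad.mul(KE_COULOMB,
                               ad.mul(ad.terf(ad.mul(r, ad.power(ad.mul(gij, np.sqrt(2.0)), -1.0))),
                                      rinv))
        elif len(self.qi):
            d = ad.add(ad.take(pos, (self.qj,)), ad.neg(ad.take(pos, (self.qi,))))
            r = ad.power(ad.tsum(ad.mul(d, d), axis=1), 0.5)
            rinv = ad.power(r, -1.0)

        zeros_cw = ad.Tensor(np.zeros((self.N, cfg.radial_length)))
        chi1 = self._per_atom_net(params_t["chi"], ad.concat([aev, zeros_cw], axis=1),
                                  model.hyper.chi_scale)
        q = self._qeq(chi1, J_atoms, gamma_atoms, pair_kern)
        q1 = q
        for _ in range(model.hyper.qeq_iterations - 1):
            cw = self._cw(radial_contrib, q)
            chi = self._per_atom_net(params_t["chi"], ad.concat([aev, cw], axis=1),
                                     model.hyper.chi_scale)
            q = self._qeq(chi, J_atoms, gamma_atoms, pair_kern)

        cw_final = self._cw(radial_contrib, q)
        feats = ad.concat([aev, ad.reshape(q, (-1, 1)), cw_final], axis=1)
        atomic_e = self._per_atom_net(params_t["energy"], feats,
                                      model.hyper.energy_scale)
        e0_atoms = ad.take(ad.stack([params_t["e0"][e] for e in cfg.element_order]),
                           (self.elem_idx,))
        E = ad.scatter((self.B,), (self.sample_id,), ad.add(atomic_e, e0_atoms))

        if len(self.qi):
            qq = ad.mul(ad.take(q, (self.qi,)), ad.take(q, (self.qj,)))
            if model.hyper.coulomb_kernel == "smeared" and pair_kern is not None:
                e_pairs = ad.mul(qq, pair_kern)
            else:
                e_pairs = ad.mul(KE_COULOMB, ad.mul(qq, rinv))
            E = ad.add(E, ad.scatter((self.B,), (self.pair_sample,), e_pairs))
            r2 = ad.power(rinv, -2.0)
            r6inv = ad.power(r2, -3.0)
            damp = ad.power(ad.add(1.0, ad.mul(model.dispersion.a,
                                               ad.power(ad.mul(r2, ad.Tensor(1.0 / self.r0_disp ** 2)),
                                                        -6.0))), -1.0)
            e_disp = ad.neg(ad.mul(ad.mul(ad.Tensor(self.c6), r6inv), damp))
            E = ad.add(E, ad.scatter((self.B,), (self.pair_sample,), e_disp))

        rel = ad.add(pos, ad.Tensor(-self.com_per_atom))
        dipoles = ad.scatter((self.B, 3), (self.sample_id,),
                             ad.mul(ad.reshape(q, (-1, 1)), rel))

        out = {"E": E, "charges": q, "charges_iter1": q1, "dipoles": dipoles}
        if need_forces:
            g = ad.grad(ad.tsum(E), pos, create_graph=create_graph)
            out["forces"] = ad.neg(g) if create_graph else ad.Tensor(-g.data)
        return out

    def split_forces(self, forces: np.ndarray) -> list[np.ndarray]:
        return [forces[self.offsets[b]:self.offsets[b + 1]] for b in range(self.B)]
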