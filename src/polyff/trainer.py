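"""Multitask training of the QRNN potential.

The loss combines energy, force and charge-label tasks with trainable
homoscedastic task uncertainties:

    L = L_E/(2σ_E²) + L_g/(2σ_g²) + L_q/(2σ_q²) + log(σ_E σ_g σ_q)

with σ stored as log σ for positivity.  The charge task is either the
squared dipole-moment error or the squared per-atom reference-charge error
(``charge_label_mode``).  Optimization is Adam with decoupled weight decay
on the weight-normalized network parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import autodiff as ad
from .batch import SystemBatch
from .model import QRNNModel
from .system import Dataset

DIPOLE = "dipole"
ATOMIC_CHARGES = "atomic_charges"


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the reference protocol (α = 1e-3, weight decay 1e-4,
    batches 256/1024, 500 epochs of 200,000 samples); use
    :meth:`desk_scale` for test-sized runs.
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_train: int = 256
    batch_val: int = 1024
    epochs: int = 500
    epoch_size: int = 200_000
    charge_label_mode: str = DIPOLE
    split: tuple = (0.9, 0.1)
    seed: int = 0
    use_forces: bool = True
    grad_clip: float = 10.0   # global gradient-norm ceiling; 0 disables
    eval_interval: int = 1    # validation metrics every k epochs

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.learning_rate, self.batch_train, self.batch_val) <= 0:
            raise ValueError("hyperparameters must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Reduced problem sizes for interactive runs and tests; the energy
        and charge tasks carry the training signal at this scale."""
        base = cls(epochs=50, epoch_size=2000, batch_train=32, batch_val=256,
                   use_forces=False)
        return replace(base, **overrides)


def combine_task_losses(L_E, L_g, L_q, log_sigmas) -> ad.Tensor:
    """The multitask objective; ``log_sigmas`` is a length-3 tensor
    (energy, gradient, charge)."""
    ls = ad.astensor(log_sigmas)
    inv = ad.texp(ad.mul(ls, -2.0))
    terms = ad.stack([ad.astensor(L_E), ad.astensor(L_g), ad.astensor(L_q)])
    return ad.add(ad.mul(0.5, ad.tsum(ad.mul(terms, inv))), ad.tsum(ls))


def multitask_loss(predictions: dict, labels: dict, log_sigmas) -> float:
    """Numpy-facing evaluation of the multitask loss.

    ``predictions``/``labels`` carry ``energy`` (per-sample arrays),
    optionally ``forces`` (stacked (N,3)), and one of ``dipole``/``charges``.
    ``n_atoms`` in labels supplies per-sample atom counts for the energy
    normalization.
    """
    for task in ("energy",):
        if task not in labels:
            raise ValueError(f"missing labels for task: {task}")
    n_atoms = np.asarray(labels.get("n_atoms", np.ones_like(np.asarray(labels["energy"]))))
    dE = (np.asarray(predictions["energy"]) - np.asarray(labels["energy"])) / n_atoms
    L_E = float(np.mean(dE ** 2))
    if "forces" in predictions:
        if "forces" not in labels:
            raise ValueError("missing labels for task: forces")
        L_g = float(np.mean((np.asarray(predictions["forces"])
                             - np.asarray(labels["forces"])) ** 2))
    else:
        L_g = 0.0
    if "charges" in predictions:
        if "charges" not in labels:
            raise ValueError("missing labels for task: charges")
        L_q = float(np.mean((np.asarray(predictions["charges"])
                             - np.asarray(labels["charges"])) ** 2))
    elif "dipole" in predictions:
        if "dipole" not in labels:
            raise ValueError("missing labels for task: dipole")
        L_q = float(np.mean((np.asarray(predictions["dipole"])
                             - np.asarray(labels["dipole"])) ** 2))
    else:
        L_q = 0.0
    return combine_task_losses(L_E, L_g, L_q, ad.Tensor(np.asarray(log_sigmas))).item()


def split_dataset(dataset: Dataset, fractions=(0.9, 0.1), seed: int = 0) -> np.ndarray:
    """Random, seed-reproducible train/val assignment (disjoint, exhaustive).

    The target-model convention is a 90-10 split; committee members use
    60-40 to increase inter-member variation.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    assignment = np.array(["val"] * n, dtype=object)
    assignment[perm[:n_train]] = "train"
    dataset.split_assignment = assignment
    return assignment


@dataclass
class EvaluationReport:
    energy_mae: float
    energy_rmse: float
    energy_mae_per_atom: float
    force_mae: float
    charge_mae: Optional[float]
    dipole_mae: Optional[float]
    epsilon: np.ndarray          # per-sample |E_ref - E_model|
    energy_ref: np.ndarray
    energy_pred: np.ndarray


def evaluate_model(model: QRNNModel, dataset: Dataset,
                   batch_size: int = 256, forces: bool = True) -> EvaluationReport:
    """Deterministic evaluation: per-sample energy errors and summary MAEs."""
    e_ref, e_pred, n_atoms = [], [], []
    f_err_sum, f_count = 0.0, 0
    q_err_sum, q_count = 0.0, 0
    d_err_sum, d_count = 0.0, 0
    pt = QRNNModel.params_t(model.params)
    for lo in range(0, len(dataset), batch_size):
        chunk = dataset.samples[lo:lo + batch_size]
        sb = SystemBatch([s.system for s in chunk], model)
        # note: no_grad would suppress the force gradient entirely
        out = sb.forward(pt, need_forces=forces)
        e_pred.extend(out["E"].numpy())
        e_ref.extend(s.energy for s in chunk)
        n_atoms.extend(s.system.n_atoms for s in chunk)
        if forces:
            f_all = out["forces"].numpy()
            f_ref = np.vstack([s.forces for s in chunk])
            f_err_sum += np.abs(f_all - f_ref).sum()
            f_count += f_ref.size
        qs = out["charges"].numpy()
        off = 0
        for s in chunk:
            n = s.system.n_atoms
            if s.ref_charges is not None:
                q_err_sum += np.abs(qs[off:off + n] - s.ref_charges).sum()
                q_count += n
            off += n
        dp = out["dipoles"].numpy()
        for b, s in enumerate(chunk):
            if s.dipole is not None:
                d_err_sum += np.abs(dp[b] - s.dipole).sum()
                d_count += 3
    e_ref = np.asarray(e_ref)
    e_pred = np.asarray(e_pred)
    n_atoms = np.asarray(n_atoms, dtype=float)
    eps = np.abs(e_ref - e_pred)
    return EvaluationReport(
        energy_mae=float(eps.mean()),
        energy_rmse=float(np.sqrt((eps ** 2).mean())),
        energy_mae_per_atom=float((eps / n_atoms).mean()),
        force_mae=float(f_err_sum / f_count) if f_count else float("nan"),
        charge_mae=float(q_err_sum / q_count) if q_count else None,
        dipole_mae=float(d_err_sum / d_count) if d_count else None,
        epsilon=eps, energy_ref=e_ref, energy_pred=e_pred)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


def _flatten_params(node, path=(), out=None):
    if out is None:
        out = []
    if isinstance(node, dict):
        for k in sorted(node):
            _flatten_params(node[k], path + (k,), out)
    elif isinstance(node, list):
        for i, v in enumerate(node):
            _flatten_params(v, path + (i,), out)
    else:
        out.append((path, node))
    return out


def train_model(dataset: Dataset, config: TrainConfig,
                model: QRNNModel | None = None,
                descriptor=None, hyper=None,
                log_fn=None) -> tuple[QRNNModel, list[dict]]:
    """Minibatch optimization of the multitask loss.

    Passing an existing ``model`` warm-starts from its parameters (transfer
    learning); otherwise a fresh model is initialized from ``config.seed``.
    Returns the trained model and a per-epoch history of losses, validation
    MAEs and σ values.  Aborts on divergence (non-finite loss).
    """
    rng = np.random.default_rng(config.seed)
    fresh = model is None
    if fresh:
        model = QRNNModel(descriptor=descriptor, hyper=hyper, seed=config.seed)
    else:
        model = model.copy()
    mode = config.charge_label_mode
    for s in dataset.samples:
        if mode == ATOMIC_CHARGES and s.ref_charges is None:
            raise ValueError("charge_label_mode=atomic_charges requires ref_charges labels")
        if mode == DIPOLE and s.dipole is None:
            raise ValueError("charge_label_mode=dipole requires dipole labels")

    if dataset.split_assignment is None:
        split_dataset(dataset, config.split, config.seed)
    train_idx = np.nonzero(dataset.split_assignment == "train")[0]
    val = dataset.subset("val")

    if fresh:
        # seed per-element energy offsets by least squares on composition
        # (standard practice; removes the large constant part of the target)
        counts = np.zeros((len(train_idx), len(model.descriptor.element_order)))
        energies = np.zeros(len(train_idx))
        for r, i in enumerate(train_idx):
            s = dataset.samples[i]
            for k, e in enumerate(model.descriptor.element_order):
                counts[r, k] = s.system.species.count(e)
            energies[r] = s.energy
        e0, *_ = np.linalg.lstsq(counts, energies, rcond=None)
        for k, e in enumerate(model.descriptor.element_order):
            model.params["e0"][e] = model.params["e0"][e] + e0[k]

    log_sigmas = np.zeros(3)  # σ = 1 at start
    flat = _flatten_params(model.params)
    decay_mask = [1.0 if (p[0] in ("chi", "energy") and p[-1] in ("v", "g")) else 0.0
                  for p, _ in flat]
    shapes = [np.shape(a) for _, a in flat] + [(3,)]
    adam = _Adam(shapes, config.learning_rate)

    history: list[dict] = []

    def epoch_metrics(epoch, train_loss):
        rep = evaluate_model(model, val, batch_size=config.batch_val, forces=False)
        rec = {"epoch": epoch, "train_loss": train_loss,
               "val_energy_mae": rep.energy_mae,
               "val_energy_mae_per_atom": rep.energy_mae_per_atom,
               "sigma_E": float(np.exp(log_sigmas[0])),
               "sigma_g": float(np.exp(log_sigmas[1])),
               "sigma_q": float(np.exp(log_sigmas[2]))}
        history.append(rec)
        if log_fn:
            log_fn(" ".join(f"{k}={v}" for k, v in rec.items()))
        return rec

    epoch_metrics(0, float("nan"))
    if config.epochs == 0:
        return model, history

    for epoch in range(1, config.epochs + 1):
        order = train_idx[rng.permutation(len(train_idx))]
        need = min(config.epoch_size, max(len(order), 1))
        reps = int(np.ceil(need / len(order)))
        order = np.tile(order, reps)[:need]
        losses = []
        for lo in range(0, len(order), config.batch_train):
            batch_idx = order[lo:lo + config.batch_train]
            batch = [dataset.samples[i] for i in batch_idx]
            loss_val = _train_step(model, batch, config, adam, flat, decay_mask,
                                   log_sigmas)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"training diverged (loss={loss_val}) at epoch {epoch}; "
                    "reduce the learning rate or check labels")
            losses.append(loss_val)
            flat = _flatten_params(model.params)
        if epoch % config.eval_interval == 0 or epoch == config.epochs:
            epoch_metrics(epoch, float(np.mean(losses)))
    return model, history


def _train_step(model, batch, config, adam, flat, decay_mask, log_sigmas):
    sb = SystemBatch([s.system for s in batch], model)
    params_t = QRNNModel.params_t(model.params, requires_grad=True)
    ls_t = ad.Tensor(log_sigmas, requires_grad=True)
    use_forces = config.use_forces and all(s.forces is not None for s in batch)

    out = sb.forward(params_t, need_forces=use_forces, create_graph=True)
    n_atoms = ad.Tensor(sb.n_atoms.astype(float))
    e_ref = ad.Tensor(np.array([s.energy for s in batch]))
    dE = ad.mul(ad.add(out["E"], ad.neg(e_ref)), ad.power(n_atoms, -1.0))
    L_E = ad.mul(ad.tsum(ad.mul(dE, dE)), 1.0 / len(batch))

    if use_forces:
        f_ref = ad.Tensor(np.vstack([s.forces for s in batch]))
        dF = ad.add(out["forces"], ad.neg(f_ref))
        L_g = ad.mul(ad.tsum(ad.mul(dF, dF)), 1.0 / (3 * sb.N))
    else:
        L_g = ad.Tensor(0.0)

    if config.charge_label_mode == ATOMIC_CHARGES:
        q_ref = ad.Tensor(np.concatenate([s.ref_charges for s in batch]))
        dq = ad.add(out["charges"], ad.neg(q_ref))
        L_q = ad.mul(ad.tsum(ad.mul(dq, dq)), 1.0 / sb.N)
    else:
        d_ref = ad.Tensor(np.vstack([s.dipole for s in batch]))
        dd = ad.add(out["dipoles"], ad.neg(d_ref))
        L_q = ad.mul(ad.tsum(ad.mul(dd, dd)), 1.0 / (3 * len(batch)))

    if use_forces:
        loss = combine_task_losses(L_E, L_g, L_q, ls_t)
    else:
        # force task inactive: σ_g stays frozen at its current value
        loss = ad.add(
            ad.add(ad.mul(0.5, ad.add(ad.mul(L_E, ad.texp(ad.mul(ls_t[0], -2.0))),
                                      ad.mul(L_q, ad.texp(ad.mul(ls_t[2], -2.0))))),
                   ls_t[0]),
            ls_t[2])

    leaves = [t for _, t in _flatten_params(params_t)]
    grads = ad.grad(loss, leaves + [ls_t])
    gvals = [g.numpy() for g in grads[:-1]]
    if config.grad_clip:
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in gvals)
                        + float((grads[-1].numpy() ** 2).sum()))
        if gnorm > config.grad_clip:
            scale = config.grad_clip / gnorm
            gvals = [g * scale for g in gvals]
            grads[-1] = ad.Tensor(grads[-1].numpy() * scale)
    pvals = [a for _, a in flat]
    # decoupled weight decay on the (unnormalized) network parameters
    new_vals = adam.step(pvals + [log_sigmas], gvals + [grads[-1].numpy()])
    for k, m in enumerate(decay_mask):
        if m:
            new_vals[k] = new_vals[k] - config.learning_rate * config.weight_decay * pvals[k]
    model.set_flat_params(new_vals[:-1])
    log_sigmas[:] = new_vals[-1]
    return loss.item()
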