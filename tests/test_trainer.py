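"""Multitask loss, dataset splits, evaluation reports, and optimization."""

import numpy as np
import pytest

from polyff import autodiff as ad
from polyff.descriptors import DescriptorConfig
from polyff.model import QRNNHyper, QRNNModel
from polyff.system import Dataset
from polyff.trainer import (ATOMIC_CHARGES, DIPOLE, TrainConfig,
                            combine_task_losses, evaluate_model,
                            multitask_loss, split_dataset, train_model)


class TestMultitaskLoss:
    def test_all_zero_losses_unit_sigmas(self):
        assert combine_task_losses(0.0, 0.0, 0.0, np.zeros(3)).item() == 0.0

    def test_direct_substitution(self):
        # L_E=2, others 0, all σ=1 → 2/(2·1) + log 1 = 1
        assert abs(combine_task_losses(2.0, 0.0, 0.0, np.zeros(3)).item() - 1.0) < 1e-12

    def test_stationary_sigma(self):
        """∂L/∂σ_E = 0 at σ_E = √L_E (numeric gradient oracle)."""
        L_E = 1.0
        h = 1e-6

        def L(ls):
            return combine_task_losses(L_E, 0.5, 0.3, np.array([ls, 0.0, 0.0])).item()

        # at log σ_E = 0.5·log L_E = 0 the energy term is stationary
        num = (L(h) - L(-h)) / (2 * h)
        assert abs(num) < 1e-6

    def test_sigma_to_infinity_recovers_energy_only(self):
        big = 50.0
        val = combine_task_losses(3.0, 100.0, 100.0, np.array([0.0, big, big])).item()
        assert abs((val - 2 * big) - 1.5) < 1e-8  # L_E/2 + log penalties

    def test_missing_task_labels_named(self):
        with pytest.raises(ValueError, match="forces"):
            multitask_loss({"energy": [1.0], "forces": np.zeros((2, 3))},
                           {"energy": [1.0]}, np.zeros(3))
        with pytest.raises(ValueError, match="dipole"):
            multitask_loss({"energy": [1.0], "dipole": np.zeros(3)},
                           {"energy": [1.0]}, np.zeros(3))

    def test_numpy_entry_point_matches_combination(self):
        preds = {"energy": np.array([2.0, 0.0]), "charges": np.array([0.1, -0.1])}
        labels = {"energy": np.array([0.0, 0.0]), "charges": np.array([0.0, 0.0]),
                  "n_atoms": np.array([1.0, 1.0])}
        got = multitask_loss(preds, labels, np.zeros(3))
        expect = combine_task_losses(2.0, 0.0, 0.01, np.zeros(3)).item()
        assert abs(got - expect) < 1e-12


class TestSplitDataset:
    def test_target_model_default_ninety_ten(self, tiny_dataset):
        a = split_dataset(tiny_dataset, (0.9, 0.1), seed=0)
        n = len(tiny_dataset)
        assert (a == "train").sum() == round(0.9 * n)
        assert (a == "val").sum() == n - round(0.9 * n)

    def test_committee_sixty_forty(self, tiny_dataset):
        a = split_dataset(tiny_dataset, (0.6, 0.4), seed=1)
        assert abs((a == "train").sum() - 0.6 * len(tiny_dataset)) <= 1

    def test_same_seed_identical(self, tiny_dataset):
        a = split_dataset(tiny_dataset, (0.8, 0.2), seed=7)
        b = split_dataset(tiny_dataset, (0.8, 0.2), seed=7)
        assert np.array_equal(a, b)

    def test_different_seed_differs(self, tiny_dataset):
        a = split_dataset(tiny_dataset, (0.5, 0.5), seed=1).copy()
        b = split_dataset(tiny_dataset, (0.5, 0.5), seed=2)
        assert not np.array_equal(a, b)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            split_dataset(Dataset([]), (0.9, 0.1), seed=0)


class TestEvaluateModel:
    def test_report_lengths(self, desk_model, tiny_dataset):
        rep = evaluate_model(desk_model, tiny_dataset, forces=False)
        assert len(rep.epsilon) == len(tiny_dataset)
        assert len(rep.energy_ref) == len(rep.energy_pred) == len(tiny_dataset)

    def test_constant_predictor_mae_by_brute_force(self, desk_model, tiny_dataset):
        rep = evaluate_model(desk_model, tiny_dataset, forces=False)
        refs = np.array([s.energy for s in tiny_dataset.samples])
        assert abs(rep.energy_mae - np.abs(refs - rep.energy_pred).mean()) < 1e-10

    def test_identity_predictor_gives_zero_mae(self, desk_model, tiny_dataset):
        """Relabeling a dataset with the model's own predictions drives
        every error metric to zero."""
        from polyff.system import LabeledSample
        relabeled = []
        for s in tiny_dataset.samples[:8]:
            out = desk_model.evaluate(s.system, forces=True)
            relabeled.append(LabeledSample(s.system, out.E_total, out.forces,
                                           out.dipole, out.charges))
        rep = evaluate_model(desk_model, Dataset(relabeled))
        assert rep.energy_mae < 1e-10
        assert rep.force_mae < 1e-9
        assert rep.charge_mae < 1e-12
        assert rep.dipole_mae < 1e-12


class TestTrainModel:
    def test_zero_epochs_is_noop(self, tiny_dataset):
        cfg = TrainConfig.desk_scale(epochs=0, charge_label_mode=ATOMIC_CHARGES)
        m0 = QRNNModel(DescriptorConfig.desk_scale(),
                       QRNNHyper(chi_hidden=(8,), energy_hidden=(8,)), seed=cfg.seed)
        trained, hist = train_model(tiny_dataset, cfg, model=m0)
        assert trained.parameter_hash() == m0.parameter_hash()
        assert len(hist) == 1

    def test_seed_reproducible(self, tiny_dataset):
        cfg = TrainConfig.desk_scale(epochs=2, epoch_size=16, batch_train=8,
                                     charge_label_mode=ATOMIC_CHARGES, seed=5)
        kw = dict(descriptor=DescriptorConfig.desk_scale(),
                  hyper=QRNNHyper(chi_hidden=(8,), energy_hidden=(8,)))
        m1, h1 = train_model(tiny_dataset, cfg, **kw)
        tiny_dataset.split_assignment = None
        m2, h2 = train_model(tiny_dataset, cfg, **kw)
        assert m1.parameter_hash() == m2.parameter_hash()
        assert h1[-1]["train_loss"] == h2[-1]["train_loss"]

    def test_loss_decreases_on_learnable_task(self, tiny_dataset):
        """Short optimization lowers the training loss (trend over the run)."""
        cfg = TrainConfig.desk_scale(epochs=10, epoch_size=36, batch_train=18,
                                     charge_label_mode=ATOMIC_CHARGES, seed=0,
                                     learning_rate=3e-3)
        _, hist = train_model(tiny_dataset, cfg,
                              descriptor=DescriptorConfig.desk_scale(),
                              hyper=QRNNHyper(chi_hidden=(12,), energy_hidden=(12,)))
        losses = [h["train_loss"] for h in hist[1:]]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_force_task_trains(self, tiny_dataset):
        """Second-order path: including the force loss still optimizes."""
        small = Dataset(tiny_dataset.samples[:12])
        cfg = TrainConfig.desk_scale(epochs=3, epoch_size=8, batch_train=4,
                                     charge_label_mode=ATOMIC_CHARGES, seed=0,
                                     use_forces=True)
        _, hist = train_model(small, cfg,
                              descriptor=DescriptorConfig.desk_scale(),
                              hyper=QRNNHyper(chi_hidden=(8,), energy_hidden=(8,)))
        assert np.isfinite(hist[-1]["train_loss"])
        assert hist[-1]["sigma_g"] != 1.0  # σ_g was actually trained

    def test_dipole_label_mode(self, tiny_dataset):
        cfg = TrainConfig.desk_scale(epochs=1, epoch_size=8, batch_train=8,
                                     charge_label_mode=DIPOLE, seed=0)
        _, hist = train_model(tiny_dataset, cfg,
                              descriptor=DescriptorConfig.desk_scale(),
                              hyper=QRNNHyper(chi_hidden=(8,), energy_hidden=(8,)))
        assert np.isfinite(hist[-1]["train_loss"])

    def test_transfer_start_not_worse_than_random(self, tiny_dataset):
        """Warm-starting from a trained model never raises the initial
        validation loss relative to that model's own final state."""
        cfg = TrainConfig.desk_scale(epochs=10, epoch_size=36, batch_train=18,
                                     charge_label_mode=ATOMIC_CHARGES, seed=3,
                                     learning_rate=3e-3)
        kw = dict(descriptor=DescriptorConfig.desk_scale(),
                  hyper=QRNNHyper(chi_hidden=(12,), energy_hidden=(12,)))
        m1, h1 = train_model(tiny_dataset, cfg, **kw)
        cfg2 = TrainConfig.desk_scale(epochs=0, charge_label_mode=ATOMIC_CHARGES,
                                      seed=3)
        _, h2 = train_model(tiny_dataset, cfg2, model=m1)
        # transfer epoch-0 val MAE equals the source model's final val MAE
        assert h2[0]["val_energy_mae"] <= h1[0]["val_energy_mae"] + 1e-9

    def test_reference_protocol_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-3
        assert cfg.weight_decay == 1e-4
        assert cfg.batch_train == 256
        assert cfg.batch_val == 1024
        assert cfg.epochs == 500
        assert cfg.epoch_size == 200_000

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.4))

    def test_missing_charge_labels_rejected(self, tiny_dataset):
        stripped = Dataset([type(s)(s.system, s.energy, s.forces, None, None)
                            for s in tiny_dataset.samples])
        cfg = TrainConfig.desk_scale(epochs=1, charge_label_mode=ATOMIC_CHARGES)
        with pytest.raises(ValueError, match="ref_charges"):
            train_model(stripped, cfg, descriptor=DescriptorConfig.desk_scale())
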