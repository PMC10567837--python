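"""Query-by-committee active learning.

A committee of five independently trained QRNN models scores candidate
clusters by the weight-averaged variance of their force predictions,

    ρ^f = Σ_{i=1}^{N_a} Σ_{x,y,z} σ(f) / √N_a ,

where σ(f) is the population variance over the committee members' force
components for one atom.  High-ρ^f samples mark regions the current model
generalizes poorly; each round selects the top-K by ρ^f plus K random
samples from the remainder, labels them, and appends them to the dataset
for retraining (or transfer learning).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .batch import SystemBatch
from .model import QRNNModel
from .system import Dataset, LabeledSample
from .trainer import TrainConfig, train_model

COMMITTEE_SIZE = 5
COMMITTEE_SPLIT = (0.6, 0.4)   # looser split than the 90/10 target model


@dataclass
class SelectionConfig:
    """Round presets: the first round selects 40,000 + 40,000, the second
    30,000 + 30,000 (scored directly on extracted clusters)."""

    n_top: int
    n_random: int
    seed: int = 0
    round_id: int = 1

    @classmethod
    def round1_preset(cls, seed: int = 0) -> "SelectionConfig":
        return cls(n_top=40_000, n_random=40_000, seed=seed, round_id=1)

    @classmethod
    def round2_preset(cls, seed: int = 0) -> "SelectionConfig":
        return cls(n_top=30_000, n_random=30_000, seed=seed, round_id=2)


@dataclass
class Committee:
    models: list[QRNNModel]
    seeds: list[int]
    split: tuple = COMMITTEE_SPLIT

    def __post_init__(self):
        if len(self.models) != COMMITTEE_SIZE:
            raise ValueError(f"a committee has exactly {COMMITTEE_SIZE} members")

    def member_hashes(self) -> list[str]:
        return [m.parameter_hash() for m in self.models]


def train_committee(dataset: Dataset, base_config: TrainConfig,
                    seeds, model_kwargs=None) -> Committee:
    """Train the five members, each on its own 60/40 split drawn from its
    seed.  Members with distinct seeds see different splits and different
    initializations, so they disagree most where data is scarce."""
    seeds = list(seeds)
    if len(seeds) != COMMITTEE_SIZE:
        raise ValueError(f"need {COMMITTEE_SIZE} seeds")
    model_kwargs = model_kwargs or {}
    models = []
    for seed in seeds:
        cfg = replace(base_config, seed=int(seed), split=COMMITTEE_SPLIT)
        member_data = Dataset(dataset.samples)   # fresh split per member
        model, _ = train_model(member_data, cfg, **model_kwargs)
        models.append(model)
    return Committee(models, seeds)


def committee_forces(committee: Committee, systems) -> list[np.ndarray]:
    """Stacked per-member force predictions: list over members of
    (N_total, 3) arrays for the concatenated systems."""
    out = []
    for model in committee.models:
        sb = SystemBatch(systems, model)
        res = sb.forward(QRNNModel.params_t(model.params), need_forces=True)
        out.append(res["forces"].numpy())
    return out


def force_variance_score(member_forces: np.ndarray, n_atoms: int,
                         statistic: str = "variance") -> float:
    """ρ^f from stacked member forces of one system, shape (5, N_a, 3).

    ``statistic`` selects the spread measure σ(f): the population variance
    (default, as stated) or the standard deviation (the alternative
    reading).
    """
    spread = member_forces.var(axis=0)          # population variance, /M
    if statistic == "std":
        spread = np.sqrt(spread)
    elif statistic != "variance":
        raise ValueError("statistic must be 'variance' or 'std'")
    return float(spread.sum() / np.sqrt(n_atoms))


def committee_force_variance(committee: Committee, systems,
                             statistic: str = "variance") -> np.ndarray:
    """ρ^f for each system in ``systems``; ≥ 0, zero iff members agree."""
    forces = committee_forces(committee, systems)
    sb = SystemBatch(systems, committee.models[0])
    scores = np.empty(len(systems))
    for b in range(sb.B):
        sl = slice(sb.offsets[b], sb.offsets[b + 1])
        stacked = np.stack([f[sl] for f in forces])
        scores[b] = force_variance_score(stacked, sb.n_atoms[b], statistic)
    return scores


def select_samples(rho: np.ndarray, config: SelectionConfig) -> np.ndarray:
    """Indices of the top-``n_top`` by ρ^f (ties broken by pool index) plus
    ``n_random`` uniform draws from the remainder; disjoint, reproducible."""
    rho = np.asarray(rho, dtype=float)
    n = len(rho)
    if config.n_top + config.n_random > n:
        raise ValueError("selection larger than the pool")
    order = np.lexsort((np.arange(n), -rho))    # descending ρ, stable by index
    top = order[:config.n_top]
    rest = order[config.n_top:]
    rng = np.random.default_rng(config.seed)
    rand = rest[rng.choice(len(rest), size=config.n_random, replace=False)]
    return np.concatenate([np.sort(top), np.sort(rand)])


def active_learning_round(dataset: Dataset, pool_systems, pool_labeler,
                          committee: Committee, config: SelectionConfig,
                          statistic: str = "variance"):
    """Score the pool, select, label, and append.

    ``pool_labeler(index) -> LabeledSample`` supplies reference labels for
    a selected pool entry; if any labeling fails the round aborts with the
    dataset unchanged.  Returns ``(augmented_dataset, selected_indices,
    rho_scores)``.
    """
    rho = committee_force_variance(committee, pool_systems, statistic)
    selected = select_samples(rho, config)
    new_samples: list[LabeledSample] = []
    try:
        for idx in selected:
            sample = pool_labeler(int(idx))
            sample.round_id = config.round_id
            new_samples.append(sample)
    except Exception as exc:
        raise RuntimeError(f"labeling failed mid-round; nothing appended: {exc}")
    augmented = Dataset(dataset.samples + new_samples)
    return augmented, selected, rho
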