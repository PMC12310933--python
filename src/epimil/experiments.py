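"""End-to-end synthetic studies: motif recovery, ablation, screening.

These functions wire the generator, trainer and metrics together at desk
scale: a tiny model configuration (2 blocks, 2 heads, d_model 32) trained on
planted-motif worlds of a few thousand peptides.  They back both the test
suite and scripts/acceptance.py, so every reported number is recomputed from
scratch at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqcore, training
from .metrics import classification_metrics
from .model import ModelConfig
from .seqcore import PeptideRecord
from .synthetic import SyntheticWorld, generate_proteome, generate_world
from .training import (DecoyPolicy, TrainConfig, ensemble_scores, fit,
                       sample_decoys)

#: small architecture used for all desk-scale synthetic studies
TINY_CONFIG = ModelConfig(n_blocks=2, n_heads=2, d_model=32)

#: schedule for the tiny configuration: same optimiser/clipping/decay rules as
#: the full-scale defaults, but sized for a 32-dimensional model on a few
#: thousand peptides — larger step, smaller batches (so an epoch provides
#: enough updates to escape the initial plateau), and a 3-epoch plateau
#: window (with so few batches per epoch the validation loss is noisy
#: epoch-to-epoch, and the full-scale 2-epoch window fires spuriously early,
#: collapsing the step size before learning starts).
TINY_TRAIN = TrainConfig(lr=2e-3, batch_size=100, max_epochs=14,
                         plateau_epochs=3)


def weighted_records(world: SyntheticWorld) -> list[PeptideRecord]:
    """Positive records with 0.8-identity cluster weights attached."""
    records = world.positive_records()
    clusters = seqcore.cluster_peptides([r.peptide.sequence for r in records])
    return seqcore.assign_weights(records, clusters)


@dataclass
class RecoveryResult:
    test_auc: float
    core_accuracy: float
    n_test_positives: int
    train_log_rows: int


def synthetic_recovery(seed: int = 0,
                       n_alleles: int = 5,
                       n_samples: int = 20,
                       positives_per_sample: int = 100,
                       concentration: float = 150.0,
                       train_config: TrainConfig = TINY_TRAIN,
                       model_config: ModelConfig = TINY_CONFIG) -> RecoveryResult:
    """Train on a strong-anchor world and measure held-out recovery.

    Returns held-out ROC-AUC (positives vs fresh decoys) and the fraction of
    held-out positives whose argmax window equals the planted core offset.
    """
    world = generate_world(n_alleles=n_alleles, n_samples=n_samples,
                           positives_per_sample=positives_per_sample,
                           polyallelic_max=n_alleles,
                           concentration=concentration, seed=seed)
    records = weighted_records(world)
    train, val, test, _ = seqcore.split_dataset(records, seed=seed)
    proteome = tuple(generate_proteome(n_proteins=150, seed=seed + 1).values())
    policy = DecoyPolicy("unscreened", proteome, seed=seed)
    result = fit(train, val, world.sample_alleles(), world.registry,
                 model_config, train_config, policy, seed=seed)

    test_decoys = sample_decoys(test, policy, epoch=900_000)
    eval_records = test + test_decoys
    scores, offsets, _ = ensemble_scores(
        [result.model], eval_records, world.sample_alleles(), world.registry)
    labels = [r.label for r in eval_records]
    auc = classification_metrics(scores, labels)["roc_auc"]

    truth = {(s.sample_id, p.peptide): p.core_offset
             for s in world.samples for p in s.positives}
    n_correct = sum(
        int(offsets[i] == truth[(r.sample_id, r.peptide.sequence)])
        for i, r in enumerate(test))
    return RecoveryResult(auc, n_correct / len(test), len(test),
                          len(result.log))


def untrained_auc(seed: int = 0, n_eval: int = 300,
                  model_config: ModelConfig = TINY_CONFIG) -> float:
    """ROC-AUC of a randomly initialised model on synthetic data (~0.5)."""
    world = generate_world(n_alleles=3, n_samples=6,
                           positives_per_sample=n_eval // 6,
                           polyallelic_max=3, concentration=50.0, seed=seed)
    records = world.positive_records()
    proteome = tuple(generate_proteome(n_proteins=60, seed=seed + 1).values())
    policy = DecoyPolicy("unscreened", proteome, seed=seed)
    decoys = sample_decoys(records, policy, epoch=0)
    eval_records = records + decoys
    model = training.PresentationModel(model_config, seed=seed)
    scores, _, _ = ensemble_scores([model], eval_records,
                                   world.sample_alleles(), world.registry)
    return classification_metrics(scores,
                                  [r.label for r in eval_records])["roc_auc"]


@dataclass
class AblationResult:
    spread_weighted: float
    spread_unweighted: float
    bin_aucs_weighted: dict
    bin_aucs_unweighted: dict


def _bin_of(cluster_size: int) -> str:
    if cluster_size == 1:
        return "singleton"
    if cluster_size <= 10:
        return "small"
    return "large"


ABLATION_TRAIN = TrainConfig(lr=2e-3, batch_size=200, max_epochs=12)


def cluster_weight_ablation(seed: int = 0,
                            n_samples: int = 10,
                            positives_per_sample: int = 100,
                            train_config: TrainConfig = ABLATION_TRAIN,
                            model_config: ModelConfig = TINY_CONFIG) -> AblationResult:
    """Train with vs without cluster weights on an 80%-dominant-motif world.

    The world routes 80% of positives through one motif and emits frequent
    near-duplicates, so one giant cluster dominates the raw loss.  Held-out
    AUC is computed per cluster-size bin (singleton / ≤10 / >10); the spread
    (max − min across bins) should shrink when inverse-cluster-size weights
    are applied.

    Records are split at random (seeded) rather than by 9mer disjointness:
    binning the held-out set by cluster size requires members of every bin,
    and a 9mer-disjoint split necessarily routes each near-duplicate cluster
    wholesale to a single side.
    """
    world = generate_world(n_alleles=3, n_samples=n_samples,
                           positives_per_sample=positives_per_sample,
                           polyallelic_max=3, dominant_fraction=0.8,
                           duplicate_rate=0.6, concentration=50.0, seed=seed)
    records = weighted_records(world)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    # 50/10/40: a large held-out share keeps every cluster-size bin populated
    n_train = int(0.5 * len(records))
    n_val = int(0.1 * len(records))
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train:n_train + n_val]]
    test = [records[i] for i in perm[n_train + n_val:]]
    proteome = tuple(generate_proteome(n_proteins=100, seed=seed + 1).values())
    policy = DecoyPolicy("unscreened", proteome, seed=seed)

    cluster_sizes = {}
    for r in records:
        cluster_sizes[r.cluster_id] = cluster_sizes.get(r.cluster_id, 0) + 1

    test_decoys = sample_decoys(test, policy, epoch=900_000)
    spreads = {}
    bin_tables = {}
    for use_weights in (True, False):
        result = fit(train, val, world.sample_alleles(), world.registry,
                     model_config, train_config, policy, seed=seed,
                     use_weights=use_weights)
        eval_records = test + test_decoys
        scores, _, _ = ensemble_scores([result.model], eval_records,
                                       world.sample_alleles(), world.registry)
        labels = np.array([r.label for r in eval_records])
        pos_scores = scores[:len(test)]
        decoy_scores = scores[len(test):]
        bins = {}
        for i, r in enumerate(test):
            bins.setdefault(_bin_of(cluster_sizes[r.cluster_id]), []).append(
                pos_scores[i])
        aucs = {}
        for b, s in bins.items():
            if len(s) < 20:     # bins too small for a stable AUC are skipped
                continue
            y = np.r_[np.ones(len(s)), np.zeros(len(decoy_scores))]
            sc = np.r_[s, decoy_scores]
            aucs[b] = classification_metrics(sc, y)["roc_auc"]
        spreads[use_weights] = max(aucs.values()) - min(aucs.values())
        bin_tables[use_weights] = aucs
    return AblationResult(spreads[True], spreads[False],
                          bin_tables[True], bin_tables[False])
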