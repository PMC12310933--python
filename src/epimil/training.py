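"""Training protocol: decoys, cluster-weighted loss, allele dropout, schedule.

Non-presented peptides are never observed directly, so negatives are length-
matched decoys drawn from a background proteome, regenerated every epoch, in
two scenarios (plain, and screened to share no 9mer with any positive); one
model is trained per scenario and predictions are averaged at inference.  The
loss is a weighted binary cross-entropy on the bag-level max logit, with
inverse-cluster-size weights so dominant binding cores do not swamp rare ones.
During training, half of the allele score rows of each polyallelic sample are
randomly excluded from the max (allele dropout) to spread credit across
underrepresented alleles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import Batch, ModelConfig, PresentationModel, make_batch
from .seqcore import Peptide, PeptideRecord, ninemer_set

logger = logging.getLogger(__name__)

SCENARIOS = ("unscreened", "screened_9mer_disjoint")


@dataclass(frozen=True)
class DecoyPolicy:
    """How per-epoch decoys are drawn from the background proteome."""

    scenario: str
    proteome: tuple[str, ...]          # background protein sequences
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not self.proteome:
            raise ValueError("empty background proteome")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; defaults follow the published full-scale run."""

    lr: float = 1e-5
    batch_size: int = 200
    max_epochs: int = 50
    lr_decay_factor: float = 0.7
    plateau_eps: float = 1e-4          # min val-loss improvement to count
    plateau_epochs: int = 2            # flat epochs triggering one decay
    early_stop_patience: int = 5
    min_decays_for_stop: int = 2
    grad_clip: float = 1.0
    allele_dropout_fraction: float = 0.5
    weight_decay: float = 0.01         # AdamW default

    def __post_init__(self):
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr decay factor must lie in (0, 1)")
        for name in ("lr", "batch_size", "max_epochs", "grad_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def sample_decoys(positives: list[PeptideRecord], policy: DecoyPolicy,
                  epoch: int) -> list[PeptideRecord]:
    """One decoy per positive: same length, sample id and weight; label 0.

    Seeded by (policy.seed, epoch), so each epoch sees fresh decoys and the
    same (seed, epoch) pair reproduces them exactly.  Under the screened
    scenario, candidates sharing any 9mer with any positive are rejected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([policy.seed, epoch]))
    screened = policy.scenario == "screened_9mer_disjoint"
    forbidden: frozenset[str] = frozenset()
    if screened:
        forbidden = frozenset().union(
            *(ninemer_set(p.peptide.sequence) for p in positives))
    lengths = np.array([len(p) for p in policy.proteome])
    decoys = []
    for pos in positives:
        L = len(pos.peptide)
        eligible = np.flatnonzero(lengths >= L)
        if eligible.size == 0:
            raise ValueError(f"no background protein of length >= {L}")
        seq = None
        for _ in range(200):
            pi = int(eligible[rng.integers(eligible.size)])
            prot = policy.proteome[pi]
            start = int(rng.integers(len(prot) - L + 1))
            cand = prot[start:start + L]
            if not screened or forbidden.isdisjoint(ninemer_set(cand)):
                seq = cand
                break
        if seq is None:
            warnings.warn("background too small to find a 9mer-disjoint decoy; "
                          "accepting an overlapping one")
            seq = cand
        decoys.append(PeptideRecord(Peptide(seq), pos.sample_id, 0,
                                    pos.cluster_id, pos.weight))
    return decoys


def allele_dropout_mask(allele_mask: np.ndarray, rng: np.random.Generator,
                        fraction: float = 0.5) -> np.ndarray:
    """Drop floor(N·fraction) allele rows per polyallelic sample from the max.

    Monoallelic rows are untouched.  Returns a new (B, N) boolean mask.
    """
    out = allele_mask.copy()
    for i in range(allele_mask.shape[0]):
        valid = np.flatnonzero(allele_mask[i])
        n_drop = int(valid.size * fraction)
        if valid.size >= 2 and n_drop:
            out[i, rng.choice(valid, size=n_drop, replace=False)] = False
    return out


def weighted_bce(scores: np.ndarray, labels: np.ndarray,
                 weights: np.ndarray) -> float:
    """loss = sum_i w_i * BCE(s_i, y_i) / sum_i w_i (scores already in (0,1))."""
    s = np.clip(np.asarray(scores, dtype=np.float64), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    bce = -(y * np.log(s) + (1 - y) * np.log(1 - s))
    return float((w * bce).sum() / w.sum())


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class AdamW:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t / (np.sqrt(v / b2t) + self.eps)
                                 + self.wd * p.data)


def clip_gradients(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: PresentationModel
    log: pd.DataFrame
    best_val_loss: float
    stopped_epoch: int


def _bucketed_order(records, allele_sets, order: np.ndarray) -> np.ndarray:
    """Stable sort by (allele count, length) so batches are shape-homogeneous.

    Pair-tensor compute scales with max(N)·max(L−8) over the batch, so mixing
    a 9mer with a 26mer (or mono- with 5-allele samples) wastes most of the
    tensor on padding.  Stability keeps the incoming shuffle as the tie-break.
    """
    key = np.array([(len(allele_sets[i]), len(records[i].peptide))
                    for i in order])
    return order[np.lexsort((key[:, 1], key[:, 0]))]


def _epoch_allele_sets(records, sample_alleles, rng=None,
                       fraction: float = 0.5) -> list[list[str]]:
    """Per-record allele sets, with training-time allele dropout applied.

    Dropping an allele before the encoders is equivalent to masking its score
    rows out of the max aggregation (alleles do not interact in the model),
    but skips the dropped rows' compute entirely.
    """
    out = []
    for r in records:
        names = sorted(sample_alleles[r.sample_id])
        n = len(names)
        n_drop = int(n * fraction) if rng is not None else 0
        if n >= 2 and n_drop:
            dropped = set(rng.choice(n, size=n_drop, replace=False).tolist())
            names = [nm for j, nm in enumerate(names) if j not in dropped]
        out.append(names)
    return out


def _batches(records, allele_sets, registry, cfg: TrainConfig,
             max_alleles: int, order: np.ndarray,
             batch_rng: np.random.Generator | None = None):
    order = _bucketed_order(records, allele_sets, order)
    starts = list(range(0, len(order), cfg.batch_size))
    if batch_rng is not None:
        batch_rng.shuffle(starts)
    for lo in starts:
        idx = order[lo:lo + cfg.batch_size]
        recs = [records[i] for i in idx]
        yield make_batch([r.peptide.sequence for r in recs],
                         [allele_sets[i] for i in idx],
                         registry, max_alleles,
                         labels=[r.label for r in recs],
                         weights=[r.weight for r in recs])


def _batch_loss(model: PresentationModel, batch: Batch, cfg: TrainConfig,
                drop_rng=None, mask_rng=None):
    logits, pair_mask, _ = model.forward(batch, rng=drop_rng)
    if mask_rng is not None:
        amask = allele_dropout_mask(batch.allele_mask, mask_rng,
                                    cfg.allele_dropout_fraction)
        pair_mask = amask[:, :, None] & batch.window_mask()[:, None, :]
    final_logits, _ = logits.masked_max(pair_mask)
    return final_logits.weighted_bce_with_logits(batch.labels, batch.weights)


def allele_dropout(pair_scores: np.ndarray, allele_mask: np.ndarray,
                   rng: np.random.Generator,
                   fraction: float = 0.5) -> np.ndarray:
    """Mask score rows of dropped alleles out of the max (−inf sentinel).

    The score-space view of training-time allele dropout; `_epoch_allele_sets`
    realises the same operation by dropping the alleles before the encoders,
    which is equivalent because alleles never attend to each other.
    """
    keep = allele_dropout_mask(allele_mask, rng, fraction)
    return np.where(keep[:, :, None], pair_scores, -np.inf)


def fit(train_positives: list[PeptideRecord],
        val_positives: list[PeptideRecord],
        sample_alleles: dict[str, list[str]],
        registry,
        model_config: ModelConfig,
        train_config: TrainConfig,
        policy: DecoyPolicy,
        seed: int = 0,
        use_weights: bool = True) -> FitResult:
    """Train one model under one decoy scenario.

    Three named RNG streams (decoys via the policy seed, dropout, init) keep
    runs bit-reproducible.  The best-validation parameter set is retained.
    Setting ``use_weights=False`` trains with uniform weights (ablation).
    """
    if not train_positives or not val_positives:
        raise ValueError("need non-empty train and validation positives")
    if not use_weights:
        train_positives = [replace(r, weight=1.0) for r in train_positives]
        val_positives = [replace(r, weight=1.0) for r in val_positives]

    ss = np.random.SeedSequence(seed)
    init_seed, drop_seed, shuffle_seed, amask_seed = ss.generate_state(4) >> 1
    model = PresentationModel(model_config, seed=int(init_seed),
                              scenario=policy.scenario)
    opt = AdamW(model.parameters(), lr=train_config.lr,
                weight_decay=train_config.weight_decay)
    drop_rng = np.random.default_rng(int(drop_seed))
    shuffle_rng = np.random.default_rng(int(shuffle_seed))
    amask_rng = np.random.default_rng(int(amask_seed))

    # fixed validation decoys: epoch index outside the training range
    val_decoys = sample_decoys(val_positives, policy, epoch=-1 & 0x7FFFFFFF)
    val_records = val_positives + val_decoys

    best_val = np.inf
    best_state = model.state_arrays()
    epochs_since_improve = 0
    flat_epochs = 0
    n_decays = 0
    rows = []
    stopped = train_config.max_epochs
    for epoch in range(train_config.max_epochs):
        decoys = sample_decoys(train_positives, policy, epoch)
        records = train_positives + decoys
        order = shuffle_rng.permutation(len(records))
        allele_sets = _epoch_allele_sets(
            records, sample_alleles, rng=amask_rng,
            fraction=train_config.allele_dropout_fraction)
        epoch_loss = 0.0
        n_batches = 0
        for batch in _batches(records, allele_sets, registry, train_config,
                              model_config.max_alleles, order,
                              batch_rng=shuffle_rng):
            model.zero_grad()
            loss = _batch_loss(model, batch, train_config, drop_rng=drop_rng)
            if not np.isfinite(loss.data):
                logger.error("non-finite loss at epoch %d; aborting with last "
                             "good checkpoint", epoch)
                model.load_state_arrays(best_state)
                log = pd.DataFrame(rows)
                return FitResult(model, log, best_val, epoch)
            loss.backward()
            clip_gradients(model.parameters(), train_config.grad_clip)
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        val_loss = _validation_loss(model, val_records, sample_alleles,
                                    registry, train_config,
                                    model_config.max_alleles)
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": opt.lr,
                     "n_decoys": len(decoys), "scenario": policy.scenario})
        logger.info("epoch %d train %.4f val %.4f lr %.2e",
                    epoch, train_loss, val_loss, opt.lr)

        if val_loss < best_val - train_config.plateau_eps:
            best_val = val_loss
            best_state = model.state_arrays()
            epochs_since_improve = 0
            flat_epochs = 0
        else:
            epochs_since_improve += 1
            flat_epochs += 1
            if flat_epochs >= train_config.plateau_epochs:
                opt.lr *= train_config.lr_decay_factor
                n_decays += 1
                flat_epochs = 0
        if (epochs_since_improve >= train_config.early_stop_patience
                and n_decays >= train_config.min_decays_for_stop):
            stopped = epoch + 1
            break

    model.load_state_arrays(best_state)
    return FitResult(model, pd.DataFrame(rows), best_val, stopped)


def _validation_loss(model, records, sample_alleles, registry,
                     cfg: TrainConfig, max_alleles: int) -> float:
    order = np.arange(len(records))
    allele_sets = _epoch_allele_sets(records, sample_alleles)  # no dropout
    total, wsum = 0.0, 0.0
    for batch in _batches(records, allele_sets, registry, cfg,
                          max_alleles, order):
        logits, pair_mask, _ = model.forward(batch, rng=None)
        final_logits, _ = logits.masked_max(pair_mask)
        scores = 1.0 / (1.0 + np.exp(-final_logits.data.astype(np.float64)))
        w = batch.weights.astype(np.float64)
        s = np.clip(scores, 1e-12, 1 - 1e-12)
        y = batch.labels.astype(np.float64)
        total += float((w * -(y * np.log(s) + (1 - y) * np.log(1 - s))).sum())
        wsum += float(w.sum())
    return total / wsum


def train_ensemble(train_positives, val_positives, sample_alleles, registry,
                   model_config: ModelConfig, train_config: TrainConfig,
                   proteome: tuple[str, ...], seed: int = 0,
                   use_weights: bool = True) -> tuple[FitResult, FitResult]:
    """Fit the two-scenario ensemble (plain decoys, screened decoys)."""
    results = []
    for k, scenario in enumerate(SCENARIOS):
        policy = DecoyPolicy(scenario, tuple(proteome), seed=seed + k)
        results.append(fit(train_positives, val_positives, sample_alleles,
                           registry, model_config, train_config, policy,
                           seed=seed + k, use_weights=use_weights))
    return tuple(results)


# ---------------------------------------------------------------------------
# batched ensemble inference
# ---------------------------------------------------------------------------

def ensemble_scores(models: list[PresentationModel],
                    records: list[PeptideRecord],
                    sample_alleles: dict[str, list[str]], registry,
                    batch_size: int = 200):
    """Mean-pair-matrix ensemble scores for many records.

    Returns (scores, core_offsets, allele_names) aligned with `records`;
    the argmax is taken on the averaged matrix (allele-major tie order).
    """
    scores = np.zeros(len(records))
    offsets = np.zeros(len(records), dtype=int)
    best_allele: list[str] = [""] * len(records)
    max_alleles = models[0].config.max_alleles
    all_sets = _epoch_allele_sets(records, sample_alleles)
    ordered = _bucketed_order(records, all_sets, np.arange(len(records)))
    for lo in range(0, len(records), batch_size):
        sel = ordered[lo:lo + batch_size]
        recs = [records[i] for i in sel]
        names = [sorted(sample_alleles[r.sample_id]) for r in recs]
        batch = make_batch([r.peptide.sequence for r in recs], names,
                           registry, max_alleles)
        pair_mask = batch.allele_mask[:, :, None] & batch.window_mask()[:, None, :]
        mean = None
        for m in models:
            logits, _, _ = m.forward(batch, rng=None)
            s = 1.0 / (1.0 + np.exp(-logits.data))
            mean = s if mean is None else mean + s
        mean /= len(models)
        mean = np.where(pair_mask, mean, -1.0)
        B, N, M = mean.shape
        flat = mean.reshape(B, -1)
        arg = flat.argmax(axis=1)
        scores[sel] = flat[np.arange(B), arg]
        offsets[sel] = arg % M
        for i, a in enumerate(arg // M):
            best_allele[sel[i]] = names[i][a]
    return scores, offsets, best_allele
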