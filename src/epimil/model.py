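"""Multiple-instance cross-attention model of HLA class II presentation.

The model mirrors the biology of class II presentation: a peptide encoder
(transformer self-attention over the padded peptide) produces residue
representations from which every candidate 9mer binding core is sliced; an
allele encoder embeds the 34-AA groove pseudo-sequence; an interaction encoder
lets each core residue cross-attend to the groove residues.  Every one of the
N × M core–allele pairs receives a presentation likelihood through a sigmoid
head on the flattened (9 × d_model) interaction features, and the peptide's
final score is the maximum over all pairs — multiple-instance learning with
max aggregation, so a bag-level label is explained by its best instance.

Defaults follow the published architecture: 8 encoder blocks, 8 heads,
d_model = 128 (head input 9 × 128 = 1152), dropout 0.1, peptides padded to
30 AAs, at most 14 alleles per sample.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._tensor import Parameter, Tensor
from .alleles import AlleleSpec, PSEUDO_LEN
from .seqcore import (CORE_LEN, MODEL_MAX_LEN, PAD_INDEX, VOCAB_SIZE,
                      pad_and_mask)

CHECKPOINT_FORMAT_VERSION = 1


class AlleleCountError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    n_blocks: int = 8
    n_heads: int = 8
    d_model: int = 128
    dropout: float = 0.1
    max_peptide_len: int = MODEL_MAX_LEN
    max_alleles: int = 14
    ffn_depth: int = 1               # linear(+ReLU) layers per block's FFN
    positional_embeddings: bool = True
    shared_embedding: bool = False   # share AA embedding across both encoders

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def head_hidden(self) -> int:
        """Width of the flattened per-pair interaction features (1152 default)."""
        return CORE_LEN * self.d_model


@dataclass(frozen=True)
class PairScoreMatrix:
    """N alleles × M windows of presentation likelihoods for one peptide."""

    scores: np.ndarray               # (N, M) in (0, 1)
    allele_names: tuple[str, ...]
    offsets: tuple[int, ...]

    @property
    def final_score(self) -> float:
        return float(self.scores.max())

    @property
    def argmax(self) -> tuple[int, int]:
        """(allele index, window offset); ties → smallest allele, then offset."""
        i = int(self.scores.argmax())        # row-major: allele-major order
        return divmod(i, self.scores.shape[1])


@dataclass(frozen=True)
class Prediction:
    peptide: str
    score: float
    core_offset: int
    core: str
    allele: str
    pair_scores: PairScoreMatrix


@dataclass
class AttentionRecord:
    """Cross-attention weights: (n_blocks, n_heads, 9, 34) per core–allele pair.

    Stored for the full batch as (n_blocks, B, N, M, n_heads, 9, 34); use
    :meth:`for_pair` to pull out one pair.  Rows are softmax-normalised.
    """

    weights: np.ndarray

    def for_pair(self, batch_index: int, allele_index: int,
                 window_index: int) -> np.ndarray:
        return self.weights[:, batch_index, allele_index, window_index]


# ---------------------------------------------------------------------------


def _init(rng: np.random.Generator, *shape, scale: float | None = None):
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Parameter(rng.normal(0.0, scale, size=shape).astype(np.float32))


class _Linear:
    def __init__(self, rng, d_in, d_out):
        self.w = _init(rng, d_in, d_out)
        self.b = Parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x.linear(self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _MultiHeadAttention:
    """Multi-head attention shared by the self- and cross-attention paths.

    Batch axes are collapsed before the Q·Kᵀ matmuls so BLAS sees few, large
    matrices instead of tens of thousands of 9×dh ones.
    """

    def __init__(self, rng, d_model, n_heads):
        self.h = n_heads
        self.dh = d_model // n_heads
        self.scale = Tensor(np.float32(1.0 / np.sqrt(self.dh)))
        self.wq = _Linear(rng, d_model, d_model)
        self.wk = _Linear(rng, d_model, d_model)
        self.wv = _Linear(rng, d_model, d_model)
        self.wo = _Linear(rng, d_model, d_model)

    def self_attn(self, x: Tensor, key_mask: np.ndarray | None = None):
        """x: (B, L, d) -> (output (B, L, d), attention (B, h, L, L))."""
        B, L, d = x.shape
        h, dh = self.h, self.dh

        def split(t):  # (B, L, d) -> (B, h, L, dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = q @ (k * self.scale).transpose(0, 1, 3, 2)
        mask = None if key_mask is None else key_mask[:, None, None, :]
        attn = logits.masked_softmax(mask)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(out), attn

    def cross_attn(self, q_in: Tensor, kv: Tensor):
        """q_in: (B, n, M, 9, d) with n ∈ {1, N}; kv: (B, N, Lk, d).

        Every 9mer core queries every allele's groove residues.  Returns the
        per-pair output (B, N, M, 9, d) and attention (B, N, M, h, 9, Lk).
        """
        B, n, M, Lq, d = q_in.shape
        _, N, Lk, _ = kv.shape
        h, dh = self.h, self.dh
        # queries: collapse (M, 9) into one row axis per (B, n, h) batch
        q = (self.wq(q_in).reshape(B, n, M, Lq, h, dh)
             .transpose(0, 1, 4, 2, 3, 5).reshape(B, n, h, M * Lq, dh))
        k = self.wk(kv).reshape(B, N, Lk, h, dh).transpose(0, 1, 3, 2, 4)
        v = self.wv(kv).reshape(B, N, Lk, h, dh).transpose(0, 1, 3, 2, 4)
        # scale K, not the (much larger) logits tensor
        logits = q @ (k * self.scale).transpose(0, 1, 2, 4, 3)  # (B,N,h,M·9,Lk)
        attn = logits.masked_softmax(None)
        out = (attn @ v)                                        # (B,N,h,M·9,dh)
        out = (out.reshape(B, N, h, M, Lq, dh)
               .transpose(0, 1, 3, 4, 2, 5).reshape(B, N, M, Lq, d))
        attn_pair = attn.data.reshape(B, N, h, M, Lq, Lk).transpose(0, 1, 3, 2, 4, 5)
        return self.wo(out), attn_pair

    def params(self):
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()


class _Block:
    """Residual block: (self or cross) attention + position-wise FFN + norms."""

    def __init__(self, rng, cfg: ModelConfig):
        d = cfg.d_model
        self.attn = _MultiHeadAttention(rng, d, cfg.n_heads)
        self.ffn = [_Linear(rng, d, d) for _ in range(cfg.ffn_depth)]
        self.g1 = Parameter(np.ones(d, dtype=np.float32))
        self.b1 = Parameter(np.zeros(d, dtype=np.float32))
        self.g2 = Parameter(np.ones(d, dtype=np.float32))
        self.b2 = Parameter(np.zeros(d, dtype=np.float32))
        self.drop = cfg.dropout

    def _ffn_half(self, x: Tensor, rng):
        f = x
        for i, lin in enumerate(self.ffn):
            f = lin(f)
            f = f.relu()
        return (x + f.dropout(self.drop, rng)).layer_norm(self.g2, self.b2)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None):
        h, attn = self.attn.self_attn(x, key_mask)
        x = (x + h.dropout(self.drop, rng)).layer_norm(self.g1, self.b1)
        return self._ffn_half(x, rng), attn

    def cross(self, q: Tensor, kv: Tensor,
              rng: np.random.Generator | None = None):
        h, attn = self.attn.cross_attn(q, kv)
        q = (q + h.dropout(self.drop, rng)).layer_norm(self.g1, self.b1)
        return self._ffn_half(q, rng), attn

    def params(self):
        out = self.attn.params() + [self.g1, self.b1, self.g2, self.b2]
        for lin in self.ffn:
            out += lin.params()
        return out


@dataclass
class Batch:
    """Padded model input for B peptides against their sample allele sets."""

    pep_tokens: np.ndarray       # (B, Lmax) int
    pep_mask: np.ndarray         # (B, Lmax) bool
    allele_tokens: np.ndarray    # (A, 34) int — unique alleles in the batch
    allele_index: np.ndarray     # (B, N) int into the A axis (0 for padding)
    allele_mask: np.ndarray      # (B, N) bool
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None

    @property
    def window_count(self) -> int:
        return self.pep_mask.shape[1] - CORE_LEN + 1

    def window_mask(self) -> np.ndarray:
        lengths = self.pep_mask.sum(axis=1)
        return np.arange(self.window_count)[None, :] <= (lengths - CORE_LEN)[:, None]


def make_batch(peptides: list[str], allele_sets: list[list[str]],
               registry: dict[str, AlleleSpec], max_alleles: int = 14,
               labels=None, weights=None) -> Batch:
    """Assemble a padded batch; allele sets are sorted by canonical name."""
    if not peptides:
        raise ValueError("empty batch")
    lmax = max(len(p) for p in peptides)
    lmax = max(lmax, CORE_LEN)
    toks = np.full((len(peptides), lmax), PAD_INDEX, dtype=np.int64)
    mask = np.zeros((len(peptides), lmax), dtype=bool)
    for i, p in enumerate(peptides):
        t, m = pad_and_mask(p, lmax)
        toks[i], mask[i] = t, m
    names = sorted({n for s in allele_sets for n in s})
    a_idx = {n: i for i, n in enumerate(names)}
    atoks = np.stack([registry[n].tokens() for n in names])
    nmax = max(len(s) for s in allele_sets)
    if nmax > max_alleles:
        raise AlleleCountError(f"{nmax} alleles in a sample exceeds the "
                               f"supported maximum of {max_alleles}")
    aindex = np.zeros((len(peptides), nmax), dtype=np.int64)
    amask = np.zeros((len(peptides), nmax), dtype=bool)
    for i, s in enumerate(allele_sets):
        for j, n in enumerate(sorted(s)):
            aindex[i, j] = a_idx[n]
            amask[i, j] = True
    return Batch(toks, mask, atoks, aindex, amask,
                 None if labels is None else np.asarray(labels, dtype=np.float32),
                 None if weights is None else np.asarray(weights, dtype=np.float32))


class PresentationModel:
    """The three-encoder architecture with per-pair sigmoid scoring."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 scenario: str = "unscreened"):
        self.config = config or ModelConfig()
        self.scenario = scenario
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = self.config
        d = cfg.d_model
        self.pep_embed = _init(rng, VOCAB_SIZE, d, scale=0.1)
        self.allele_embed = (self.pep_embed if cfg.shared_embedding
                             else _init(rng, VOCAB_SIZE, d, scale=0.1))
        self.pep_pos = _init(rng, cfg.max_peptide_len, d, scale=0.1)
        self.allele_pos = _init(rng, PSEUDO_LEN, d, scale=0.1)
        self.pep_blocks = [_Block(rng, cfg) for _ in range(cfg.n_blocks)]
        self.allele_blocks = [_Block(rng, cfg) for _ in range(cfg.n_blocks)]
        self.cross_blocks = [_Block(rng, cfg) for _ in range(cfg.n_blocks)]
        self.head = _Linear(rng, cfg.head_hidden, 1)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Parameter]:
        out = [self.pep_embed, self.pep_pos, self.allele_pos]
        if self.allele_embed is not self.pep_embed:
            out.append(self.allele_embed)
        for blocks in (self.pep_blocks, self.allele_blocks, self.cross_blocks):
            for b in blocks:
                out += b.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.astype(np.float32).copy()

    # -- encoders ------------------------------------------------------------

    def encode_peptide(self, tokens: np.ndarray, mask: np.ndarray,
                       rng: np.random.Generator | None = None) -> Tensor:
        """(B, L) tokens -> (B, L, d) representations; pads never attended."""
        cfg = self.config
        x = self.pep_embed.take_rows(tokens)
        if cfg.positional_embeddings:
            x = x + self.pep_pos.take_rows(np.arange(tokens.shape[1]))
        x = x.dropout(cfg.dropout, rng)
        for blk in self.pep_blocks:
            x, _ = blk(x, key_mask=mask, rng=rng)
        return x

    def encode_allele(self, tokens: np.ndarray,
                      rng: np.random.Generator | None = None) -> Tensor:
        """(A, 34) tokens -> (A, 34, d) groove-residue representations."""
        if tokens.shape[-1] != PSEUDO_LEN:
            raise ValueError(f"allele pseudo-sequences must have {PSEUDO_LEN} "
                             f"positions, got {tokens.shape[-1]}")
        cfg = self.config
        x = self.allele_embed.take_rows(tokens)
        if cfg.positional_embeddings:
            x = x + self.allele_pos.take_rows(np.arange(PSEUDO_LEN))
        x = x.dropout(cfg.dropout, rng)
        for blk in self.allele_blocks:
            x, _ = blk(x, rng=rng)
        return x

    def interact(self, pep_enc: Tensor, batch: Batch, allele_enc: Tensor,
                 rng: np.random.Generator | None = None,
                 record_attention: bool = False):
        """Cross-attend every 9mer to every allele.

        Returns flattened per-pair features (B, N, M, 9·d) and, optionally,
        the per-block attention stack as an :class:`AttentionRecord`.
        """
        M = batch.window_count
        win_idx = np.arange(M)[:, None] + np.arange(CORE_LEN)[None, :]
        windows = pep_enc.take_axis1(win_idx)          # (B, M, 9, d)
        q = windows.expand_dims(1)                     # (B, 1, M, 9, d)
        kv = allele_enc.take_rows(batch.allele_index)  # (B, N, 34, d)
        attn_stack = [] if record_attention else None
        for blk in self.cross_blocks:
            q, attn = blk.cross(q, kv, rng=rng)        # attn (B,N,M,h,9,34)
            if record_attention:
                attn_stack.append(attn)
        B, N = batch.allele_index.shape
        feats = q.reshape(-1, N, M, self.config.head_hidden)
        record = AttentionRecord(np.stack(attn_stack)) if record_attention else None
        return feats, record

    def score_pairs(self, feats: Tensor,
                    rng: np.random.Generator | None = None) -> Tensor:
        """Per-pair presentation logits (B, N, M); sigmoid gives likelihoods."""
        h = feats.dropout(self.config.dropout, rng)
        return self.head(h).squeeze(-1)

    def forward(self, batch: Batch, rng: np.random.Generator | None = None,
                record_attention: bool = False):
        """Full pass: returns (pair logits (B,N,M), pair mask, AttentionRecord)."""
        pep = self.encode_peptide(batch.pep_tokens, batch.pep_mask, rng)
        alle = self.encode_allele(batch.allele_tokens, rng)
        feats, record = self.interact(pep, batch, alle, rng, record_attention)
        logits = self.score_pairs(feats, rng)
        pair_mask = batch.allele_mask[:, :, None] & batch.window_mask()[:, None, :]
        return logits, pair_mask, record

    # -- inference -----------------------------------------------------------

    def pair_scores(self, peptide: str, alleles: list[AlleleSpec],
                    record_attention: bool = False):
        """Evaluation-mode N × M score matrix for one peptide."""
        if not 1 <= len(alleles) <= self.config.max_alleles:
            raise AlleleCountError(
                f"need 1..{self.config.max_alleles} alleles, got {len(alleles)}")
        L = len(peptide)
        if not CORE_LEN <= L <= self.config.max_peptide_len:
            raise ValueError(f"peptide length {L} outside supported range "
                             f"[{CORE_LEN}, {self.config.max_peptide_len}]")
        ordered = sorted(alleles, key=lambda a: a.name)
        registry = {a.name: a for a in ordered}
        batch = make_batch([peptide], [[a.name for a in ordered]], registry,
                           self.config.max_alleles)
        logits, pair_mask, record = self.forward(
            batch, rng=None, record_attention=record_attention)
        scores = 1.0 / (1.0 + np.exp(-logits.data[0]))
        scores = np.where(pair_mask[0], scores, 0.0)
        mat = PairScoreMatrix(scores, tuple(a.name for a in ordered),
                              tuple(range(batch.window_count)))
        return mat, record


def predict(peptide: str, alleles: list[AlleleSpec],
            ensemble: list[PresentationModel],
            aggregate: str = "mean_pair") -> Prediction:
    """Ensemble prediction across one or more trained model states.

    ``mean_pair`` (default) averages the per-pair score matrices before the
    max, which keeps the reported core/allele consistent with the reported
    score; ``mean_max`` instead averages each model's own maximum (the
    reported core/allele still come from the averaged matrix).  Presented
    iff score >= 0.5.
    """
    if not ensemble:
        raise ValueError("need at least one model state")
    if aggregate not in ("mean_pair", "mean_max"):
        raise ValueError("aggregate must be 'mean_pair' or 'mean_max'")
    mats = [m.pair_scores(peptide, alleles)[0] for m in ensemble]
    mean = np.mean([m.scores for m in mats], axis=0)
    mat = PairScoreMatrix(mean, mats[0].allele_names, mats[0].offsets)
    ai, off = mat.argmax
    score = (mat.final_score if aggregate == "mean_pair"
             else float(np.mean([m.final_score for m in mats])))
    return Prediction(peptide, score, off,
                      peptide[off:off + CORE_LEN], mat.allele_names[ai], mat)


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(model: PresentationModel, path):
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "scenario": model.scenario,
        "seed": model.seed,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> PresentationModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format "
                             f"{meta['format_version']}")
        arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    model = PresentationModel(ModelConfig(**meta["config"]),
                              seed=meta["seed"], scenario=meta["scenario"])
    model.load_state_arrays(arrays)
    return model
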