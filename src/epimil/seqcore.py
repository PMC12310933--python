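"""Peptide records, 9mer window enumeration, padding, clustering and splits.

HLA class II ligands are 9–26 residues long; the groove engages a contiguous
9-residue binding core, so every analysis here revolves around enumerating the
L − 8 candidate cores of a length-L peptide.  Immunopeptidomes are heavily
redundant (nested length variants of the same core), so training records carry
an inverse-cluster-size weight computed from 0.8-identity sequence clusters.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
PAD_INDEX = 20
UNK_INDEX = 21
VOCAB_SIZE = 22
#: letters that occur in real FASTA but are not canonical residues
AMBIGUOUS_AA = set("BJXZUO")

CORE_LEN = 9
MIN_PEPTIDE_LEN = 9   # length-8 ligands exist but have no 9mer core; excluded
MAX_PEPTIDE_LEN = 26
MODEL_MAX_LEN = 30    # padding target for the model input


class DegenerateLengthError(ValueError):
    """Peptide too short to hold a 9mer binding core."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence over the canonical 20-letter alphabet."""

    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - set(AA_ALPHABET) - AMBIGUOUS_AA
        if bad:
            raise ValueError(f"non-amino-acid letters in peptide: {sorted(bad)}")
        if set(self.sequence) & AMBIGUOUS_AA:
            logger.warning("ambiguous residue(s) in %s mapped to unknown token",
                           self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def tokens(self) -> np.ndarray:
        return np.array([AA_TO_INDEX.get(a, UNK_INDEX) for a in self.sequence],
                        dtype=np.int64)


@dataclass(frozen=True)
class PeptideRecord:
    """One observed (or decoy) peptide tied to a sample: the training atom."""

    peptide: Peptide
    sample_id: str
    label: int                      # 1 presented, 0 decoy
    cluster_id: str | None = None
    weight: float = 1.0


@dataclass(frozen=True)
class WindowSet:
    windows: tuple[str, ...]
    offsets: tuple[int, ...]

    def __len__(self):
        return len(self.windows)


def extract_windows(peptide: Peptide | str) -> WindowSet:
    """All contiguous 9mers of the peptide, left to right (M = L − 8)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if len(seq) < CORE_LEN:
        raise DegenerateLengthError(
            f"peptide of length {len(seq)} has no 9mer window")
    offsets = tuple(range(len(seq) - CORE_LEN + 1))
    return WindowSet(tuple(seq[i:i + CORE_LEN] for i in offsets), offsets)


def ninemer_set(seq: str) -> frozenset[str]:
    if len(seq) < CORE_LEN:
        return frozenset()
    return frozenset(seq[i:i + CORE_LEN] for i in range(len(seq) - CORE_LEN + 1))


def pad_and_mask(peptide: Peptide | str,
                 max_len: int = MODEL_MAX_LEN) -> tuple[np.ndarray, np.ndarray]:
    """Token sequence padded to `max_len` plus a boolean mask of real positions."""
    pep = peptide if isinstance(peptide, Peptide) else Peptide(peptide)
    L = len(pep)
    if L > max_len:
        raise ValueError(f"peptide length {L} exceeds maximum {max_len}")
    tokens = np.full(max_len, PAD_INDEX, dtype=np.int64)
    tokens[:L] = pep.tokens()
    mask = np.zeros(max_len, dtype=bool)
    mask[:L] = True
    return tokens, mask


# ---------------------------------------------------------------------------
# greedy star clustering at fractional identity (MMseqs2 easy-cluster stand-in)
# ---------------------------------------------------------------------------

def _best_offset_identity(rep_mat: np.ndarray, rep_lens: np.ndarray,
                          cand: np.ndarray) -> np.ndarray:
    """Ungapped identity of `cand` vs every representative row.

    The candidate (never longer than any representative, by sort order) is slid
    along each representative; identity = best matches / candidate length.
    """
    Lc = cand.size
    max_off = rep_mat.shape[1] - Lc
    best = np.zeros(rep_mat.shape[0], dtype=np.int64)
    for off in range(max_off + 1):
        valid = rep_lens >= Lc + off
        if not valid.any():
            break
        m = (rep_mat[:, off:off + Lc] == cand).sum(axis=1)
        np.maximum(best, np.where(valid, m, 0), out=best)
    return best / Lc


def cluster_peptides(peptides: list[str],
                     min_identity: float = 0.8) -> dict[str, str]:
    """Greedy star clustering of unique sequences at `min_identity`.

    Sequences are sorted by (length desc, lexicographic); each joins the first
    representative whose best ungapped sliding-offset identity (matches divided
    by the shorter length) reaches the threshold, otherwise founds a cluster.
    Deterministic; identical sequences always share a cluster.
    """
    uniq = sorted(set(peptides), key=lambda s: (-len(s), s))
    if not uniq:
        return {}
    maxlen = len(uniq[0])
    rep_mat = np.zeros((len(uniq), maxlen), dtype=np.int8)
    rep_lens = np.zeros(len(uniq), dtype=np.int64)
    rep_names: list[str] = []
    assignment: dict[str, str] = {}
    n_reps = 0
    for seq in uniq:
        cand = np.frombuffer(seq.encode("ascii"), dtype=np.int8)
        if n_reps:
            ident = _best_offset_identity(rep_mat[:n_reps], rep_lens[:n_reps], cand)
            hits = np.nonzero(ident >= min_identity)[0]
            if hits.size:
                assignment[seq] = rep_names[hits[0]]
                continue
        rep_mat[n_reps, :cand.size] = cand
        rep_lens[n_reps] = cand.size
        rep_names.append(seq)
        assignment[seq] = seq
        n_reps += 1
    return assignment


def read_cluster_tsv(path) -> dict[str, str]:
    """Import an MMseqs2 easy-cluster TSV (representative<TAB>member)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["rep", "member"])
    return dict(zip(df["member"], df["rep"]))


def assign_weights(records: list[PeptideRecord],
                   clusters: dict[str, str]) -> list[PeptideRecord]:
    """Attach w = 1 / cluster size; size counts cluster ids over all records.

    Identical peptides presented in several samples each count toward their
    shared cluster, so per-cluster weights sum to one over the full record set.
    """
    ids = []
    for r in records:
        seq = r.peptide.sequence
        if seq not in clusters:
            raise KeyError(f"no cluster assignment for peptide {seq}")
        ids.append(clusters[seq])
    counts = pd.Series(ids).value_counts()
    return [replace(r, cluster_id=cid, weight=1.0 / counts[cid])
            for r, cid in zip(records, ids)]


# ---------------------------------------------------------------------------
# train/validation/test split minimising shared 9mers
# ---------------------------------------------------------------------------

def split_dataset(records: list[PeptideRecord],
                  ratios: tuple[float, float, float] = (8, 1, 1),
                  seed: int = 0):
    """Greedy 8:1:1 split keeping 9mer-sharing records together.

    Records connected by any shared 9mer form a group (union-find); groups are
    placed, largest first with a stable tie order, into the split furthest
    below its target fraction.  Returns (train, val, test, n_leaked_9mers).
    """
    if len(records) < 10:
        raise ValueError("refusing to split fewer than 10 records")
    rng = np.random.default_rng(seed)

    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    owner: dict[str, int] = {}
    for i, r in enumerate(records):
        for k in ninemer_set(r.peptide.sequence):
            if k in owner:
                ri, rj = find(owner[k]), find(i)
                if ri != rj:
                    parent[rj] = ri
            else:
                owner[k] = i

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(records)):
        groups[find(i)].append(i)
    ordered = sorted(groups.values(),
                     key=lambda g: (-len(g),
                                    min(records[i].peptide.sequence for i in g)))

    targets = np.asarray(ratios, dtype=float)
    targets /= targets.sum()
    sizes = np.zeros(3)
    bins: list[list[int]] = [[], [], []]
    total = len(records)
    for g in ordered:
        deficit = targets - sizes / total
        best = np.flatnonzero(deficit == deficit.max())
        choice = best[0] if best.size == 1 else rng.choice(best)
        bins[choice].extend(g)
        sizes[choice] += len(g)

    splits = tuple([records[i] for i in sorted(b)] for b in bins)
    kmer_sets = [set().union(*(ninemer_set(r.peptide.sequence) for r in s))
                 if s else set() for s in splits]
    leaked = (len(kmer_sets[0] & kmer_sets[1]) + len(kmer_sets[0] & kmer_sets[2])
              + len(kmer_sets[1] & kmer_sets[2]))
    return splits[0], splits[1], splits[2], leaked


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peptide_table(path, min_length: int = MIN_PEPTIDE_LEN,
                       max_length: int = MAX_PEPTIDE_LEN) -> list[PeptideRecord]:
    """TSV with columns peptide, sample_id[, label]; out-of-range rows dropped."""
    df = pd.read_csv(path, sep="\t")
    records = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        seq = row.peptide
        if not (min_length <= len(seq) <= max_length):
            n_dropped += 1
            continue
        records.append(PeptideRecord(Peptide(seq), str(row.sample_id),
                                     int(getattr(row, "label", 1))))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} peptide(s) outside "
                      f"[{min_length}, {max_length}] AAs")
    return records


def write_peptide_table(records: list[PeptideRecord], path):
    pd.DataFrame({
        "peptide": [r.peptide.sequence for r in records],
        "sample_id": [r.sample_id for r in records],
        "label": [r.label for r in records],
    }).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path):
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")
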