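"""Evaluation: classification metrics, core accuracy, entropy, contact maps.

F1 is computed from the confusion matrix at the 0.5 presentation cutoff as
2·(precision·recall)/(precision+recall); per-position Shannon entropy of the
predicted binding cores reveals allele anchor preferences (DR-like motifs are
most constrained at core positions 1, 4, 6 and 9); contact maps from crystal
structures (minimum heavy-atom distance < 5 Å) are compared against the
interaction encoder's cross-attention to ask whether the model attends to
structurally contacting groove residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

from .alleles import ALPHA_PSEUDO_LEN, PositionTable
from .seqcore import AA_ALPHABET, CORE_LEN

CONTACT_CUTOFF_ANGSTROM = 5.0


@dataclass(frozen=True)
class CoreAnnotation:
    """Structurally annotated binding core: peptide + true 0-based offset."""

    peptide: str
    core_offset: int
    allele: str

    def __post_init__(self):
        if self.core_offset + CORE_LEN > len(self.peptide):
            raise ValueError("annotated core exceeds the peptide")


@dataclass(frozen=True)
class ContactMap:
    """Boolean peptide-residue × chain-residue contacts (< 5 Å heavy atoms)."""

    contacts: np.ndarray           # (n_pep_res, n_chain_res) bool
    chain_label: str
    cutoff: float = CONTACT_CUTOFF_ANGSTROM


def f1_score_at(scores, labels, threshold: float = 0.5) -> float:
    """F1 = 2·(precision·recall)/(precision+recall) at the given cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def classification_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """F1 at the cutoff, ROC-AUC, PR-AUC (trapezoidal), and TPR."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUCs undefined with a single class "
                         "(use f1_score_at for F1 alone)")
    prec, rec, _ = precision_recall_curve(y, s)
    tpr = float(((s >= threshold) & (y == 1)).sum() / (y == 1).sum())
    return {
        "f1": f1_score_at(s, y, threshold),
        "roc_auc": float(roc_auc_score(y, s)),
        "pr_auc": float(auc(rec, prec)),
        "tpr": tpr,
    }


def per_allele_report(allele_names, scores, labels,
                      threshold: float = 0.5):
    """TPR per monoallelic allele + pooled overall TPR.

    Returns (dict allele → (tpr, n_positives), overall tpr).  Alleles with no
    positives are excluded with a warning.
    """
    names = np.asarray(allele_names)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    table = {}
    hits, total = 0, 0
    for a in sorted(set(names)):
        m = (names == a) & (y == 1)
        n = int(m.sum())
        if n == 0:
            warnings.warn(f"allele {a} has no positives; excluded")
            continue
        h = int((s[m] >= threshold).sum())
        table[a] = (h / n, n)
        hits += h
        total += n
    return table, hits / total if total else float("nan")


def core_accuracy(predicted_offsets, annotations: list[CoreAnnotation],
                  max_supported_len: int = 30):
    """Compare predicted argmax core offsets with structural annotations.

    `predicted_offsets[i]` may be None for unsupported peptides (length
    outside the model range — reported as NA rather than wrong).
    Returns (n_correct, n_wrong, n_unsupported).
    """
    if len(predicted_offsets) != len(annotations):
        raise ValueError("predictions and annotations differ in length")
    correct = wrong = unsupported = 0
    for off, ann in zip(predicted_offsets, annotations):
        if off is None or not CORE_LEN <= len(ann.peptide) <= max_supported_len:
            unsupported += 1
        elif int(off) == ann.core_offset:
            correct += 1
        else:
            wrong += 1
    return correct, wrong, unsupported


def position_entropy(cores: list[str], base: float = 2.0) -> np.ndarray:
    """Shannon entropy of observed residue frequencies per core position.

    Returns a 9-vector; bits by default, bounded by log2 20 ≈ 4.322.
    """
    if not cores:
        raise ValueError("need at least one core")
    if any(len(c) != CORE_LEN for c in cores):
        raise ValueError("all cores must be 9mers")
    aa_index = {a: i for i, a in enumerate(AA_ALPHABET)}
    counts = np.zeros((CORE_LEN, len(AA_ALPHABET)))
    for c in cores:
        for p, a in enumerate(c):
            counts[p, aa_index[a]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    nz = np.where(freq > 0, freq, 1.0)
    return -(freq * np.log(nz) / np.log(base)).sum(axis=1)


# ---------------------------------------------------------------------------
# structure: contacts and attention agreement
# ---------------------------------------------------------------------------

def contact_map(peptide_residues: dict[int, np.ndarray],
                chain_residues: dict[int, np.ndarray],
                cutoff: float = CONTACT_CUTOFF_ANGSTROM,
                chain_label: str = "") -> ContactMap:
    """Contacts from residue-grouped heavy-atom coordinates (strict < cutoff)."""
    pk = sorted(peptide_residues)
    ck = sorted(chain_residues)
    mat = np.zeros((len(pk), len(ck)), dtype=bool)
    for i, pr in enumerate(pk):
        pa = np.atleast_2d(peptide_residues[pr])
        if pa.size == 0:
            warnings.warn(f"peptide residue {pr} has no atoms; skipped")
            continue
        for j, cr in enumerate(ck):
            ca = np.atleast_2d(chain_residues[cr])
            if ca.size == 0:
                warnings.warn(f"chain residue {cr} has no atoms; skipped")
                continue
            mat[i, j] = cdist(pa, ca).min() < cutoff
    return ContactMap(mat, chain_label, cutoff)


def read_pdb_atoms(path) -> dict[str, dict[int, np.ndarray]]:
    """Minimal PDB ATOM-record reader: chain → residue number → heavy-atom xyz.

    Fixed-column parsing of ATOM records only; hydrogens (element H/D) are
    skipped.  Altloc and insertion codes pass through untouched.
    """
    chains: dict[str, dict[int, list]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            element = line[76:78].strip() or line[12:16].strip()[:1]
            if element in ("H", "D"):
                continue
            chain = line[21]
            resnum = int(line[22:26])
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            chains.setdefault(chain, {}).setdefault(resnum, []).append(xyz)
    return {c: {r: np.asarray(v) for r, v in res.items()}
            for c, res in chains.items()}


def contacts_to_pseudo(cmap_alpha: ContactMap, cmap_beta: ContactMap,
                       table: PositionTable) -> np.ndarray:
    """Restrict chain-residue contacts to the 34 pseudo-sequence positions.

    Columns of the chain contact maps are assumed indexed by 0-based mature
    chain position; columns outside the groove table are invisible to the
    model and excluded.  Returns a (9, 34) boolean matrix.
    """
    out = np.zeros((CORE_LEN, 34), dtype=bool)
    for j, pos in enumerate(table.alpha_positions):
        if pos < cmap_alpha.contacts.shape[1]:
            out[:, j] = cmap_alpha.contacts[:CORE_LEN, pos]
    for j, pos in enumerate(table.beta_positions):
        if pos < cmap_beta.contacts.shape[1]:
            out[:, ALPHA_PSEUDO_LEN + j] = cmap_beta.contacts[:CORE_LEN, pos]
    return out


def attention_recovery(attention: np.ndarray, pseudo_contacts: np.ndarray,
                       k: int = 3, mode: str = "per_position"):
    """Fraction of groove contacts recovered by top-k attention values.

    `attention` has shape (n_blocks, n_heads, 9, 34) for one core–allele pair;
    `pseudo_contacts` is the (9, 34) contact matrix restricted to pseudo
    positions.  In ``per_position`` mode each core query position marks its
    top-k attended keys; in ``global`` mode the top-(9·k) cells of the whole
    map are marked.  Returns (per-layer/head matrix, max) — NaN when the
    restricted contact map is empty.
    """
    n_contacts = int(pseudo_contacts.sum())
    L, H = attention.shape[:2]
    rec = np.full((L, H), np.nan)
    if n_contacts == 0:
        return rec, float("nan")
    for l in range(L):
        for h in range(H):
            a = attention[l, h]
            marked = np.zeros_like(pseudo_contacts)
            if mode == "per_position":
                top = np.argsort(a, axis=1)[:, -k:]
                for q in range(a.shape[0]):
                    marked[q, top[q]] = True
            elif mode == "global":
                flat = np.argsort(a, axis=None)[-(a.shape[0] * k):]
                marked.reshape(-1)[flat] = True
            else:
                raise ValueError("mode must be 'per_position' or 'global'")
            rec[l, h] = (marked & pseudo_contacts).sum() / n_contacts
    return rec, float(np.nanmax(rec))
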