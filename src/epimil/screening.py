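"""Antibody immunogenicity screening and neoantigen tiering.

An *epitope* here is a unique 9mer binding core that (i) belongs to a window
of the antibody chain scored as presented (score >= 0.5 against the allele
panel) and (ii) does not occur as a substring of any human germline antibody
sequence — germline cores are tolerated by the immune system and are filtered
out.  The per-antibody epitope count is the immunogenicity feature; a count
cutoff is calibrated by leave-one-out maximisation of Youden's J.  Long
neoantigen peptides are windowed into model-supported lengths and tiered by
their maximal presentation score.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .model import PresentationModel, predict
from .seqcore import CORE_LEN, read_fasta

DEFAULT_WINDOW_SIZES = (9, 12, 13, 14, 15, 16, 17, 18, 19)
ADA_THRESHOLD_PCT = 10.0
PRESENTATION_CUTOFF = 0.5
DEFAULT_TIERS = (0.5, 0.95)
TIER_NAMES = ("not-presented", "low-likelihood", "high-likelihood")


@dataclass(frozen=True)
class ScreenHit:
    """One scored window: final score and the argmax core within the window."""

    score: float
    core_offset: int          # 0-based, relative to the window
    core: str
    allele: str


class WindowScorer(Protocol):
    """Anything that maps a peptide to a ScreenHit (model ensemble or oracle)."""

    def __call__(self, peptide: str) -> ScreenHit: ...


def ensemble_scorer(models: list[PresentationModel], panel) -> WindowScorer:
    """Adapt a model ensemble + allele panel to the WindowScorer interface."""

    def score(peptide: str) -> ScreenHit:
        p = predict(peptide, panel, models)
        return ScreenHit(p.score, p.core_offset, p.core, p.allele)

    return score


class GermlineDB:
    """Exact-substring membership of 9mers in a germline sequence set."""

    def __init__(self, sequences: dict[str, str]):
        self._ninemers: set[str] = set()
        for seq in sequences.values():
            for i in range(len(seq) - CORE_LEN + 1):
                self._ninemers.add(seq[i:i + CORE_LEN])
        digest = hashlib.sha256(
            "".join(sorted(sequences.values())).encode()).hexdigest()
        self.source_digest = digest[:16]

    @classmethod
    def from_fasta(cls, path) -> "GermlineDB":
        return cls(read_fasta(path))

    def __contains__(self, ninemer: str) -> bool:
        return ninemer in self._ninemers

    def __len__(self) -> int:
        return len(self._ninemers)


@dataclass
class EpitopeReport:
    """Per-chain screening result: unique non-germline cores + hotspots."""

    chain_id: str
    epitope_cores: set[str]
    hotspot: np.ndarray            # per-residue max score over covering cores
    window_sizes: tuple[int, ...]

    @property
    def epitope_count(self) -> int:
        return len(self.epitope_cores)


@dataclass(frozen=True)
class ADALabel:
    """Clinical immunogenicity label: immunogenic iff ADA incidence > 10%."""

    antibody_id: str
    ada_fraction: float            # percent of patients developing ADA

    @property
    def immunogenic(self) -> bool:
        return self.ada_fraction > ADA_THRESHOLD_PCT


# ---------------------------------------------------------------------------


def enumerate_screen_windows(chain: str,
                             sizes=DEFAULT_WINDOW_SIZES) -> list[tuple[str, int, int]]:
    """All (sequence, start, size) windows of the requested sizes."""
    out = []
    seen = set()
    for size in sorted(sizes):
        for start in range(len(chain) - size + 1):
            key = (chain[start:start + size], start, size)
            if key not in seen:
                seen.add(key)
                out.append(key)
    if not out:
        warnings.warn(f"chain of length {len(chain)} shorter than every "
                      f"window size; nothing to screen")
    return out


def filter_germline(cores: set[str], db: GermlineDB) -> set[str]:
    """Drop cores that occur verbatim in the germline; idempotent."""
    return {c for c in cores if c not in db}


def screen_chain(chain_id: str, chain: str, scorer: WindowScorer,
                 db: GermlineDB, threshold: float = PRESENTATION_CUTOFF,
                 sizes=DEFAULT_WINDOW_SIZES) -> EpitopeReport:
    """Score every window; collect unique non-germline cores and hotspots."""
    hotspot = np.zeros(len(chain))
    cores: set[str] = set()
    for seq, start, _size in enumerate_screen_windows(chain, sizes):
        hit = scorer(seq)
        if hit.score < threshold:
            continue
        if hit.core in db:
            continue
        cores.add(hit.core)
        lo = start + hit.core_offset
        hi = lo + CORE_LEN
        np.maximum(hotspot[lo:hi], hit.score, out=hotspot[lo:hi])
    return EpitopeReport(chain_id, cores, hotspot, tuple(sorted(sizes)))


def count_epitopes(chains: dict[str, str], scorer: WindowScorer,
                   db: GermlineDB, threshold: float = PRESENTATION_CUTOFF,
                   sizes=DEFAULT_WINDOW_SIZES):
    """Screen every chain; returns ({chain: EpitopeReport}, total unique count).

    The total counts cores unique across all chains of the antibody.
    """
    reports = {cid: screen_chain(cid, seq, scorer, db, threshold, sizes)
               for cid, seq in chains.items()}
    all_cores = set().union(*(r.epitope_cores for r in reports.values())) \
        if reports else set()
    return reports, len(all_cores)


def hotspot_heatmap(report: EpitopeReport) -> np.ndarray:
    """Per-residue score: max over epitope cores covering the residue."""
    return report.hotspot.copy()


def mapps_heatmap(observed_peptides: list[str], chain: str) -> np.ndarray:
    """Experimental coverage: pHLAII count per residue / max count.

    Each observed peptide is aligned by exact substring match; peptides
    matching at several loci contribute coverage to every locus.
    """
    cov = np.zeros(len(chain))
    for pep in observed_peptides:
        start = chain.find(pep)
        if start < 0:
            raise ValueError(f"observed peptide not found in chain: {pep!r}")
        while start >= 0:
            cov[start:start + len(pep)] += 1
            start = chain.find(pep, start + 1)
    top = cov.max()
    return cov / top if top > 0 else cov


# ---------------------------------------------------------------------------
# ADA calibration
# ---------------------------------------------------------------------------

def _youden(counts: np.ndarray, y: np.ndarray, c: float) -> float:
    pred = counts >= c
    return (float((pred & (y == 1)).sum()) / y.sum()
            - float((pred & (y == 0)).sum()) / (1 - y).sum())


def _best_cutoff(counts: np.ndarray, y: np.ndarray) -> float:
    """Cutoff (count >= c ⇒ immunogenic) maximising Youden's J = TPR − FPR.

    Candidates are the observed counts and their successors.  When several
    candidates tie, the midpoint of the optimal plateau is returned (maximal
    margin to both groups), falling back to the smallest tied candidate if
    the plateau is not contiguous.
    """
    candidates = np.unique(np.r_[counts, counts + 1])
    js = np.array([_youden(counts, y, c) for c in candidates])
    best = candidates[js == js.max()]
    mid = float(best.min() + best.max()) / 2.0
    if _youden(counts, y, mid) >= js.max() - 1e-12:
        return mid
    return float(best.min())


def loo_cutoff(epitope_counts: np.ndarray, labels: list[ADALabel]):
    """Leave-one-out calibration of the epitope-count cutoff.

    Per fold, the cutoff maximising Youden's J on the n−1 discovery samples
    is applied to the held-out sample; the overall cutoff is the fold mean and
    F1 is computed from the pooled held-out predictions.
    Returns (mean cutoff, fold cutoffs, F1).
    """
    counts = np.asarray(epitope_counts, dtype=float)
    y = np.array([int(l.immunogenic) for l in labels])
    if len(counts) != len(y):
        raise ValueError("counts and labels differ in length")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least two antibodies per class")
    folds = np.zeros(len(y))
    preds = np.zeros(len(y), dtype=int)
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        folds[i] = _best_cutoff(counts[mask], y[mask])
        preds[i] = int(counts[i] >= folds[i])
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return float(folds.mean()), folds, f1


def resolve_duplicate_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate antibodies with identical sequences.

    Pairs on the same side of the 10% ADA threshold keep one row; pairs that
    straddle it (conflicting labels) are dropped entirely.  Expects columns
    ``sequence`` and ``ada_fraction``.
    """
    keep_rows = []
    for _seq, grp in table.groupby("sequence", sort=False):
        if len(grp) == 1:
            keep_rows.append(grp.index[0])
            continue
        sides = set(grp["ada_fraction"] > ADA_THRESHOLD_PCT)
        if len(sides) == 1:
            keep_rows.append(grp.index[0])
        # else: conflicting labels -> drop all
    return table.loc[sorted(keep_rows)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# neoantigens
# ---------------------------------------------------------------------------

def score_neoantigen(long_peptide: str, scorer: WindowScorer,
                     tiers: tuple[float, float] = DEFAULT_TIERS,
                     sizes=DEFAULT_WINDOW_SIZES):
    """Window a long peptide, score, tier by the maximal presentation score.

    Tier boundaries are inclusive at the lower edge: score >= tiers[1] is
    high-likelihood, tiers[0] <= score < tiers[1] low-likelihood, otherwise
    not-presented.  Returns (score, tier name, best core, core offset in the
    long peptide).
    """
    if len(long_peptide) < CORE_LEN:
        raise ValueError("neoantigen peptide shorter than a 9mer core")
    usable = [s for s in sizes if s <= len(long_peptide)]
    if not usable:
        usable = [CORE_LEN]
    best = None
    for seq, start, _size in enumerate_screen_windows(long_peptide, usable):
        hit = scorer(seq)
        if best is None or hit.score > best[0]:
            best = (hit.score, start + hit.core_offset, hit.core)
    score, off, core = best
    if score >= tiers[1]:
        tier = TIER_NAMES[2]
    elif score >= tiers[0]:
        tier = TIER_NAMES[1]
    else:
        tier = TIER_NAMES[0]
    return score, tier, core, off
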