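"""HLA class II allele registry and pseudo-sequence construction.

An HLA class II molecule is an alpha/beta heterodimer; its peptide-binding
groove is lined by a small set of (mostly polymorphic) residues.  Each allele
is represented compactly by a 34-AA *pseudo-sequence*: 15 groove-lining
residues of the alpha chain followed by 19 of the beta chain.  The residue
positions are read from an editable table (data/groove_positions.txt), so the
groove definition is data rather than code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .seqcore import AA_TO_INDEX

ALPHA_PSEUDO_LEN = 15
BETA_PSEUDO_LEN = 19
PSEUDO_LEN = ALPHA_PSEUDO_LEN + BETA_PSEUDO_LEN  # 34

#: the nine common DR alleles used as the population-representative panel;
#: all pair with the invariant DRA1 alpha chain (DRA1*01:01)
COMMON_DR_ALLELES = (
    "DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*07:01", "DRB1*08:01",
    "DRB1*09:01", "DRB1*11:01", "DRB1*13:01", "DRB1*15:01",
)
DR_ALPHA_CHAIN = "DRA1*01:01"


class AlleleConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleSpec:
    """An HLAII heterodimer with its 34-AA pseudo-sequence."""

    name: str
    alpha_pseudo: str
    beta_pseudo: str

    def __post_init__(self):
        if len(self.alpha_pseudo) != ALPHA_PSEUDO_LEN:
            raise AlleleConstructionError(
                f"{self.name}: alpha pseudo-sequence must be "
                f"{ALPHA_PSEUDO_LEN} AAs, got {len(self.alpha_pseudo)}")
        if len(self.beta_pseudo) != BETA_PSEUDO_LEN:
            raise AlleleConstructionError(
                f"{self.name}: beta pseudo-sequence must be "
                f"{BETA_PSEUDO_LEN} AAs, got {len(self.beta_pseudo)}")
        bad = set(self.pseudo) - set(AA_TO_INDEX)
        if bad:
            raise AlleleConstructionError(
                f"{self.name}: non-canonical residues {sorted(bad)}")

    @property
    def pseudo(self) -> str:
        return self.alpha_pseudo + self.beta_pseudo

    def tokens(self) -> np.ndarray:
        return np.array([AA_TO_INDEX[a] for a in self.pseudo], dtype=np.int64)

    @classmethod
    def from_pseudo(cls, name: str, pseudo: str) -> "AlleleSpec":
        """Build directly from a 34-AA pseudo-sequence (synthetic alleles)."""
        if len(pseudo) != PSEUDO_LEN:
            raise AlleleConstructionError(
                f"{name}: pseudo-sequence must be {PSEUDO_LEN} AAs")
        return cls(name, pseudo[:ALPHA_PSEUDO_LEN], pseudo[ALPHA_PSEUDO_LEN:])


@dataclass(frozen=True)
class PositionTable:
    """Groove-lining positions (0-based internally; 1-based in files)."""

    alpha_positions: tuple[int, ...]
    beta_positions: tuple[int, ...]
    provenance: str = "unspecified"

    def __post_init__(self):
        for label, pos, want in (("alpha", self.alpha_positions, ALPHA_PSEUDO_LEN),
                                 ("beta", self.beta_positions, BETA_PSEUDO_LEN)):
            if len(pos) != want:
                raise AlleleConstructionError(
                    f"{label} position table must have {want} entries")
            if list(pos) != sorted(set(pos)) or min(pos) < 0:
                raise AlleleConstructionError(
                    f"{label} positions must be strictly increasing and >= 0")

    @classmethod
    def from_file(cls, path, provenance: str | None = None) -> "PositionTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    rows.append(tuple(int(x) - 1 for x in line.split()))
        if len(rows) != 2:
            raise AlleleConstructionError(
                "position table file must have two data lines (alpha, beta)")
        return cls(rows[0], rows[1], provenance or str(path))


def default_position_table() -> PositionTable:
    ref = resources.files("epimil.data").joinpath("groove_positions.txt")
    with resources.as_file(ref) as path:
        return PositionTable.from_file(path, provenance="packaged default")


def build_pseudo(name: str, alpha_chain: str, beta_chain: str,
                 table: PositionTable) -> AlleleSpec:
    """Extract groove residues from full chains and concatenate (alpha+beta)."""
    for label, chain, pos in (("alpha", alpha_chain, table.alpha_positions),
                              ("beta", beta_chain, table.beta_positions)):
        if max(pos) >= len(chain):
            raise AlleleConstructionError(
                f"{name}: {label} chain of length {len(chain)} does not cover "
                f"groove position {max(pos) + 1}")
    alpha = "".join(alpha_chain[i] for i in table.alpha_positions)
    beta = "".join(beta_chain[i] for i in table.beta_positions)
    return AlleleSpec(name, alpha, beta)


def common_dr_panel() -> list[str]:
    """Names of the nine common DR alleles (shared DRA1 alpha chain)."""
    return list(COMMON_DR_ALLELES)


# ---------------------------------------------------------------------------
# registry I/O
# ---------------------------------------------------------------------------

def read_registry(path) -> dict[str, AlleleSpec]:
    df = pd.read_csv(path, sep="\t")
    return {row.name_: AlleleSpec(row.name_, row.alpha_pseudo, row.beta_pseudo)
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)}


def write_registry(alleles: dict[str, AlleleSpec], path):
    pd.DataFrame({
        "name": [a.name for a in alleles.values()],
        "alpha_pseudo": [a.alpha_pseudo for a in alleles.values()],
        "beta_pseudo": [a.beta_pseudo for a in alleles.values()],
    }).to_csv(path, sep="\t", index=False)
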