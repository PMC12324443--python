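"""Domain types shared across the toolkit.

Crosslink endpoints are stored in a canonical order (lexicographic by
accession, then residue) so that the same residue pair written in either
direction compares and hashes identically.  Residue coordinates are
1-based positions in the full-length canonical sequence; structures keep
their author numbering and are reconciled by alignment in
:mod:`phixlink.restraints`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class DecoyClass(str, enum.Enum):
    """Target/decoy class of a match: both target, one decoy, both decoys."""

    TT = "TT"
    TD = "TD"
    DD = "DD"

    @property
    def badness(self) -> int:
        return ("TT", "TD", "DD").index(self.value)


def decoy_class_for(protein_a: str, protein_b: str, decoy_prefix: str) -> DecoyClass:
    """Derive the TT/TD/DD class from per-protein decoy prefixes."""
    n = int(protein_a.startswith(decoy_prefix)) + int(protein_b.startswith(decoy_prefix))
    return (DecoyClass.TT, DecoyClass.TD, DecoyClass.DD)[n]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry, possibly a reversed-sequence decoy."""

    accession: str
    sequence: str
    is_decoy: bool = False
    core_subunit: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        bad = set(self.sequence.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue codes {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CrosslinkRecord:
    """One unique crosslinked residue pair, endpoints in canonical order."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    score: float = 0.0
    decoy_class: DecoyClass = DecoyClass.TT
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError("residue positions are 1-based and must be >= 1")
        a = (self.protein_a, self.residue_a)
        b = (self.protein_b, self.residue_b)
        if b < a:
            object.__setattr__(self, "protein_a", b[0])
            object.__setattr__(self, "residue_a", b[1])
            object.__setattr__(self, "protein_b", a[0])
            object.__setattr__(self, "residue_b", a[1])
        if not isinstance(self.decoy_class, DecoyClass):
            object.__setattr__(self, "decoy_class", DecoyClass(self.decoy_class))

    @property
    def is_inter_protein(self) -> bool:
        return self.protein_a != self.protein_b

    @property
    def pair_key(self) -> tuple[str, int, str, int]:
        """Canonical residue-pair identity (ignores score/provenance)."""
        return (self.protein_a, self.residue_a, self.protein_b, self.residue_b)

    @property
    def protein_pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    def with_score(self, score: float) -> "CrosslinkRecord":
        return replace(self, score=score)


@dataclass(frozen=True)
class CandidateMatch(CrosslinkRecord):
    """A crosslink candidate with fragment-evidence counts for prefiltering."""

    n_noncleaved_sda_fragments: int = 0
    n_matches_peptide_a: int = 0
    n_matches_peptide_b: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("n_noncleaved_sda_fragments", "n_matches_peptide_a",
                     "n_matches_peptide_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_crosslink(self) -> CrosslinkRecord:
        return CrosslinkRecord(
            self.protein_a, self.residue_a, self.protein_b, self.residue_b,
            score=self.score, decoy_class=self.decoy_class,
            dataset_id=self.dataset_id)


@dataclass
class Chain:
    """One chain of Cα positions with author residue numbering."""

    chain_id: str
    resnums: np.ndarray          # author residue numbers, strictly increasing
    sequence: str                # one-letter code per retained residue
    coords: np.ndarray           # (n, 3) Cα coordinates in Å

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.resnums)
        if self.coords.shape != (n, 3) or len(self.sequence) != n:
            raise ValueError(f"chain {self.chain_id}: inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"chain {self.chain_id}: non-finite coordinate")
        if n > 1 and not np.all(np.diff(self.resnums) > 0):
            raise ValueError(
                f"chain {self.chain_id}: residue numbers must strictly increase")
        self._index = {int(r): i for i, r in enumerate(self.resnums)}

    def __len__(self) -> int:
        return len(self.resnums)

    def coord_of(self, author_resnum: int) -> np.ndarray | None:
        i = self._index.get(int(author_resnum))
        return None if i is None else self.coords[i]


@dataclass
class StructureModel:
    """Chains of Cα coordinates plus the chain -> protein assignment."""

    model_id: str
    chains: list[Chain]
    chain_to_protein: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {c.chain_id for c in self.chains}
        missing = set(self.chain_to_protein) - ids
        if missing:
            raise ValueError(f"mapped chains absent from model: {sorted(missing)}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def chains_for(self, accession: str) -> list[Chain]:
        """All chain copies assigned to one protein accession."""
        return [c for c in self.chains
                if self.chain_to_protein.get(c.chain_id) == accession]


@dataclass
class QuantMatrix:
    """Protein x sample intensity table with group labels.

    Missing values are NaN; zeros on the raw scale are converted to NaN on
    construction (LFQ convention: a zero is an absent quantification, not an
    abundance).
    """

    intensities: pd.DataFrame      # index: accessions, columns: sample ids
    groups: dict[str, str]         # sample id -> group label
    scale: str = "raw"             # "raw" | "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing = set(self.intensities.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.intensities = self.intensities.astype(float)
        if self.scale == "raw":
            vals = self.intensities.to_numpy()
            vals[vals <= 0] = np.nan
            self.intensities = pd.DataFrame(
                vals, index=self.intensities.index, columns=self.intensities.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def observed_mask(self) -> pd.DataFrame:
        return self.intensities.notna()

    def copy_with(self, intensities: pd.DataFrame, scale: str | None = None) -> "QuantMatrix":
        return QuantMatrix(intensities.copy(), dict(self.groups),
                           scale if scale is not None else self.scale)


@dataclass
class ModelScoreSet:
    """Per-model ipTM/pTM scores for one predicted protein pair."""

    pair_id: tuple[str, ...]
    per_model: list[tuple[float, float]]      # (ipTM, pTM)
    coordinates: list["StructureModel | None"] | None = None

    def __post_init__(self) -> None:
        self.pair_id = tuple(self.pair_id)
        if not self.per_model:
            raise ValueError(f"{self.pair_id}: at least one model required")
        for iptm, ptm in self.per_model:
            if not (0.0 <= iptm <= 1.0 and 0.0 <= ptm <= 1.0):
                raise ValueError(
                    f"{self.pair_id}: ipTM/pTM must lie in [0, 1]")
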