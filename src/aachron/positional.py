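"""Per-protein positional statistics.

Every residue of a protein is assigned its 1-based rank from the
initiation codon (position 1) to the last coded position k (the protein
length; the stop signal is never a position).  For each amino-acid
species the arithmetic mean of its ranks, divided by k, gives the
*size-standardized mean position* (``std_mean`` in (0, 1]): values below
0.5 place the species on average in the 5'-proximal half of the gene,
values above 0.5 in the 3'-proximal half.  Dividing by k makes proteins
of different lengths comparable.

Non-standard residues (X, U, O, B, Z, ...) occupy positions and count
toward k but are excluded from the 20 species profiles.

The per-protein "ro" statistic is the Pearson correlation, over the
species present in the protein, between inclusion-order rank and
standardized mean position; a negative value means recently included
amino acids sit closer to the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alphabet import AMINO_ACID_SET, NONSTANDARD
from .hypotheses import RankTable
from .stats import PearsonResult, pearson

__all__ = [
    "ProteinRecord",
    "PositionProfile",
    "residue_ranks",
    "mean_positions",
    "protein_rank_correlation",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: identifier plus ordered one-letter residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def k(self) -> int:
        """Number of coded positions before the stop signal."""
        return len(self.residues)

    def reversed(self) -> "ProteinRecord":
        return ProteinRecord(id=self.id, residues=self.residues[::-1])


@dataclass(frozen=True)
class PositionProfile:
    """Per-species positional summary of one protein.

    ``count``, ``mean_rank`` and ``std_mean`` are keyed by the one-letter
    codes of the species actually present (plus the non-standard bucket
    in ``count``/``mean_rank`` when such residues occur); absent species
    are missing from the mappings, never stored as zero.
    """

    protein_id: str
    k: int
    count: dict[str, int]
    mean_rank: dict[str, float]
    std_mean: dict[str, float]

    def species_present(self) -> list[str]:
        """Standard species with at least one residue, alphabetical."""
        return sorted(a for a in self.std_mean if a != NONSTANDARD)


def residue_ranks(protein: ProteinRecord) -> dict[str, list[int]]:
    """Assign every residue its 1-based sequence rank, grouped by species.

    Returns a mapping from one-letter code (plus the ``NONSTANDARD``
    bucket when applicable) to the sorted list of ranks occupied by that
    species.  The union of all lists is exactly {1..k}.
    """
    ranks: dict[str, list[int]] = {}
    for pos, residue in enumerate(protein.residues, start=1):
        key = residue if residue in AMINO_ACID_SET else NONSTANDARD
        ranks.setdefault(key, []).append(pos)
    return ranks


def mean_positions(protein: ProteinRecord) -> PositionProfile:
    """Mean 1-based rank per species, size-standardized by protein length.

    For each species present, ``mean_rank`` is the arithmetic mean of its
    ranks and ``std_mean = mean_rank / k``.  The count-weighted mean of
    ``mean_rank`` over all classes (including the non-standard bucket)
    is always (k + 1) / 2.
    """
    ranks = residue_ranks(protein)
    k = protein.k
    count: dict[str, int] = {}
    mean_rank: dict[str, float] = {}
    std_mean: dict[str, float] = {}
    for species, positions in ranks.items():
        count[species] = len(positions)
        mr = float(np.mean(positions))
        mean_rank[species] = mr
        if species != NONSTANDARD:
            std_mean[species] = mr / k
    return PositionProfile(
        protein_id=protein.id, k=k, count=count, mean_rank=mean_rank, std_mean=std_mean
    )


def protein_rank_correlation(
    profile: PositionProfile, ranks: RankTable
) -> Optional[PearsonResult]:
    """Per-protein "ro": Pearson r between inclusion rank and std_mean.

    Computed over the species present in the protein (>= 1 residue, no
    minimum count).  Returns ``None`` — a flagged missing value — when
    fewer than 3 species overlap or either vector is constant.  The
    one-tailed P is for the predicted negative direction.
    """
    species = [a for a in profile.species_present() if a in ranks.ranks]
    if len(species) < 3:
        return None
    x = [float(ranks.ranks[a]) for a in species]
    y = [profile.std_mean[a] for a in species]
    return pearson(x, y, direction="negative")
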