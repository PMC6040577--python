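"""Amino-acid inclusion-order hypotheses for the genetic code.

A :class:`RankTable` assigns every one of the 20 standard amino acids a
positive integer rank: the hypothesized chronological order in which the
amino acid was recruited into the genetic code (1 = earliest; ties are
allowed).  The built-in ``"consensus"`` table is the average of 40
published inclusion-order hypotheses; glycine and alanine open it, and
tryptophan (rank 20) closes it.

Amino acids split into an *early* decade (rank < 11) and a *recent*
decade (rank > 10); under the consensus the tie at rank 11 (Q and I)
falls on the recent side, giving an exact 10/10 partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

from .alphabet import AMINO_ACIDS, AMINO_ACID_SET

__all__ = [
    "RankTable",
    "EpochLabel",
    "CONSENSUS_RANKS",
    "EPOCH_BOUNDARY",
    "consensus_ranks",
    "load_rank_table",
    "save_rank_table",
    "epoch_of",
]

#: Consensus inclusion ranks (average of 40 hypotheses).
CONSENSUS_RANKS: dict[str, int] = {
    "A": 2, "C": 16, "D": 3, "E": 7, "F": 17, "G": 1, "H": 14, "I": 11,
    "K": 15, "L": 8, "M": 19, "N": 12, "P": 5, "Q": 11, "R": 10, "S": 6,
    "T": 8, "V": 4, "W": 20, "Y": 18,
}

#: Early means rank < 11; recent means rank > 10.
EPOCH_BOUNDARY = 11


@dataclass(frozen=True)
class RankTable:
    """A named inclusion-order hypothesis: amino acid -> positive integer rank."""

    name: str
    ranks: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = AMINO_ACID_SET - set(self.ranks)
        if missing:
            raise ValueError(
                f"rank table {self.name!r} missing amino acids: {sorted(missing)}"
            )
        extra = set(self.ranks) - AMINO_ACID_SET
        if extra:
            raise ValueError(
                f"rank table {self.name!r} has unknown codes: {sorted(extra)}"
            )
        for aa, rank in self.ranks.items():
            if int(rank) != rank or rank < 1:
                raise ValueError(
                    f"rank table {self.name!r}: rank for {aa} must be a positive "
                    f"integer, got {rank!r}"
                )
        object.__setattr__(self, "ranks", dict(self.ranks))

    def __getitem__(self, aa: str) -> int:
        return self.ranks[aa]

    def vector(self) -> list[int]:
        """Ranks in canonical (alphabetical) amino-acid order."""
        return [self.ranks[aa] for aa in AMINO_ACIDS]


@dataclass(frozen=True)
class EpochLabel:
    """Partition of the 20 amino acids into 'early' and 'recent'."""

    labels: Mapping[str, str] = field(default_factory=dict)

    @property
    def early(self) -> frozenset[str]:
        return frozenset(a for a, lab in self.labels.items() if lab == "early")

    @property
    def recent(self) -> frozenset[str]:
        return frozenset(a for a, lab in self.labels.items() if lab == "recent")


def consensus_ranks() -> RankTable:
    """The built-in consensus inclusion-order table."""
    return RankTable(name="consensus", ranks=dict(CONSENSUS_RANKS))


def load_rank_table(source: Union[str, Path]) -> RankTable:
    """Load a rank table by registry name or from a two-column TSV file.

    The file format is one ``<amino acid>\\t<rank>`` pair per line;
    lines starting with '#' and a header line ``aa\\trank`` are skipped.
    All 20 standard amino acids must appear exactly once.
    """
    if isinstance(source, str) and source == "consensus":
        return consensus_ranks()
    path = Path(source)
    ranks: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (amino acid, rank), "
                    f"got {len(parts)}"
                )
            aa, rank_str = parts[0].strip().upper(), parts[1].strip()
            if aa in ("AA", "AMINO_ACID") and lineno == 1:
                continue  # header
            if aa not in AMINO_ACID_SET:
                raise ValueError(f"{path}:{lineno}: unknown amino-acid code {aa!r}")
            if aa in ranks:
                raise ValueError(f"{path}:{lineno}: duplicate entry for {aa}")
            try:
                rank = int(rank_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer rank {rank_str!r} for {aa}"
                ) from exc
            ranks[aa] = rank
    missing = AMINO_ACID_SET - set(ranks)
    if missing:
        raise ValueError(f"{path}: missing amino acids: {sorted(missing)}")
    return RankTable(name=path.stem, ranks=ranks)


def save_rank_table(table: RankTable, path: Union[str, Path]) -> None:
    """Write a rank table as two-column TSV (alphabetical amino-acid order)."""
    with open(path, "w") as fh:
        fh.write("aa\trank\n")
        for aa in AMINO_ACIDS:
            fh.write(f"{aa}\t{table.ranks[aa]}\n")


def epoch_of(ranks: RankTable) -> EpochLabel:
    """Label every amino acid early (rank < 11) or recent (rank > 10)."""
    return EpochLabel(
        labels={
            aa: ("early" if ranks.ranks[aa] < EPOCH_BOUNDARY else "recent")
            for aa in AMINO_ACIDS
        }
    )
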