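"""The 20 standard amino acids and the bucket for everything else."""

from __future__ import annotations

#: The 20 standard one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L",
    "M", "N", "P", "Q", "R", "S", "T", "V", "W", "Y",
)

AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Key under which non-standard residues (X, U, O, B, Z, ...) are collected.
#: They occupy sequence positions and count toward the protein length k, but
#: never contribute to any of the 20 species profiles.
NONSTANDARD = "_nonstandard"
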