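"""Residue pairwise contact energies versus inclusion-rank differences.

A :class:`ContactMatrix` is a labeled symmetric 20x20 table of pairwise
amino-acid contact energies (Miyazawa-Jernigan-style statistical
potentials and their derivatives; units and sign convention are dialect
dependent).  The analyses here correlate those energies with the
absolute difference |k1 - k2| in genetic-code inclusion ranks of the
interacting pair:

* per focal amino acid, over the 19 pairs it forms with the other
  species (self-pair excluded);
* between whole matrices (upper triangle, diagonal configurable);
* for the *delta* matrix — hydrophobic-core (intra) energies minus
  polar-surface (inter) energies, entrywise.

A negative focal correlation means the focal residue forms its most
stabilizing contacts with species included at a very different time,
the signature of late amino acids being recruited to stabilize
structures built from early ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .hypotheses import RankTable
from .stats import PearsonResult, pearson

__all__ = [
    "ContactMatrix",
    "read_contact_matrix",
    "write_contact_matrix",
    "rank_diff_matrix",
    "focal_correlations",
    "delta_matrix",
    "matrix_correlation",
]

SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ContactMatrix:
    """Named symmetric 20x20 pairwise contact-energy table."""

    name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        labels = list(df.index)
        if sorted(labels) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"matrix {self.name!r} must be labeled by the 20 standard amino "
                f"acids; got {labels}"
            )
        if list(df.columns) != labels:
            df = df.loc[labels, labels]
        df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
        arr = df.to_numpy()
        asym = np.max(np.abs(arr - arr.T))
        if asym > 1e-6:
            raise ValueError(
                f"matrix {self.name!r} is asymmetric beyond tolerance "
                f"(max |e(a,b)-e(b,a)| = {asym:.3g})"
            )
        if asym > SYMMETRY_TOL:
            warnings.warn(
                f"matrix {self.name!r}: small asymmetry {asym:.3g} symmetrized "
                "by averaging",
                stacklevel=2,
            )
            arr = (arr + arr.T) / 2.0
            df = pd.DataFrame(arr, index=df.index, columns=df.columns)
        object.__setattr__(self, "values", df)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def read_contact_matrix(path: Union[str, Path], name: Optional[str] = None) -> ContactMatrix:
    """Read a labeled 20x20 matrix from whitespace/TSV with a header row.

    The first row holds the 20 column labels; each following row starts
    with its row label.  Asymmetric input beyond 1e-6 is rejected; tiny
    asymmetries (> 1e-9) are symmetrized by averaging with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = [str(i).strip().upper() for i in df.index]
    df.columns = [str(c).strip().upper() for c in df.columns]
    return ContactMatrix(name=name or path.stem, values=df)


def write_contact_matrix(matrix: ContactMatrix, path: Union[str, Path]) -> None:
    """Write a contact matrix as TSV with row and column labels."""
    matrix.values.to_csv(path, sep="\t", float_format="%.10g")


def rank_diff_matrix(ranks: RankTable) -> pd.DataFrame:
    """Absolute inclusion-rank differences d(a, b) = |rank(a) - rank(b)|.

    Zero on the diagonal (and for tied ranks), symmetric, bounded by
    max rank - 1.
    """
    vec = np.array([ranks.ranks[aa] for aa in AMINO_ACIDS], dtype=float)
    diff = np.abs(vec[:, None] - vec[None, :])
    return pd.DataFrame(diff, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


def focal_correlations(
    matrix: ContactMatrix, diffs: pd.DataFrame
) -> pd.DataFrame:
    """Per-species correlation of contact energy with |k1 - k2|.

    For each focal amino acid, Pearson r over exactly 19 points pairing
    e(focal, other) with d(focal, other), the self-pair excluded.
    Returns a frame indexed by focal species with columns ``r``,
    ``p_one_tailed`` (negative direction), ``p_two_tailed`` and ``n``;
    a constant energy row yields NaN (flagged missing).
    """
    if list(diffs.index) != list(AMINO_ACIDS):
        diffs = diffs.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
    rows = []
    for focal in AMINO_ACIDS:
        others = [aa for aa in AMINO_ACIDS if aa != focal]
        e = matrix.values.loc[focal, others].to_numpy(dtype=float)
        d = diffs.loc[focal, others].to_numpy(dtype=float)
        res = pearson(d, e, direction="negative")
        if res is None:
            rows.append({"r": np.nan, "p_one_tailed": np.nan,
                         "p_two_tailed": np.nan, "n": len(others)})
        else:
            rows.append({"r": res.r, "p_one_tailed": res.p_one_tailed,
                         "p_two_tailed": res.p_two_tailed, "n": res.n})
    return pd.DataFrame(rows, index=list(AMINO_ACIDS))


def delta_matrix(intra: ContactMatrix, inter: ContactMatrix) -> ContactMatrix:
    """Entrywise intra - inter: core energies contrasted with surface ones."""
    if list(intra.values.index) != list(inter.values.index):
        raise ValueError("matrices must share the same labels")
    return ContactMatrix(
        name=f"{intra.name}-minus-{inter.name}",
        values=intra.values - inter.values,
    )


def matrix_correlation(
    m1: ContactMatrix,
    m2: ContactMatrix,
    entries: str = "upper+diag",
) -> Optional[PearsonResult]:
    """Pearson r between two contact matrices over their unique entries.

    ``entries`` selects which cells are paired: ``"upper+diag"`` (default,
    210 points), ``"upper"`` (190 off-diagonal pairs) or ``"full"`` (all
    400 cells, each off-diagonal pair counted twice).
    """
    if list(m1.values.index) != list(m2.values.index):
        raise ValueError("matrices must share the same labels")
    a1, a2 = m1.to_numpy(), m2.to_numpy()
    n = a1.shape[0]
    if entries == "upper+diag":
        iu = np.triu_indices(n, k=0)
    elif entries == "upper":
        iu = np.triu_indices(n, k=1)
    elif entries == "full":
        iu = np.indices((n, n)).reshape(2, -1)
    else:
        raise ValueError(f"unknown entries mode {entries!r}")
    return pearson(a1[tuple(iu)], a2[tuple(iu)], direction="positive")
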