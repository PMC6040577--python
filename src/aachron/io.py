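"""Readers and writers for the pipeline's plain-text formats.

FASTA in (protein alphabet, terminal '*' stop symbols stripped before
the length k is computed), TSV out: per-protein profiles, group
manifests and per-protein covariates.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, NONSTANDARD
from .positional import PositionProfile, ProteinRecord

__all__ = [
    "read_fasta",
    "write_profiles",
    "read_profiles",
    "read_group_manifest",
    "read_covariate",
]

log = logging.getLogger("aachron")

_NUCLEOTIDE = set("ACGTN")


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Record ids are the first whitespace-delimited header token; trailing
    '*' stop characters are stripped before k is computed; empty records
    and duplicate ids are rejected.  A record whose residues are >= 95%
    ACGTN triggers a nucleotide-content warning (the unit of analysis is
    the protein sequence).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if "*" in seq:
            raise ValueError(
                f"{path}: record {rec.id!r} has an internal stop symbol"
            )
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        frac_nt = sum(1 for c in seq if c in _NUCLEOTIDE) / len(seq)
        if frac_nt >= 0.95:
            warnings.warn(
                f"{path}: record {rec.id!r} looks like nucleotide sequence "
                f"({frac_nt:.0%} ACGTN)",
                stacklevel=2,
            )
        records.append(ProteinRecord(id=rec.id, residues=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    log.info("read %d protein records from %s", len(records), path)
    return records


def write_profiles(
    profiles: list[PositionProfile],
    path: Union[str, Path],
    times100: bool = False,
) -> None:
    """One row per protein: k, per-species std_mean and counts.

    ``times100`` applies the x100 presentation scaling to std_mean
    columns; computation always stays full precision.
    """
    rows = []
    for p in profiles:
        row: dict[str, object] = {"protein_id": p.protein_id, "k": p.k}
        for aa in AMINO_ACIDS:
            v = p.std_mean.get(aa)
            row[f"std_{aa}"] = (
                "" if v is None else f"{v * 100:.10g}" if times100 else f"{v:.12g}"
            )
            row[f"n_{aa}"] = p.count.get(aa, 0)
        row["n_other"] = p.count.get(NONSTANDARD, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: Union[str, Path]) -> list[PositionProfile]:
    """Re-read a full-precision profile TSV written by :func:`write_profiles`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    profiles = []
    for _, row in df.iterrows():
        k = int(row["k"])
        count: dict[str, int] = {}
        mean_rank: dict[str, float] = {}
        std_mean: dict[str, float] = {}
        for aa in AMINO_ACIDS:
            n = int(row[f"n_{aa}"])
            if n == 0:
                continue
            count[aa] = n
            std = float(row[f"std_{aa}"])
            std_mean[aa] = std
            mean_rank[aa] = std * k
        n_other = int(row.get("n_other", 0))
        if n_other:
            count[NONSTANDARD] = n_other
            # mean rank of the bucket is recoverable from conservation
            total = k * (k + 1) / 2
            assigned = sum(count[aa] * mean_rank[aa] for aa in std_mean)
            mean_rank[NONSTANDARD] = (total - assigned) / n_other
        profiles.append(
            PositionProfile(
                protein_id=str(row["protein_id"]),
                k=k,
                count=count,
                mean_rank=mean_rank,
                std_mean=std_mean,
            )
        )
    return profiles


def read_group_manifest(path: Union[str, Path]) -> dict[str, str]:
    """Two-column TSV (protein_id, group_name) -> mapping id -> group."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: group manifest needs two columns")
    id_col, grp_col = df.columns[:2]
    dup = df[id_col][df[id_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate protein ids: {sorted(set(dup))}")
    return dict(zip(df[id_col], df[grp_col]))


def read_covariate(path: Union[str, Path]) -> dict[str, float]:
    """Two-column TSV (protein_id, value) -> mapping id -> float value."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: covariate file needs two columns")
    id_col, val_col = df.columns[:2]
    return {str(i): float(v) for i, v in zip(df[id_col], df[val_col])}
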