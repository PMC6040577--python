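"""Group-level aggregation of per-protein positional profiles.

A *group* is a set of related proteins (e.g. class I tRNA synthetases,
ribosomal proteins, the 13 mitogenome-encoded proteins).  For each group
and each amino-acid species we count how many proteins place that
species, on average, in the 5' half (std_mean < 0.5, strict), run an
exact sign test on that count, and correlate inclusion rank with

* R_n — the fraction of proteins with std_mean < 0.5, and
* R_m — the group mean of std_mean.

Species absent from a protein contribute nothing to that protein's
tally, so per-species denominators can be smaller than the group size.

Across groups, grand means per species (unweighted over groups by
default) feed the epoch majority test: early amino acids (inclusion
rank < 11) are predicted to sit 3'-ward (grand mean > 0.5) and recent
ones 5'-ward (grand mean < 0.5); the count of conforming species goes
into an exact sign test, and per-species sign-test P values are
Fisher-combined separately within the early and recent decades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .hypotheses import EpochLabel, RankTable
from .positional import PositionProfile, protein_rank_correlation
from .stats import (
    CombinedP,
    PearsonResult,
    SignTestResult,
    fisher_combine,
    pearson,
    sign_test,
    spearman,
)

__all__ = [
    "GroupSummary",
    "CrossGroupResult",
    "EpochTestResult",
    "CovariateResult",
    "summarize_group",
    "cross_group_mean",
    "epoch_majority_test",
    "covariate_correlation",
]

#: Midpoint of the standardized position scale; strict '<' counts as 5'-ward.
MIDPOINT = 0.5


@dataclass(frozen=True)
class GroupSummary:
    """Per-group aggregation over proteins.

    ``table`` is indexed by the 20 amino acids with columns:

    n_present
        proteins in which the species occurs at least once
    n_below
        proteins with std_mean < 0.5 (strict) for that species
    frac_below
        n_below / n_present (NaN when the species occurs nowhere)
    mean_std
        group mean of std_mean over proteins containing the species
    sign_p_one / sign_p_two
        exact sign test of n_below against n_present at p = 1/2
    """

    name: str
    n_proteins: int
    table: pd.DataFrame
    r_n: Optional[PearsonResult]
    r_m: Optional[PearsonResult]
    protein_r: dict[str, Optional[PearsonResult]]

    def ro_values(self) -> dict[str, float]:
        """Per-protein "ro" correlations (NaN where flagged missing)."""
        return {
            pid: (np.nan if res is None else res.r)
            for pid, res in self.protein_r.items()
        }


@dataclass(frozen=True)
class CrossGroupResult:
    """Grand per-species means across groups and their rank correlation."""

    grand_means: pd.Series
    correlation: Optional[PearsonResult]
    excluded: tuple[str, ...]
    weighted: bool


@dataclass(frozen=True)
class EpochTestResult:
    """Majority test of the early-3'/recent-5' prediction on grand means."""

    conforming: dict[str, bool]
    sign: SignTestResult
    fisher_early: CombinedP
    fisher_recent: CombinedP


@dataclass(frozen=True)
class CovariateResult:
    """Correlation of per-protein gradient strength with a covariate."""

    covariate: str
    n_used: int
    n_dropped: int
    pairs: list[tuple[str, float, float]]
    pearson: Optional[PearsonResult]
    spearman: Optional[PearsonResult]


def summarize_group(
    profiles: Sequence[PositionProfile],
    ranks: RankTable,
    name: str = "group",
) -> GroupSummary:
    """Aggregate per-protein profiles into a group summary.

    Requires at least 2 profiles.  Counts use the strict inequality
    std_mean < 0.5; a species exactly at the midpoint is not 5'-ward.
    """
    if len(profiles) < 2:
        raise ValueError(f"group {name!r} needs >= 2 proteins, got {len(profiles)}")

    rows = []
    for aa in AMINO_ACIDS:
        values = [p.std_mean[aa] for p in profiles if aa in p.std_mean]
        n_present = len(values)
        n_below = sum(1 for v in values if v < MIDPOINT)
        if n_present:
            st = sign_test(n_below, n_present)
            p_one, p_two = st.p_one_tailed, st.p_two_tailed
            frac = n_below / n_present
            mean_std = float(np.mean(values))
        else:
            p_one = p_two = frac = mean_std = np.nan
        rows.append(
            {
                "n_present": n_present,
                "n_below": n_below,
                "frac_below": frac,
                "mean_std": mean_std,
                "sign_p_one": p_one,
                "sign_p_two": p_two,
            }
        )
    table = pd.DataFrame(rows, index=list(AMINO_ACIDS))

    rank_vec = np.array([ranks.ranks[aa] for aa in AMINO_ACIDS], dtype=float)
    # recent species sitting 5'-ward raise frac_below, so the predicted
    # direction for R_n is positive (and negative for R_m)
    r_n = pearson(rank_vec, table["frac_below"].to_numpy(), direction="positive")
    r_m = pearson(rank_vec, table["mean_std"].to_numpy(), direction="negative")

    protein_r = {p.protein_id: protein_rank_correlation(p, ranks) for p in profiles}

    return GroupSummary(
        name=name,
        n_proteins=len(profiles),
        table=table,
        r_n=r_n,
        r_m=r_m,
        protein_r=protein_r,
    )


def cross_group_mean(
    summaries: Sequence[GroupSummary],
    ranks: RankTable,
    exclude: Iterable[str] = (),
    weighted: bool = False,
) -> CrossGroupResult:
    """Per-species grand means across groups, correlated with inclusion rank.

    By default groups are weighted equally regardless of size; with
    ``weighted=True`` group means are weighted by the number of proteins
    containing the species.  ``exclude`` removes species (e.g. "M") from
    the correlation only — grand means are reported for all 20.
    """
    if len(summaries) < 2:
        raise ValueError(f"need >= 2 groups, got {len(summaries)}")
    excluded = tuple(sorted(set(exclude)))

    means = pd.DataFrame({s.name: s.table["mean_std"] for s in summaries})
    if weighted:
        weights = pd.DataFrame({s.name: s.table["n_present"] for s in summaries})
        weights = weights.where(means.notna(), 0.0)
        grand = (means.fillna(0.0) * weights).sum(axis=1) / weights.sum(axis=1)
    else:
        grand = means.mean(axis=1, skipna=True)
    grand.name = "grand_mean_std"

    keep = [aa for aa in AMINO_ACIDS if aa not in excluded and np.isfinite(grand[aa])]
    corr = pearson(
        [float(ranks.ranks[aa]) for aa in keep],
        [float(grand[aa]) for aa in keep],
        direction="negative",
    )
    return CrossGroupResult(
        grand_means=grand, correlation=corr, excluded=excluded, weighted=weighted
    )


def epoch_majority_test(
    summaries: Sequence[GroupSummary],
    epoch: EpochLabel,
    weighted: bool = False,
) -> EpochTestResult:
    """Sign test of the early-3'/recent-5' prediction across all 20 species.

    A species conforms when its grand mean std_mean lies strictly on the
    predicted side of 0.5 (early > 0.5, recent < 0.5; a value exactly at
    the midpoint is non-conforming).  The conforming count over 20 feeds
    an exact sign test.  Separately, per-species one-tailed sign tests in
    the predicted direction — on protein counts pooled across groups —
    are Fisher-combined within the early set and within the recent set.
    """
    means = pd.DataFrame({s.name: s.table["mean_std"] for s in summaries})
    if weighted:
        weights = pd.DataFrame({s.name: s.table["n_present"] for s in summaries})
        weights = weights.where(means.notna(), 0.0)
        grand = (means.fillna(0.0) * weights).sum(axis=1) / weights.sum(axis=1)
    else:
        grand = means.mean(axis=1, skipna=True)
    if not np.all(np.isfinite(grand.to_numpy())):
        missing = [aa for aa in AMINO_ACIDS if not np.isfinite(grand[aa])]
        raise ValueError(f"grand means unavailable for species: {missing}")

    conforming: dict[str, bool] = {}
    for aa in AMINO_ACIDS:
        if aa in epoch.early:
            conforming[aa] = bool(grand[aa] > MIDPOINT)
        else:
            conforming[aa] = bool(grand[aa] < MIDPOINT)
    majority = sign_test(sum(conforming.values()), len(conforming))

    # Pooled per-species counts across groups, tested in the predicted
    # direction, then combined within each epoch.
    n_present = sum(s.table["n_present"] for s in summaries)
    n_below = sum(s.table["n_below"] for s in summaries)
    per_species_p: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        n = int(n_present[aa])
        below = int(n_below[aa])
        if n == 0:
            per_species_p[aa] = 1.0
            continue
        successes = below if aa in epoch.recent else n - below
        per_species_p[aa] = sign_test(successes, n).p_one_tailed

    fisher_early = fisher_combine([per_species_p[aa] for aa in sorted(epoch.early)])
    fisher_recent = fisher_combine([per_species_p[aa] for aa in sorted(epoch.recent)])
    return EpochTestResult(
        conforming=conforming,
        sign=majority,
        fisher_early=fisher_early,
        fisher_recent=fisher_recent,
    )


def covariate_correlation(
    per_protein_r: Mapping[str, float],
    covariate: Mapping[str, float],
    name: str = "covariate",
) -> CovariateResult:
    """Correlate per-protein "ro" values with a per-protein covariate.

    Pairing is by protein id; proteins missing either value (or with a
    flagged-missing ro) are dropped and counted.  Both Pearson r and
    Spearman rs are reported with one-tailed P in the negative direction.
    """
    pairs: list[tuple[str, float, float]] = []
    dropped = 0
    all_ids = set(per_protein_r) | set(covariate)
    for pid in sorted(all_ids):
        r = per_protein_r.get(pid, np.nan)
        c = covariate.get(pid, np.nan)
        if np.isfinite(r) and np.isfinite(c):
            pairs.append((pid, float(r), float(c)))
        else:
            dropped += 1
    if len(pairs) < 3:
        return CovariateResult(
            covariate=name, n_used=len(pairs), n_dropped=dropped,
            pairs=pairs, pearson=None, spearman=None,
        )
    rs = [p[1] for p in pairs]
    cs = [p[2] for p in pairs]
    return CovariateResult(
        covariate=name,
        n_used=len(pairs),
        n_dropped=dropped,
        pairs=pairs,
        pearson=pearson(cs, rs, direction="negative"),
        spearman=spearman(cs, rs, direction="negative"),
    )
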