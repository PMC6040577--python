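"""End-to-end pipeline: FASTA in, profile/group/epoch reports out.

All computation and the JSON summary are full precision; the x100
rounding of the tabular reports is presentation only, applied in the
report writers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .groups import (
    CovariateResult,
    GroupSummary,
    covariate_correlation,
    cross_group_mean,
    epoch_majority_test,
    summarize_group,
)
from .hypotheses import RankTable, consensus_ranks, epoch_of, load_rank_table
from .io import read_covariate, read_fasta, read_group_manifest, write_profiles
from .positional import mean_positions

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("aachron")


@dataclass
class RunConfig:
    """Paths and flags for one pipeline run."""

    fasta: Union[str, Path]
    outdir: Union[str, Path]
    groups: Optional[Union[str, Path]] = None
    ranks: Union[str, Path] = "consensus"
    covariate: Optional[Union[str, Path]] = None
    covariate_name: str = "covariate"
    times100: bool = True
    exclude_from_cross: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for label, p in (("fasta", self.fasta), ("groups", self.groups),
                         ("covariate", self.covariate)):
            if p is not None and label != "ranks" and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.ranks != "consensus" and not Path(self.ranks).exists():
            raise FileNotFoundError(f"ranks file not found: {self.ranks}")


def _corr_dict(res) -> Optional[dict]:
    if res is None:
        return None
    return {
        "r": res.r,
        "p_one_tailed": res.p_one_tailed,
        "p_two_tailed": res.p_two_tailed,
        "n": res.n,
        "direction": res.direction,
    }


def _write_group_report(
    summary: GroupSummary, ranks: RankTable, path: Path, times100: bool
) -> None:
    t = summary.table.copy()
    if times100:
        t["frac_below"] = (t["frac_below"] * 100).round(1)
        t["mean_std"] = (t["mean_std"] * 100).round(0)
        t["sign_p_two"] = (t["sign_p_two"] * 100).round(4)
    t.insert(0, "rank", [ranks.ranks[aa] for aa in AMINO_ACIDS])
    t.to_csv(path, sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the inputs allow and write reports.

    Always emits a per-protein profile TSV and per-protein "ro" table;
    with a group manifest adds per-group summaries, the cross-group
    means and the epoch majority test; with a covariate file adds the
    covariate correlation.  A machine-readable ``summary.json`` holds
    every r, P and count at full precision.  Returns the summary dict.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ranks = (
        consensus_ranks() if config.ranks == "consensus" else load_rank_table(config.ranks)
    )
    proteins = read_fasta(config.fasta)
    profiles = [mean_positions(p) for p in proteins]
    write_profiles(profiles, outdir / "profiles.tsv")
    if config.times100:
        write_profiles(profiles, outdir / "profiles_x100.tsv", times100=True)

    summary: dict = {
        "n_proteins": len(proteins),
        "ranks": ranks.name,
        "seed": config.seed,
        "dropped": [],
        "flagged_missing": [],
    }

    from .positional import protein_rank_correlation

    per_protein = {p.protein_id: protein_rank_correlation(p, ranks) for p in profiles}
    for pid, res in per_protein.items():
        if res is None:
            summary["flagged_missing"].append(f"ro:{pid}")
            log.info("ro flagged missing for protein %s", pid)
    pd.DataFrame(
        [
            {
                "protein_id": pid,
                "ro": np.nan if r is None else r.r,
                "p_one_tailed": np.nan if r is None else r.p_one_tailed,
            }
            for pid, r in per_protein.items()
        ]
    ).to_csv(outdir / "per_protein_ro.tsv", sep="\t", index=False)
    summary["per_protein_ro"] = {
        pid: (None if r is None else r.r) for pid, r in per_protein.items()
    }

    if config.groups is not None:
        manifest = read_group_manifest(config.groups)
        unmatched = [p.protein_id for p in profiles if p.protein_id not in manifest]
        for pid in unmatched:
            log.info("protein %s not in group manifest; dropped from grouping", pid)
        summary["dropped"].extend(f"grouping:{pid}" for pid in unmatched)

        by_group: dict[str, list] = {}
        for prof in profiles:
            g = manifest.get(prof.protein_id)
            if g is not None:
                by_group.setdefault(g, []).append(prof)
        summaries = []
        summary["groups"] = {}
        for gname in sorted(by_group):
            members = by_group[gname]
            if len(members) < 2:
                log.warning("group %s has < 2 proteins; skipped", gname)
                continue
            gs = summarize_group(members, ranks, name=gname)
            summaries.append(gs)
            log.info("group %s: %d proteins", gname, gs.n_proteins)
            _write_group_report(
                gs, ranks, outdir / f"group_{gname}.tsv", config.times100
            )
            gs.table.to_csv(outdir / f"group_{gname}_full.tsv", sep="\t")
            summary["groups"][gname] = {
                "n_proteins": gs.n_proteins,
                "R_n": _corr_dict(gs.r_n),
                "R_m": _corr_dict(gs.r_m),
            }
        if len(summaries) >= 2:
            cross = cross_group_mean(
                summaries, ranks, exclude=config.exclude_from_cross
            )
            cross.grand_means.to_csv(outdir / "grand_means.tsv", sep="\t")
            epoch = epoch_majority_test(summaries, epoch_of(ranks))
            summary["cross_group"] = {
                "grand_means": cross.grand_means.to_dict(),
                "correlation": _corr_dict(cross.correlation),
                "excluded": list(cross.excluded),
            }
            summary["epoch_test"] = {
                "conforming": int(epoch.sign.s),
                "n_species": int(epoch.sign.n),
                "p_one_tailed": epoch.sign.p_one_tailed,
                "fisher_early_p": epoch.fisher_early.p,
                "fisher_recent_p": epoch.fisher_recent.p,
            }

    if config.covariate is not None:
        cov = read_covariate(config.covariate)
        result: CovariateResult = covariate_correlation(
            {pid: (np.nan if r is None else r.r) for pid, r in per_protein.items()},
            cov,
            name=config.covariate_name,
        )
        summary["covariate"] = {
            "name": result.covariate,
            "n_used": result.n_used,
            "n_dropped": result.n_dropped,
            "pearson": _corr_dict(result.pearson),
            "spearman": _corr_dict(result.spearman),
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
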