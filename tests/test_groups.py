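"""Group aggregation, cross-group means, epoch test, covariates."""

import numpy as np
import pandas as pd
import pytest

from aachron import (
    AMINO_ACIDS,
    GradientConfig,
    GroupSummary,
    ProteinRecord,
    consensus_ranks,
    covariate_correlation,
    cross_group_mean,
    epoch_majority_test,
    epoch_of,
    generate_proteins,
    mean_positions,
    summarize_group,
)
from aachron.hypotheses import EpochLabel
from conftest import brute_pearson


def make_summary(mean_std, n_present=10, n_below=5, name="fake"):
    """Directly assemble a GroupSummary from prescribed per-species values."""
    table = pd.DataFrame(
        {
            "n_present": {aa: n_present for aa in AMINO_ACIDS},
            "n_below": {aa: n_below for aa in AMINO_ACIDS},
            "frac_below": {aa: n_below / n_present for aa in AMINO_ACIDS},
            "mean_std": {aa: mean_std[aa] for aa in AMINO_ACIDS},
            "sign_p_one": {aa: 1.0 for aa in AMINO_ACIDS},
            "sign_p_two": {aa: 1.0 for aa in AMINO_ACIDS},
        }
    ).loc[list(AMINO_ACIDS)]
    return GroupSummary(
        name=name, n_proteins=n_present, table=table, r_n=None, r_m=None,
        protein_r={},
    )


@pytest.fixture
def synthetic_profiles():
    cfg = GradientConfig(beta=1.0, n_proteins=12, length=200, seed=101)
    return [mean_positions(p) for p in generate_proteins(cfg)]


class TestSummarizeGroup:
    def test_identical_proteins_tally_all_or_nothing(self, example_protein):
        profiles = [
            mean_positions(ProteinRecord(f"p{i}", example_protein.residues))
            for i in range(5)
        ]
        gs = summarize_group(profiles, consensus_ranks())
        t = gs.table
        # M's std_mean 0.269 < 0.5, so every protein counts below
        assert t.loc["M", "n_below"] == t.loc["M", "n_present"] == 5
        present = t["n_present"] > 0
        assert ((t.loc[present, "n_below"] == 0)
                | (t.loc[present, "n_below"] == t.loc[present, "n_present"])).all()

    def test_absent_species_reduce_denominator(self, example_protein):
        profiles = [
            mean_positions(ProteinRecord("a", example_protein.residues)),
            mean_positions(ProteinRecord("b", "GAGAWAGA")),
        ]
        gs = summarize_group(profiles, consensus_ranks())
        assert gs.table.loc["W", "n_present"] == 1
        assert gs.table.loc["M", "n_present"] == 1
        assert gs.table.loc["G", "n_present"] == 2

    def test_duplicated_profile_rm_matches_single_profile_correlation(
        self, synthetic_profiles
    ):
        prof = synthetic_profiles[0]
        twin = [prof, prof]
        gs = summarize_group(twin, consensus_ranks())
        species = prof.species_present()
        expected = brute_pearson(
            [consensus_ranks().ranks[a] for a in species],
            [prof.std_mean[a] for a in species],
        )
        assert gs.r_m.r == pytest.approx(expected, abs=1e-12)

    def test_order_invariance(self, synthetic_profiles):
        gs1 = summarize_group(synthetic_profiles, consensus_ranks())
        gs2 = summarize_group(synthetic_profiles[::-1], consensus_ranks())
        pd.testing.assert_frame_equal(gs1.table, gs2.table)
        assert gs1.r_m.r == pytest.approx(gs2.r_m.r, abs=1e-12)

    def test_total_below_bounded(self, synthetic_profiles):
        gs = summarize_group(synthetic_profiles, consensus_ranks())
        assert gs.table["n_below"].sum() <= 20 * len(synthetic_profiles)
        assert (gs.table["n_below"] <= gs.table["n_present"]).all()

    def test_small_group_rejected(self, synthetic_profiles):
        with pytest.raises(ValueError):
            summarize_group(synthetic_profiles[:1], consensus_ranks())

    def test_shuffled_composition_calibrates_sign_tests(self):
        """Uniform shuffles of one composition keep per-species fractions
        near 1/2 and sign tests almost always non-significant at n = 50."""
        rng = np.random.default_rng(77)
        base = list("ACDEFGHIKLMNPQRSTVWY" * 8)  # every species present
        sig = total = 0
        for _ in range(10):
            profiles = []
            for i in range(50):
                rng.shuffle(base)
                profiles.append(mean_positions(ProteinRecord(f"p{i}", "".join(base))))
            gs = summarize_group(profiles, consensus_ranks())
            sig += int((gs.table["sign_p_two"] < 0.05).sum())
            total += 20
        # discrete test at n=50 has attainable level < 0.05
        assert sig / total < 0.10


class TestCrossGroupMean:
    def test_identical_groups_preserve_group_mean(self, synthetic_profiles):
        gs = summarize_group(synthetic_profiles, consensus_ranks())
        res = cross_group_mean([gs, gs], consensus_ranks())
        pd.testing.assert_series_equal(
            res.grand_means, gs.table["mean_std"],
            check_names=False,
        )

    def test_decreasing_means_give_minus_one(self):
        ranks = consensus_ranks()
        means = {aa: 1.0 - 0.02 * ranks.ranks[aa] for aa in AMINO_ACIDS}
        s = make_summary(means)
        res = cross_group_mean([s, s], ranks)
        assert res.correlation.r == pytest.approx(-1.0)

    def test_exclusion_drops_species_from_correlation_only(self):
        ranks = consensus_ranks()
        means = {aa: 1.0 - 0.02 * ranks.ranks[aa] for aa in AMINO_ACIDS}
        means["M"] = 0.99  # outlier
        s = make_summary(means)
        with_m = cross_group_mean([s, s], ranks)
        without_m = cross_group_mean([s, s], ranks, exclude=("M",))
        assert without_m.correlation.r == pytest.approx(-1.0)
        assert with_m.correlation.r > -1.0
        assert "M" in without_m.grand_means.index

    def test_gradient_groups_recover_negative_correlation(self):
        """Eight synthetic groups generated with a positive gradient yield a
        negative rank correlation of the grand means."""
        ranks = consensus_ranks()
        summaries = []
        for g in range(8):
            cfg = GradientConfig(beta=1.0, n_proteins=10, length=200, seed=500 + g)
            profiles = [mean_positions(p) for p in generate_proteins(cfg)]
            summaries.append(summarize_group(profiles, ranks, name=f"g{g}"))
        res = cross_group_mean(summaries, ranks)
        assert res.correlation.r < 0
        assert res.correlation.p_one_tailed < 0.05


class TestEpochMajority:
    def test_sixteen_conforming_matches_published_tail(self):
        ranks = consensus_ranks()
        epoch = epoch_of(ranks)
        means = {}
        for aa in AMINO_ACIDS:
            means[aa] = 0.6 if aa in epoch.early else 0.4
        # flip 4 species to non-conforming
        for aa in ("G", "A", "C", "W"):
            means[aa] = 1.0 - means[aa]
        res = epoch_majority_test([make_summary(means)] * 2, epoch)
        assert res.sign.s == 16
        assert res.sign.p_one_tailed == pytest.approx(0.0059, abs=5e-5)

    def test_all_conforming(self):
        ranks = consensus_ranks()
        epoch = epoch_of(ranks)
        means = {aa: (0.6 if aa in epoch.early else 0.4) for aa in AMINO_ACIDS}
        res = epoch_majority_test([make_summary(means)] * 2, epoch)
        assert res.sign.s == 20
        assert res.sign.p_one_tailed == pytest.approx(0.5**20)

    def test_midpoint_is_nonconforming(self):
        epoch = epoch_of(consensus_ranks())
        means = {aa: 0.5 for aa in AMINO_ACIDS}
        res = epoch_majority_test([make_summary(means)] * 2, epoch)
        assert res.sign.s == 0
        assert res.sign.p_one_tailed == 1.0

    def test_flipped_labels_complement_count(self):
        ranks = consensus_ranks()
        epoch = epoch_of(ranks)
        rng = np.random.default_rng(9)
        means = {aa: float(rng.uniform(0.3, 0.7)) for aa in AMINO_ACIDS}
        flipped = EpochLabel(
            labels={aa: ("recent" if lab == "early" else "early")
                    for aa, lab in epoch.labels.items()}
        )
        s1 = epoch_majority_test([make_summary(means)] * 2, epoch).sign.s
        s2 = epoch_majority_test([make_summary(means)] * 2, flipped).sign.s
        assert s1 + s2 == 20

    def test_fisher_combinations_cover_both_decades(self, synthetic_profiles):
        ranks = consensus_ranks()
        gs = summarize_group(synthetic_profiles, ranks)
        res = epoch_majority_test([gs, gs], epoch_of(ranks))
        assert res.fisher_early.df == 20
        assert res.fisher_recent.df == 20
        assert 0 < res.fisher_early.p <= 1


class TestCovariate:
    def test_identity_covariate_perfect_correlation(self):
        ro = {f"p{i}": -0.1 * i for i in range(8)}
        res = covariate_correlation(ro, dict(ro))
        assert res.pearson.r == pytest.approx(1.0)
        assert res.n_used == 8
        assert res.n_dropped == 0

    def test_constant_covariate_flagged_missing(self):
        ro = {f"p{i}": -0.1 * i for i in range(8)}
        res = covariate_correlation(ro, {k: 3.0 for k in ro})
        assert res.pearson is None

    def test_unmatched_proteins_dropped_and_counted(self):
        ro = {"a": -0.5, "b": -0.2, "c": 0.1, "d": float("nan")}
        cov = {"a": 1.0, "b": 2.0, "c": 3.0, "e": 4.0}
        res = covariate_correlation(ro, cov)
        assert res.n_used == 3
        assert res.n_dropped == 2  # d (NaN ro) and e (no ro)

    def test_gradient_strength_tracks_covariate(self):
        """13 proteins whose gradient strengthens with a mutation-rate-like
        covariate recover the negative ro-vs-covariate correlation."""
        ranks = consensus_ranks()
        ro = {}
        cov = {}
        for i in range(13):
            beta = 0.25 * i  # gradient strength rises with the covariate
            cfg = GradientConfig(beta=beta, n_proteins=1, length=500, seed=900 + i)
            profile = mean_positions(generate_proteins(cfg)[0])
            from aachron import protein_rank_correlation

            res = protein_rank_correlation(profile, ranks)
            ro[f"p{i}"] = res.r
            cov[f"p{i}"] = float(i + 1)  # ranked covariate
        result = covariate_correlation(ro, cov)
        assert result.pearson.r < 0
        assert result.pearson.p_one_tailed < 0.05
        assert result.spearman.r < 0
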