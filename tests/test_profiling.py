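"""Tests for cluster physicochemical profiles, composition and comparisons."""

import numpy as np
import pytest

from pepfocus.hier_clustering import ClusterModel
from pepfocus.library_design import encode, enumerate_tripeptides, scale
from pepfocus.profiling import (
    cluster_profile,
    compare_profiles,
    composition,
)


def model_over(peptides, assignment):
    assignment = np.asarray(assignment)
    return ClusterModel(
        peptides=tuple(peptides), assignment=assignment, K=int(assignment.max())
    )


@pytest.fixture(scope="module")
def scaled_features(table):
    return scale(encode(enumerate_tripeptides(), table))


@pytest.fixture(scope="module")
def full_peptides():
    return enumerate_tripeptides()


class TestClusterProfile:
    def test_requires_scaled_features(self, table):
        fm = encode(["AAA", "CCC"], table)
        model = model_over(["AAA", "CCC"], [1, 2])
        with pytest.raises(ValueError, match="scaled"):
            cluster_profile(model, fm, 1)

    def test_singleton_cluster_zero_sd(self, scaled_features, full_peptides):
        assignment = np.ones(len(full_peptides), dtype=int)
        assignment[full_peptides.index("WNY")] = 2
        model = model_over(full_peptides, assignment)
        prof = cluster_profile(model, scaled_features, 2)
        assert prof.peptides == ("WNY",)
        assert (prof.profile.sd == 0).all()

    def test_homotrimer_cluster_position_symmetry(self, scaled_features, full_peptides):
        assignment = np.ones(len(full_peptides), dtype=int)
        for h in ("AAA", "GGG", "WWW"):
            assignment[full_peptides.index(h)] = 2
        model = model_over(full_peptides, assignment)
        prof = cluster_profile(model, scaled_features, 2)
        means = prof.profile["mean"]
        for i in range(1, 14):
            m1, m2, m3 = (means[f"{p}A-{i}"] for p in (1, 2, 3))
            # positions share raw values; after per-column z-scoring against
            # the full library the three positions still agree because each
            # column's library distribution is identical across positions
            assert m1 == pytest.approx(m2, abs=1e-9)
            assert m2 == pytest.approx(m3, abs=1e-9)

    def test_two_peptide_mean_matches_hand_computation(
        self, scaled_features, full_peptides, table
    ):
        assignment = np.ones(len(full_peptides), dtype=int)
        for p in ("WAA", "VAA"):
            assignment[full_peptides.index(p)] = 2
        model = model_over(full_peptides, assignment)
        prof = cluster_profile(model, scaled_features, 2)
        col = scaled_features.labels.index("1A-7")
        w = scaled_features.values[full_peptides.index("WAA"), col]
        v = scaled_features.values[full_peptides.index("VAA"), col]
        assert prof.profile["mean"]["1A-7"] == pytest.approx((w + v) / 2)
        # and the scaled values trace back to the raw hydropathy entries
        raw = encode(["WAA", "VAA"], table)
        j = raw.labels.index("1A-7")
        assert raw.values[0, j] == pytest.approx(-0.9)  # W
        assert raw.values[1, j] == pytest.approx(4.2)  # V

    def test_unknown_cluster(self, scaled_features, full_peptides):
        model = model_over(full_peptides, np.ones(len(full_peptides), dtype=int))
        with pytest.raises(KeyError):
            cluster_profile(model, scaled_features, 99)

    def test_union_mean_is_weighted_mean_of_parts(self, scaled_features, full_peptides):
        assignment = np.ones(len(full_peptides), dtype=int)
        part_a = ["WNY", "WRF", "WAY"]
        part_b = ["AAA", "CCC"]
        for p in part_a:
            assignment[full_peptides.index(p)] = 2
        for p in part_b:
            assignment[full_peptides.index(p)] = 3
        model = model_over(full_peptides, assignment)
        pa = cluster_profile(model, scaled_features, 2).profile["mean"]
        pb = cluster_profile(model, scaled_features, 3).profile["mean"]
        union_assignment = np.where(assignment == 3, 2, assignment)
        union = cluster_profile(
            model_over(full_peptides, union_assignment), scaled_features, 2
        ).profile["mean"]
        expected = (len(part_a) * pa + len(part_b) * pb) / (len(part_a) + len(part_b))
        np.testing.assert_allclose(union.to_numpy(), expected.to_numpy(), atol=1e-12)


class TestComposition:
    def test_single_homotrimer(self):
        model = model_over(["AAA", "CCC"], [1, 2])
        rep = composition(model, 1)
        assert rep.percentages["A"] == 100.0
        assert rep.percentages.drop("A").eq(0).all()

    def test_counting_example(self):
        model = model_over(["WNY", "WRF", "AAA"], [1, 1, 2])
        rep = composition(model, 1, groups={"aromatic": "FYW"})
        assert rep.percentages["W"] == pytest.approx(100 * 2 / 6)
        assert rep.group_percentages["aromatic"] == pytest.approx(100 * 4 / 6)

    def test_aromatic_group_share(self):
        model = model_over(["WNY", "WRF"], [1, 1])
        rep = composition(model, 1, groups={"aromatic": "FYW"})
        # residues W,N,Y,W,R,F: the aromatics are W, Y, W, F -> 4 of 6
        assert rep.group_percentages["aromatic"] == pytest.approx(100 * 4 / 6)
        assert rep.percentages.sum() == pytest.approx(100.0, abs=1e-6)

    def test_percentages_sum_to_100_per_cluster(self, default_model):
        for c in (1, 10, 25, 50):
            rep = composition(default_model, c)
            assert rep.percentages.sum() == pytest.approx(100.0, abs=1e-6)
            for row in rep.per_position.itertuples(index=False):
                assert sum(row) == pytest.approx(100.0, abs=1e-6)

    def test_unknown_group_residue(self):
        model = model_over(["AAA"], [1])
        with pytest.raises(ValueError, match="unknown residues"):
            composition(model, 1, groups={"bad": "XZ"})


class TestCompareProfiles:
    def test_identical_clusters_zero_difference(self, scaled_features, full_peptides):
        assignment = np.ones(len(full_peptides), dtype=int)
        for p in ("WNY", "WRF"):
            assignment[full_peptides.index(p)] = 2
        model = model_over(full_peptides, assignment)
        prof = cluster_profile(model, scaled_features, 2)
        report = compare_profiles(prof, prof)
        assert (report.mean_diff == 0).all()
        assert (report.standardized_diff == 0).all()

    def test_antisymmetric(self, scaled_features, full_peptides):
        assignment = np.ones(len(full_peptides), dtype=int)
        for p in ("WNY", "WRF"):
            assignment[full_peptides.index(p)] = 2
        for p in ("AAC", "CAD"):
            assignment[full_peptides.index(p)] = 3
        model = model_over(full_peptides, assignment)
        a = cluster_profile(model, scaled_features, 2)
        b = cluster_profile(model, scaled_features, 3)
        ab = compare_profiles(a, b)
        ba = compare_profiles(b, a)
        np.testing.assert_allclose(ab.mean_diff, -ba.mean_diff, atol=1e-12)
        np.testing.assert_allclose(
            ab.standardized_diff, -ba.standardized_diff, atol=1e-12
        )

    def test_n_terminal_difference_dominates(self, scaled_features, full_peptides):
        # clusters identical at positions 2 and 3, maximally different at 1
        assignment = np.ones(len(full_peptides), dtype=int)
        for p in ("WAC", "YAC", "FAC"):
            assignment[full_peptides.index(p)] = 2
        for p in ("GAC", "PAC", "SAC"):
            assignment[full_peptides.index(p)] = 3
        model = model_over(full_peptides, assignment)
        a = cluster_profile(model, scaled_features, 2)
        b = cluster_profile(model, scaled_features, 3)
        report = compare_profiles(a, b)
        top = report[report["rank"] <= 10]
        assert (top.position == 1).all()
        pos_summary = report.attrs["position_summary"]
        assert pos_summary.loc[1].iloc[0] == pos_summary.max().iloc[0]
        # positions 2 and 3 are literally identical -> zero difference
        assert report[report.position > 1].mean_diff.abs().max() == 0.0

    def test_label_mismatch_rejected(self, scaled_features, full_peptides, table):
        assignment = np.ones(len(full_peptides), dtype=int)
        assignment[0] = 2
        model = model_over(full_peptides, assignment)
        a = cluster_profile(model, scaled_features, 2)
        b_prof = a.profile.iloc[:10]
        import dataclasses

        b = dataclasses.replace(a, profile=b_prof)
        with pytest.raises(ValueError, match="mismatched"):
            compare_profiles(a, b)
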