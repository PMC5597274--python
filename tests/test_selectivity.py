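"""Tests for replicate pooling, normalization, cluster summaries, the
leave-one-out correlation diagnostic and the per-peptide selectivity calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepfocus.hier_clustering import select_representatives
from pepfocus.selectivity import (
    ClusterSummary,
    _pooled_t,
    call_selective_cluster,
    cluster_summaries,
    loo_correlation,
    normalize_channel,
    selectivity_test,
    summarize_replicates,
)


def spot_frame(rows):
    return pd.DataFrame(rows, columns=["peptide", "role", "channel", "intensity"])


class TestSummarizeReplicates:
    def test_mean_of_one_to_nine(self):
        spots = spot_frame(
            [("AAA", "library", "ColIV", float(v)) for v in range(1, 10)]
        )
        summary = summarize_replicates(spots)
        row = summary.table.iloc[0]
        assert row["mean"] == 5.0 and row["n"] == 9

    def test_noiseless_run_has_zero_sd(self, small_base, small_config):
        from pepfocus.recovery import run_pipeline

        cfg = small_config
        cfg.sigma_spot = 0.0
        cfg.sigma_array = 0.0
        run = run_pipeline(small_base, cfg, seed=0)
        raw = summarize_replicates(run.spots, run.layout)
        assert (raw.table.sd == 0).all()

    def test_missing_replicates_listed(self, small_base, small_config):
        from pepfocus.recovery import run_pipeline

        run = run_pipeline(small_base, small_config, seed=0)
        victim = run.model.all_representatives[0]
        broken = run.spots[
            ~((run.spots.peptide == victim) & (run.spots.replicate == 1))
        ]
        with pytest.raises(ValueError, match=victim):
            summarize_replicates(broken, run.layout)

    def test_row_cardinality(self, default_run):
        lib = default_run.summary.table.query("role == 'library'")
        assert len(lib) == 500 * 3  # peptides x channels


class TestNormalization:
    def test_two_point_closed_form(self):
        spots = spot_frame(
            [("AAA", "library", "ColIV", 10.0), ("CCC", "library", "ColIV", 30.0)]
        )
        norm = normalize_channel(summarize_replicates(spots))
        got = norm.table.set_index("peptide").norm_mean
        assert got["AAA"] == pytest.approx(-1.0)
        assert got["CCC"] == pytest.approx(1.0)

    def test_controls_transformed_but_excluded_from_params(self):
        spots = spot_frame(
            [
                ("AAA", "library", "ColIV", 10.0),
                ("CCC", "library", "ColIV", 30.0),
                ("WWW", "control", "ColIV", 40.0),
            ]
        )
        norm = normalize_channel(summarize_replicates(spots))
        got = norm.table.set_index("peptide").norm_mean
        # library params: mean 20, SD 10 -> control (40-20)/10 = 2
        assert got["WWW"] == pytest.approx(2.0)
        assert norm.channel_params["ColIV"] == (20.0, 10.0)

    def test_ranking_preserved(self, default_run):
        t = default_run.summary.table.query("role == 'library'")
        for _, grp in t.groupby("channel"):
            assert (
                grp.sort_values("mean").norm_mean.is_monotonic_increasing
            )

    def test_zero_variance_channel_rejected(self):
        spots = spot_frame(
            [("AAA", "library", "ColIV", 5.0), ("CCC", "library", "ColIV", 5.0)]
        )
        with pytest.raises(ValueError, match="zero variance"):
            normalize_channel(summarize_replicates(spots))


class TestClusterSummaries:
    def _summary(self, values_by_peptide):
        rows = [
            (p, "library", "ColIV", v) for p, v in values_by_peptide.items()
        ] + [(p, "library", "ColI", -v) for p, v in values_by_peptide.items()]
        return normalize_channel(summarize_replicates(spot_frame(rows)))

    def test_median_and_degenerate_cluster(self):
        vals = {"AAA": 1.0, "AAC": 2.0, "AAD": 3.0, "CCC": 9.0}
        summary = self._summary(vals)
        model = select_representatives(
            list(vals), np.array([1, 1, 1, 2]), n_rep=5, seed=0
        )
        cs = cluster_summaries(summary, model)
        c2 = cs.per_cluster.query("cluster == 2 and channel == 'ColIV'").iloc[0]
        assert c2.sd == 0.0 and c2["median"] == c2["mean"]
        c1 = cs.per_cluster.query("cluster == 1 and channel == 'ColIV'").iloc[0]
        norm = summary.table.query("channel == 'ColIV'").set_index("peptide").norm_mean
        assert c1["median"] == pytest.approx(norm[["AAA", "AAC", "AAD"]].median())

    def test_all_row_covers_library(self, default_run):
        assert (default_run.clusters.overall.n == 500).all()
        assert len(default_run.clusters.per_cluster) == 50 * 3


class TestLooCorrelation:
    def _cluster_summary(self, a, b):
        rows = []
        for i, (x, y) in enumerate(zip(a, b), start=1):
            rows.append((i, "ColIV", 1, x, x, x, 0.0, x))
            rows.append((i, "ColI", 1, y, y, y, 0.0, y))
        per_cluster = pd.DataFrame(
            rows, columns=["cluster", "channel", "n", "median", "q1", "q3", "sd", "mean"]
        )
        return ClusterSummary(per_cluster=per_cluster, overall=per_cluster.iloc[:0])

    def test_collinear_points(self):
        a = np.arange(10.0)
        cs = self._cluster_summary(a, 2 * a + 1)
        diag = loo_correlation(cs, "ColIV", "ColI")
        assert diag.r_all == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in diag.r_excluding.values())

    def test_planted_outlier_detected(self):
        a = np.concatenate([np.arange(10.0), [5.0]])
        b = np.concatenate([2 * np.arange(10.0) + 1, [25.0]])  # point 11 off-line
        diag = loo_correlation(self._cluster_summary(a, b), "ColIV", "ColI")
        assert diag.top_outlier == 11
        assert diag.r_excluding[11] > diag.r_all
        assert diag.r_excluding[11] == pytest.approx(1.0)

    def test_too_few_clusters(self):
        cs = self._cluster_summary([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            loo_correlation(cs, "ColIV", "ColI")


class TestStudentT:
    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 1
        t, p = _pooled_t(x, y)
        assert t == pytest.approx(-1.0)
        assert p == pytest.approx(2 * stats.t.sf(1.0, df=8))  # df = n1 + n2 - 2

    def test_identical_samples_null(self):
        x = np.array([2.0, 2.0, 2.0])
        t, p = _pooled_t(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_warns(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = _pooled_t(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert p == 0.0 and t == -np.inf

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n1, n2 = rng.integers(2, 12, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(loc=0.3, size=n2)
            t, p = _pooled_t(x, y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (
                n1 + n2 - 2
            )
            t_ref = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p_ref = 2 * stats.t.sf(abs(t_ref), df=n1 + n2 - 2)
            assert t == pytest.approx(t_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestSelectivityCalls:
    def test_requires_normalization(self, small_base, small_config):
        from pepfocus.recovery import run_pipeline

        run = run_pipeline(small_base, small_config, seed=1)
        raw = summarize_replicates(run.spots, run.layout)
        with pytest.raises(ValueError, match="normalize_channel"):
            selectivity_test(raw)

    def test_planted_peptides_flagged_at_default_effect(self, default_run):
        planted_reps = {
            p
            for p in default_run.model.all_representatives
            if default_run.truth.is_planted(p)
        }
        calls = default_run.calls.set_index("peptide")
        flagged = calls.loc[sorted(planted_reps)].selective
        assert flagged.mean() >= 0.9  # near-unit power at delta = 1.0

    def test_selective_flag_consistency(self, default_run):
        calls = default_run.calls
        sel = calls[calls.selective]
        assert (sel.p_vs_ColI < 0.01).all() and (sel.p_vs_Alb < 0.01).all()
        assert (sel.norm_mean_ColIV > sel.norm_mean_ColI).all()
        assert (sel.norm_mean_ColIV > sel.norm_mean_Alb).all()


class TestCallSelectiveCluster:
    def test_planted_cluster_ranked_first(self, default_run):
        assert int(default_run.report.iloc[0].cluster) == default_run.planted_cluster

    def test_single_cluster_degenerate(self):
        rows = [
            (1, "ColIV", 3, 0.5, 0.1, 0.9, 0.2, 0.5),
            (1, "ColI", 3, -0.5, -0.9, -0.1, 0.2, -0.5),
        ]
        per_cluster = pd.DataFrame(
            rows, columns=["cluster", "channel", "n", "median", "q1", "q3", "sd", "mean"]
        )
        cs = ClusterSummary(per_cluster=per_cluster, overall=per_cluster.iloc[:0])
        model = select_representatives(["AAA"], np.array([1]), 1, seed=0)
        report = call_selective_cluster(cs, [], pd.DataFrame(), model)
        assert len(report) == 1
        assert np.isnan(report.loo_delta.iloc[0])
        assert report["rank"].iloc[0] == 1
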