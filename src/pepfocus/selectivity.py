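"""Selectivity analysis of spot-level screening intensities.

Stages, in the order the screen is analysed:

1. ``summarize_replicates`` — pool each peptide's replicate spots across
   arrays (nine per peptide in the default 3 arrays x triplicate design) and
   record per-(peptide, channel) mean and SD.
2. ``normalize_channel`` — z-score peptide means within each channel over
   the library peptides (mean 0, SD 1); controls are transformed with the
   library's parameters but excluded from them.
3. ``cluster_summaries`` — per-cluster box-plot statistics (median,
   quartiles, SD, mean) of member representatives' normalized means, plus an
   "All" row over the whole library.
4. ``loo_correlation`` — Pearson correlation between two channels over the
   K cluster means, recomputed with each cluster left out.  A selective
   cluster reveals itself as the point whose removal raises r the most.
5. ``selectivity_test`` — per-peptide two-sample equal-variance Student t of
   target-channel replicates against each non-target channel (replicates
   normalized with their channel's library parameters); a peptide is called
   selective when its target mean exceeds both non-target means and both
   p-values clear alpha (default 0.01, uncorrected).
6. ``call_selective_cluster`` — clusters ranked by a composite of the
   median-intensity margin and the mean leave-one-out correlation gain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .array_sim import ArrayLayout, CHANNELS
from .hier_clustering import ClusterModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-(peptide, channel) replicate pools and summary statistics.

    ``table`` columns: peptide, role, channel, n, mean, sd and, after
    normalization, norm_mean.  ``replicates`` keeps the spot-level rows for
    the per-peptide t-tests.  ``channel_params`` maps channel -> (library
    mean, library SD) of the peptide means once normalized.
    """

    table: pd.DataFrame
    replicates: pd.DataFrame
    channel_params: dict[str, tuple[float, float]] | None = None

    @property
    def normalized(self) -> bool:
        return self.channel_params is not None

    def peptide_norm_means(self, role: str = "library") -> pd.DataFrame:
        """Wide frame: peptides x channels of normalized means."""
        if not self.normalized:
            raise ValueError("summary is not normalized yet")
        sub = self.table[self.table.role == role]
        return sub.pivot(index="peptide", columns="channel", values="norm_mean")


def summarize_replicates(
    spots: pd.DataFrame, layout: ArrayLayout | None = None
) -> ReplicateSummary:
    """Pool replicate spots across arrays per (peptide, channel).

    If ``layout`` is given, every library peptide must carry its complete
    replicate set (n_arrays x n_replicates spots per channel); missing
    replicates raise with the offending peptides listed.
    """
    required = {"peptide", "role", "channel", "intensity"}
    if not required <= set(spots.columns):
        raise ValueError(f"spot table must have columns {sorted(required)}")
    if layout is not None:
        expected = layout.n_arrays * layout.n_replicates
        counts = (
            spots[spots.role == "library"]
            .groupby(["peptide", "channel"], observed=True)
            .size()
        )
        short = sorted({p for (p, _c), n in counts.items() if n != expected})
        missing_entirely = sorted(
            set(layout.library_peptides) - set(counts.index.get_level_values(0))
        )
        bad = short + missing_entirely
        if bad:
            raise ValueError(
                f"incomplete replicate sets ({expected} expected) for peptides: {bad}"
            )
    grouped = spots.groupby(["peptide", "role", "channel"], observed=True)["intensity"]
    table = grouped.agg(n="size", mean="mean", sd=lambda x: x.std(ddof=0)).reset_index()
    return ReplicateSummary(table=table, replicates=spots.copy())


def normalize_channel(summary: ReplicateSummary) -> ReplicateSummary:
    """Z-score peptide means within each channel over library peptides.

    Controls are carried through the same affine transform but do not enter
    the location/scale estimates.
    """
    table = summary.table.copy()
    params: dict[str, tuple[float, float]] = {}
    lib = table.role == "library"
    for channel, sub in table[lib].groupby("channel", observed=True):
        if len(sub) < 2:
            raise ValueError(f"channel {channel!r} has fewer than 2 library peptides")
        mu = float(sub["mean"].mean())
        sd = float(sub["mean"].std(ddof=0))
        if sd == 0:
            raise ValueError(f"channel {channel!r} has zero variance across peptides")
        params[channel] = (mu, sd)
    norm = np.empty(len(table))
    for i, (_, row) in enumerate(table.iterrows()):
        mu, sd = params[row["channel"]]
        norm[i] = (row["mean"] - mu) / sd
    table["norm_mean"] = norm
    return replace(summary, table=table, channel_params=params)


@dataclass(frozen=True)
class ClusterSummary:
    """Box-plot statistics per (cluster, channel) over representative peptides.

    ``per_cluster`` columns: cluster, channel, n, median, q1, q3, sd, mean.
    ``overall`` holds the same statistics over all library peptides (the
    "All" row of the cluster box-plot figure).
    """

    per_cluster: pd.DataFrame
    overall: pd.DataFrame

    @property
    def clusters(self) -> list[int]:
        return sorted(self.per_cluster.cluster.unique())

    def channel_means(self, channel: str) -> pd.Series:
        sub = self.per_cluster[self.per_cluster.channel == channel]
        return sub.set_index("cluster")["mean"].sort_index()

    def channel_medians(self, channel: str) -> pd.Series:
        sub = self.per_cluster[self.per_cluster.channel == channel]
        return sub.set_index("cluster")["median"].sort_index()

    def to_tsv(self, stream) -> None:
        out = self.per_cluster.copy()
        out["cluster"] = out["cluster"].astype(str)
        allrow = self.overall.copy()
        allrow.insert(0, "cluster", "All")
        pd.concat([out, allrow], ignore_index=True).to_csv(
            stream, sep="\t", index=False
        )


def cluster_summaries(
    summary: ReplicateSummary, model: ClusterModel
) -> ClusterSummary:
    """Summarize normalized means per cluster x channel over representatives."""
    wide = summary.peptide_norm_means("library")
    rep_cluster = {
        p: c for c, reps in model.representatives.items() for p in reps
    }
    unknown = set(wide.index) - set(rep_cluster)
    if unknown:
        raise ValueError(
            f"library peptides without a cluster assignment: {sorted(unknown)[:5]}"
        )
    rows = []
    for c in sorted(model.representatives):
        members = [p for p in model.representatives[c] if p in wide.index]
        if not members:
            continue
        vals = wide.loc[members]
        for channel in wide.columns:
            v = vals[channel].to_numpy()
            rows.append(
                (
                    c,
                    channel,
                    len(v),
                    float(np.median(v)),
                    float(np.quantile(v, 0.25)),
                    float(np.quantile(v, 0.75)),
                    float(np.std(v)),
                    float(np.mean(v)),
                )
            )
    per_cluster = pd.DataFrame(
        rows, columns=["cluster", "channel", "n", "median", "q1", "q3", "sd", "mean"]
    )
    overall_rows = []
    for channel in wide.columns:
        v = wide[channel].to_numpy()
        overall_rows.append(
            (
                channel,
                len(v),
                float(np.median(v)),
                float(np.quantile(v, 0.25)),
                float(np.quantile(v, 0.75)),
                float(np.std(v)),
                float(np.mean(v)),
            )
        )
    overall = pd.DataFrame(
        overall_rows, columns=["channel", "n", "median", "q1", "q3", "sd", "mean"]
    )
    return ClusterSummary(per_cluster=per_cluster, overall=overall)


@dataclass(frozen=True)
class CorrelationDiagnostic:
    """Leave-one-out Pearson diagnostic over cluster mean intensities."""

    channel_a: str
    channel_b: str
    r_all: float
    r_excluding: dict[int, float]
    top_outlier: int

    def delta(self, cluster: int) -> float:
        return self.r_excluding[cluster] - self.r_all

    @property
    def mean_abs_gain(self) -> float:
        return max(self.r_excluding.values()) - self.r_all


def loo_correlation(
    clusters: ClusterSummary, channel_a: str, channel_b: str
) -> CorrelationDiagnostic:
    """Pearson r over K cluster points, and r with each cluster excluded.

    The *top outlier* is the cluster whose exclusion raises r the most — the
    signature of a cluster that breaks the otherwise shared binding trend of
    the two channels.
    """
    xa = clusters.channel_means(channel_a)
    xb = clusters.channel_means(channel_b)
    ids = xa.index.to_numpy()
    if len(ids) < 3:
        raise ValueError("need at least 3 clusters for the LOO diagnostic")
    a = xa.to_numpy()
    b = xb.to_numpy()
    r_all = float(np.corrcoef(a, b)[0, 1])
    r_excluding: dict[int, float] = {}
    for i, cid in enumerate(ids):
        mask = np.ones(len(ids), dtype=bool)
        mask[i] = False
        r_excluding[int(cid)] = float(np.corrcoef(a[mask], b[mask])[0, 1])
    top = max(r_excluding, key=lambda c: (r_excluding[c] - r_all, -c))
    return CorrelationDiagnostic(
        channel_a=channel_a,
        channel_b=channel_b,
        r_all=r_all,
        r_excluding=r_excluding,
        top_outlier=int(top),
    )


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sided two-sample t with degenerate-case handling."""
    n1, n2 = len(x), len(y)
    if np.allclose(x.var(ddof=1) + y.var(ddof=1), 0.0):
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means; reporting p=0", stacklevel=2
        )
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def selectivity_test(
    summary: ReplicateSummary,
    alpha: float = 0.01,
    target: str = CHANNELS[0],
) -> pd.DataFrame:
    """Per-peptide Student t of the target channel against each non-target.

    Replicate intensities are first transformed with their channel's library
    normalization parameters so that channels share a common scale.  A
    library peptide is flagged ``selective`` when its normalized target mean
    exceeds both non-target means and both two-sided p-values are below
    ``alpha``.  Degrees of freedom are n1 + n2 - 2.
    """
    if not summary.normalized:
        raise ValueError("normalize_channel must run before selectivity_test")
    reps = summary.replicates
    channels = sorted(reps.channel.unique())
    if target not in channels:
        raise ValueError(f"target channel {target!r} absent from spot table")
    non_targets = [c for c in channels if c != target]
    params = summary.channel_params
    lib = reps[reps.role == "library"]
    pools = {
        (p, c): g["intensity"].to_numpy()
        for (p, c), g in lib.groupby(["peptide", "channel"], observed=True)
    }

    def z(vals: np.ndarray, channel: str) -> np.ndarray:
        mu, sd = params[channel]
        return (vals - mu) / sd

    rows = []
    for peptide in sorted({p for p, _ in pools}):
        xt = z(pools[(peptide, target)], target)
        if len(xt) < 2:
            raise ValueError(f"peptide {peptide} has <2 target-channel replicates")
        entry: dict[str, object] = {"peptide": peptide}
        entry[f"norm_mean_{target}"] = float(xt.mean())
        significant = []
        higher = []
        for nt in non_targets:
            xo = z(pools[(peptide, nt)], nt)
            if len(xo) < 2:
                raise ValueError(f"peptide {peptide} has <2 {nt} replicates")
            t, p = _pooled_t(xt, xo)
            entry[f"norm_mean_{nt}"] = float(xo.mean())
            entry[f"t_vs_{nt}"] = t
            entry[f"p_vs_{nt}"] = p
            significant.append(p < alpha)
            higher.append(xt.mean() > xo.mean())
        entry["selective"] = bool(all(significant) and all(higher))
        rows.append(entry)
    return pd.DataFrame(rows)


def call_selective_cluster(
    clusters: ClusterSummary,
    diagnostics: list[CorrelationDiagnostic],
    calls: pd.DataFrame,
    model: ClusterModel,
    target: str = CHANNELS[0],
) -> pd.DataFrame:
    """Rank clusters by target selectivity.

    Two complementary signals are combined by rank sum:

    * ``margin`` — the cluster's median normalized target intensity minus
      the larger of its non-target medians (how selective the cluster looks
      in the box-plot summary);
    * ``loo_delta`` — the mean, over the supplied channel pairs, of the
      Pearson-r gain when the cluster is excluded (how strongly the cluster
      distorts the shared between-channel trend).

    The report also counts each cluster's individually selective peptides.
    Ties in the composite rank resolve toward the larger margin.  With a
    single cluster the LOO component is undefined and the margin alone
    decides.
    """
    channels = sorted(clusters.per_cluster.channel.unique())
    non_targets = [c for c in channels if c != target]
    ids = clusters.clusters
    med = {c: clusters.channel_medians(c) for c in channels}
    margin = pd.Series(
        {
            cid: med[target][cid] - max(med[nt][cid] for nt in non_targets)
            for cid in ids
        }
    )
    if diagnostics:
        loo = pd.Series(
            {
                cid: float(np.mean([d.delta(cid) for d in diagnostics]))
                for cid in ids
            }
        )
    else:
        loo = pd.Series({cid: np.nan for cid in ids})
    rep_cluster = {p: c for c, reps in model.representatives.items() for p in reps}
    sel_counts = (
        calls[calls.selective]
        .peptide.map(rep_cluster)
        .value_counts()
        .reindex(ids, fill_value=0)
        if len(calls)
        else pd.Series(0, index=ids)
    )
    report = pd.DataFrame(
        {
            "cluster": ids,
            "margin": margin.loc[ids].to_numpy(),
            "loo_delta": loo.loc[ids].to_numpy(),
            "n_selective": sel_counts.loc[ids].to_numpy(),
        }
    )
    rank_margin = stats.rankdata(-report.margin)
    if report.loo_delta.notna().all() and len(report) > 1:
        rank_loo = stats.rankdata(-report.loo_delta)
        report["composite"] = rank_margin + rank_loo
    else:
        report["composite"] = rank_margin
    report = report.sort_values(
        ["composite", "margin"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report
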