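"""Physicochemical characterization of peptide clusters.

Position-resolved heat maps and mean/SD profiles over the 39 scaled
descriptor columns, residue-composition percentages, and pairwise cluster
profile comparisons (which features, and hence which sequence position,
discriminate two clusters most).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aaindex import AMINO_ACIDS
from .hier_clustering import ClusterModel
from .library_design import FeatureMatrix

#: Residue groups frequently discussed for collagen-binding peptides.
EXAMPLE_GROUPS = {
    "positively_charged": "RK",
    "aromatic": "FYW",
    "VLM": "VLM",
}


@dataclass(frozen=True)
class ClusterProfile:
    """Members-by-features heat-map block plus per-feature mean/SD profile."""

    cluster: int
    peptides: tuple[str, ...]
    heatmap: pd.DataFrame  # members x 39 scaled feature values
    profile: pd.DataFrame  # per feature label: mean, sd

    def to_heatmap_tsv(self, stream) -> None:
        out = self.heatmap.copy()
        out.index.name = "peptide"
        out.to_csv(stream, sep="\t")

    def to_profile_tsv(self, stream) -> None:
        out = self.profile.copy()
        out.index.name = "feature"
        out.to_csv(stream, sep="\t")


def cluster_profile(
    model: ClusterModel, features: FeatureMatrix, cluster: int
) -> ClusterProfile:
    """Scaled feature block and per-feature mean/SD for one cluster."""
    if not features.scaled:
        raise ValueError("cluster_profile expects scaled features")
    if cluster not in range(1, model.K + 1):
        raise KeyError(f"unknown cluster id {cluster}")
    members = model.members(cluster)
    frame = features.to_frame()
    block = frame.loc[members]
    profile = pd.DataFrame(
        {"mean": block.mean(axis=0), "sd": block.std(axis=0, ddof=0)}
    )
    return ClusterProfile(
        cluster=cluster,
        peptides=tuple(members),
        heatmap=block,
        profile=profile,
    )


@dataclass(frozen=True)
class CompositionReport:
    """Residue usage of one cluster, as percentages of all positions."""

    cluster: int
    n_peptides: int
    percentages: pd.Series  # per residue, sums to 100
    group_percentages: pd.Series
    per_position: pd.DataFrame  # positions x residues, each row sums to 100

    def to_tsv(self, stream) -> None:
        out = self.percentages.rename("percent").to_frame()
        out.index.name = "residue"
        out.to_csv(stream, sep="\t")


def composition(
    model: ClusterModel,
    cluster: int,
    groups: dict[str, str] | None = None,
) -> CompositionReport:
    """Residue percentages over all positions of a cluster's member sequences.

    ``groups`` maps a group name to a string of residues (e.g.
    ``{"aromatic": "FYW"}``); group percentages are sums of their members'.
    """
    members = model.members(cluster)
    if not members:
        raise KeyError(f"unknown or empty cluster {cluster}")
    groups = groups or {}
    for name, residues in groups.items():
        bad = set(residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"group {name!r} contains unknown residues {sorted(bad)}")
    counts = Counter("".join(members))
    total = sum(counts.values())
    pct = pd.Series(
        {aa: 100.0 * counts.get(aa, 0) / total for aa in AMINO_ACIDS}
    )
    grp = pd.Series(
        {name: float(pct[list(residues)].sum()) for name, residues in groups.items()},
        dtype=float,
    )
    pos_rows = []
    npos = len(members[0])
    for p in range(npos):
        c = Counter(seq[p] for seq in members)
        pos_rows.append(
            {aa: 100.0 * c.get(aa, 0) / len(members) for aa in AMINO_ACIDS}
        )
    per_position = pd.DataFrame(pos_rows, index=range(1, npos + 1))
    return CompositionReport(
        cluster=cluster,
        n_peptides=len(members),
        percentages=pct,
        group_percentages=grp,
        per_position=per_position,
    )


def compare_profiles(a: ClusterProfile, b: ClusterProfile) -> pd.DataFrame:
    """Per-feature difference report between two cluster profiles.

    Columns: mean_diff (a - b), pooled_sd, standardized_diff
    (mean_diff / pooled_sd, 0 when both SDs vanish), rank by
    |standardized_diff|, and the position prefix of each feature.  The
    attached ``position_summary`` attribute aggregates mean
    |standardized_diff| per sequence position, highlighting which position
    discriminates the clusters most.
    """
    if list(a.profile.index) != list(b.profile.index):
        raise ValueError("profiles have mismatched feature labels")
    mean_diff = a.profile["mean"] - b.profile["mean"]
    pooled = np.sqrt((a.profile["sd"] ** 2 + b.profile["sd"] ** 2) / 2.0)
    std_diff = np.where(pooled > 0, mean_diff / pooled, 0.0)
    report = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "pooled_sd": pooled,
            "standardized_diff": std_diff,
        }
    )
    report["position"] = [int(label.split("A-")[0]) for label in report.index]
    report["rank"] = (
        (-report.standardized_diff.abs()).rank(method="first").astype(int)
    )
    pos_summary = (
        report.groupby("position")["standardized_diff"]
        .agg(lambda s: float(np.mean(np.abs(s))))
        .rename("mean_abs_standardized_diff")
        .to_frame()
    )
    report.attrs["position_summary"] = pos_summary
    return report


def plot_profile_heatmap(profile: ClusterProfile, path) -> None:
    """Render the members-by-features heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(10, max(2.0, 0.08 * len(profile.peptides)))
    )
    im = ax.imshow(profile.heatmap.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(profile.heatmap.columns)))
    ax.set_xticklabels(profile.heatmap.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_title(f"Cluster {profile.cluster} ({len(profile.peptides)} peptides)")
    fig.colorbar(im, ax=ax, label="scaled index value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
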