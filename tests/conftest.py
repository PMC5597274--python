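"""Shared fixtures: the bundled index table, the full default clustering
(computed once per session), one seeded default screening run, and the
brute-force UPGMA oracle used to validate the fast implementation."""

from __future__ import annotations

import numpy as np
import pytest

from pepfocus import (
    RunConfig,
    build_base,
    bundled_table,
    run_pipeline,
    select_representatives,
)


@pytest.fixture(scope="session")
def table():
    return bundled_table()


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_base(default_config):
    """Full 8000-peptide encoding + 50-cluster partition (shared, ~10 s)."""
    return build_base(default_config)


@pytest.fixture(scope="session")
def default_model(default_base, default_config):
    return select_representatives(
        list(default_base.peptides),
        default_base.assignment,
        default_config.n_representatives,
        seed=default_config.seed,
    )


@pytest.fixture(scope="session")
def default_run(default_base, default_config):
    """One seeded end-to-end screening run under default conditions."""
    return run_pipeline(default_base, default_config, seed=7)


@pytest.fixture(scope="session")
def small_base():
    """A miniature pipeline base: 120 peptides, 6 clusters (fast unit runs)."""
    import itertools

    from pepfocus import encode, pairwise_distance, average_linkage, cut_tree
    from pepfocus.recovery import PipelineBase
    from pepfocus.library_design import scale

    residues = "ACDEFG"  # 216 tripeptides over a reduced alphabet, subsampled
    peptides = ["".join(p) for p in itertools.product(residues, repeat=3)][:120]
    features = encode(peptides, bundled_table())
    dendro = average_linkage(pairwise_distance(features))
    assignment = cut_tree(dendro, 6)
    return PipelineBase(
        peptides=tuple(peptides),
        assignment=assignment,
        K=6,
        features_scaled=scale(features),
    )


@pytest.fixture
def small_config():
    return RunConfig(
        k_clusters=6,
        n_representatives=5,
        n_arrays=2,
        n_replicates=2,
    )


def brute_force_upgma(D0: np.ndarray) -> np.ndarray:
    """O(n^3) UPGMA oracle: rescan the full between-cluster mean-distance
    matrix from the original distances at every step.

    Ties resolve to the smallest (older-id, newer-id) pair, ids assigned in
    creation order (leaves first), matching the convention of the package's
    fast implementation so the two can be compared merge-for-merge.
    """
    n = D0.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = float(
                    np.mean([D0[x, y] for x in clusters[a] for y in clusters[b]])
                )
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)
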