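"""Average-linkage (UPGMA) hierarchical clustering and representative selection.

The clustering is implemented here rather than delegated, because the exact
merge order and its tie-break convention define the cluster numbering the
rest of the pipeline depends on:

* at each step the pair of clusters with the minimal mean inter-cluster
  distance is merged; after merging clusters i and j, the distance to any
  other cluster k is the size-weighted average
  (n_i * d(i,k) + n_j * d(j,k)) / (n_i + n_j)  (Lance-Williams, UPGMA);
* exact ties are broken by the lexicographically smallest
  (older-cluster-id, newer-cluster-id) pair, ids being assigned in creation
  order (leaves 0..n-1, then one new id per merge);
* a flat K-cluster partition removes the K-1 highest (i.e. last) merges and
  numbers the resulting components 1..K by their smallest leaf index.

Average linkage is reducible, so merge heights are non-decreasing; this is
asserted by the test suite, not silently assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .library_design import FeatureMatrix

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "pearson", "uncentered_pearson")

# scipy.spatial.distance names for the supported metrics; "correlation" is
# 1 - Pearson r, "cosine" is 1 - uncentered correlation.
_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "pearson": "correlation",
    "uncentered_pearson": "cosine",
}


def pairwise_distance(matrix: FeatureMatrix | np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Condensed pairwise distance vector over the rows of ``matrix``.

    ``pearson`` distance is 1 - r, ``uncentered_pearson`` is 1 - the
    uncentered (cosine) correlation.  Correlation metrics reject constant
    (or, uncentered, all-zero) rows because their correlation is undefined.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        names = matrix.peptides
    else:
        X = np.asarray(matrix, dtype=float)
        names = None
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if metric == "pearson":
        bad = np.flatnonzero(X.std(axis=1) == 0)
    elif metric == "uncentered_pearson":
        bad = np.flatnonzero(np.linalg.norm(X, axis=1) == 0)
    else:
        bad = np.array([], dtype=int)
    if bad.size:
        who = [names[i] if names else int(i) for i in bad]
        raise ValueError(
            f"correlation distance undefined for constant/zero rows: {who}"
        )
    d = pdist(X, metric=_SCIPY_METRIC[metric])
    # cancellation can push correlation distances to tiny negatives
    if metric != "euclidean":
        d = np.maximum(d, 0.0)
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges`` has one row per merge: (left id, right id, height, merged
    size), with left < right.  Leaves carry ids 0..leaf_count-1; the t-th
    merge creates id leaf_count + t.
    """

    merges: np.ndarray  # (leaf_count - 1, 4)
    leaf_count: int

    def __post_init__(self) -> None:
        if self.merges.shape != (self.leaf_count - 1, 4):
            raise ValueError("merges must have leaf_count - 1 rows of 4")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy.cluster.hierarchy layout (same id scheme)."""
        return self.merges.astype(float)

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.leaf_count
        if labels is None:
            labels = [str(i) for i in range(n)]
        height = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for t, (a, b, h, _s) in enumerate(self.merges):
            node = n + t
            children[node] = (int(a), int(b))
            height[node] = float(h)
        root = n + len(self.merges) - 1
        # iterative post-order formatting (the tree can be chain-like)
        out: dict[int, str] = {}
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < n:
                out[node] = labels[node]
                continue
            a, b = children[node]
            if not expanded:
                stack.append((node, True))
                stack.append((a, False))
                stack.append((b, False))
            else:
                ba = height[node] - height[a]
                bb = height[node] - height[b]
                out[node] = f"({out[a]}:{ba:.10g},{out[b]}:{bb:.10g})"
        return out[root] + ";"


def average_linkage(distances: np.ndarray) -> Dendrogram:
    """UPGMA clustering of a condensed (or square) distance structure."""
    distances = np.asarray(distances, dtype=float)
    if distances.ndim == 1:
        D = squareform(distances)
    else:
        D = distances.copy()
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distance encountered")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")

    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    n_active = n
    ids = np.arange(n)  # cluster id currently occupying each slot
    sizes = np.ones(n, dtype=np.int64)
    nn_val = D.min(axis=1)
    nn_idx = D.argmin(axis=1)
    merges = np.empty((n - 1, 4))
    next_id = n

    for step in range(n - 1):
        m = nn_val.min()  # inactive slots hold +inf
        # Tie-break on the smallest (older, newer) id pair.  Both endpoints
        # of any min-attaining pair are rows whose cached minimum equals m,
        # so the lexicographically smallest pair is: the tied row with the
        # oldest id, joined to its oldest-id partner.
        cand = np.flatnonzero(nn_val == m)
        s = int(cand[np.argmin(ids[cand])])
        partners = np.flatnonzero(D[s] == m)
        t = int(partners[np.argmin(ids[partners])])
        na, nb = int(sizes[s]), int(sizes[t])
        merges[step] = (ids[s], ids[t], m, na + nb)

        row = (na * D[s] + nb * D[t]) / (na + nb)
        row[~active] = np.inf
        row[s] = np.inf
        row[t] = np.inf
        D[s, :] = row
        D[:, s] = row
        D[t, :] = np.inf
        D[:, t] = np.inf
        active[t] = False
        n_active -= 1
        sizes[s] = na + nb
        ids[s] = next_id
        next_id += 1
        nn_val[t] = np.inf
        nn_idx[t] = t
        if step == n - 2:
            break
        nn_val[s] = D[s].min()
        nn_idx[s] = D[s].argmin()
        # rows whose cached nearest neighbour involved s or t must rescan;
        # everyone else can only improve via the new cluster in slot s
        stale = active & ((nn_idx == t) | (nn_idx == s))
        stale[s] = False
        if stale.any():
            sub = D[stale]
            nn_val[stale] = sub.min(axis=1)
            nn_idx[stale] = sub.argmin(axis=1)
        better = active & (D[s] < nn_val)  # D stays symmetric: row == column
        better[s] = False
        if better.any():
            nn_val[better] = D[better, s]
            nn_idx[better] = s
        # compact the matrix once most slots are dead: keeps row ops cache-friendly
        if n_active > 64 and n_active < 0.6 * D.shape[0]:
            act = np.flatnonzero(active)
            remap = np.full(D.shape[0], -1)
            remap[act] = np.arange(act.size)
            D = np.ascontiguousarray(D[np.ix_(act, act)])
            ids = ids[act]
            sizes = sizes[act]
            nn_val = nn_val[act]
            nn_idx = remap[nn_idx[act]]
            active = np.ones(act.size, dtype=bool)
    return Dendrogram(merges=merges, leaf_count=n)


def cut_tree(dendrogram: Dendrogram, K: int) -> np.ndarray:
    """Flat partition into K clusters by removing the K-1 highest merges.

    Returns an array of cluster ids in 1..K, one per leaf, components
    numbered in order of their smallest leaf index.
    """
    n = dendrogram.leaf_count
    if not 1 <= K <= n:
        raise ValueError(f"K={K} out of range 1..{n}")
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members: dict[int, int] = {i: i for i in range(n)}  # node id -> a leaf root
    for t in range(n - K):
        a, b, _h, _s = dendrogram.merges[t]
        ra, rb = find(members[int(a)]), find(members[int(b)])
        parent[rb] = ra
        members[n + t] = ra
    roots = np.array([find(i) for i in range(n)])
    order = {}
    labels = np.empty(n, dtype=np.int64)
    for leaf in range(n):
        r = roots[leaf]
        if r not in order:
            order[r] = len(order) + 1
        labels[leaf] = order[r]
    assert len(order) == K
    return labels


@dataclass(frozen=True)
class ClusterModel:
    """Flat clustering of a peptide library plus per-cluster representatives."""

    peptides: tuple[str, ...]
    assignment: np.ndarray  # cluster id in 1..K per peptide
    K: int
    representatives: dict[int, tuple[str, ...]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.assignment)
        if lab.shape != (len(self.peptides),):
            raise ValueError("assignment length must match peptide count")
        present = np.unique(lab)
        if not np.array_equal(present, np.arange(1, self.K + 1)):
            raise ValueError(f"assignment must cover cluster ids 1..{self.K}")
        member_sets = {c: set(self.members(c)) for c in self.representatives}
        for c, reps in self.representatives.items():
            if len(set(reps)) != len(reps) or not set(reps) <= member_sets[c]:
                raise ValueError(f"invalid representatives for cluster {c}")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.K + 1)[1:]

    def members(self, cluster: int) -> list[str]:
        idx = np.flatnonzero(self.assignment == cluster)
        return [self.peptides[i] for i in idx]

    def cluster_of(self, peptide: str) -> int:
        return int(self.assignment[self.peptides.index(peptide)])

    @property
    def all_representatives(self) -> list[str]:
        out: list[str] = []
        for c in sorted(self.representatives):
            out.extend(self.representatives[c])
        return out

    def to_tsv(self, stream) -> None:
        rep = {p for reps in self.representatives.values() for p in reps}
        stream.write("peptide\tcluster_id\tis_representative\n")
        for p, c in zip(self.peptides, self.assignment):
            stream.write(f"{p}\t{int(c)}\t{int(p in rep)}\n")


def select_representatives(
    peptides: list[str] | tuple[str, ...],
    assignment: np.ndarray,
    n_rep: int = 10,
    seed: int = 0,
) -> ClusterModel:
    """Uniformly sample min(n_rep, size) members per cluster, without replacement.

    Sampling uses one seeded generator consumed in ascending cluster-id
    order, so the full representative set is reproducible from the seed.
    Clusters smaller than ``n_rep`` contribute all their members (a warning
    is logged, not an error).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    assignment = np.asarray(assignment)
    K = int(assignment.max())
    rng = np.random.default_rng(seed)
    reps: dict[int, tuple[str, ...]] = {}
    peps = np.asarray(peptides, dtype=object)
    for c in range(1, K + 1):
        members = peps[assignment == c]
        if members.size < n_rep:
            logger.warning(
                "cluster %d has only %d members (< n_rep=%d); taking all",
                c, members.size, n_rep,
            )
            chosen = members
        else:
            chosen = rng.choice(members, size=n_rep, replace=False)
        reps[c] = tuple(str(p) for p in chosen)
    return ClusterModel(
        peptides=tuple(peptides),
        assignment=assignment,
        K=K,
        representatives=reps,
        seed=seed,
    )
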