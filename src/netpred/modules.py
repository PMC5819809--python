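"""Module detection: topological overlap, hierarchical clustering, tree cut.

The topological overlap of two nodes measures how much of their network
neighborhood they share; its complement (dissTOM) is the dissimilarity fed
to average-linkage hierarchical clustering.  The dendrogram is cut by a
simplified dynamic hybrid rule: a static cut near the top of the merge
heights, dissolution of clusters below the minimum size, and iterative
re-assignment of loose features to the nearest retained cluster.  Features
that fit no retained cluster keep label 0 (unassigned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from netpred.network import WeightedNetwork

#: deep_split level -> lower quantile of merge heights bounding the cut scan
DEEP_SPLIT_BASE_QUANTILES = {0: 0.25, 1: 0.10, 2: 0.05, 3: 0.02, 4: 0.0}

#: number of candidate cut heights scanned between the base quantile and the
#: top of the dendrogram
N_CUT_CANDIDATES = 40


@dataclass
class TomMatrix:
    tom: np.ndarray
    diss: np.ndarray


@dataclass
class ModulePartition:
    """Feature -> module labels; 0 marks unassigned features."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or (self.labels < 0).any():
            raise ValueError("labels must be a 1-d vector of ints >= 0")
        present = sorted(set(self.labels[self.labels > 0]))
        if present != list(range(1, len(present) + 1)):
            raise ValueError("module labels must be contiguous 1..L")

    @classmethod
    def from_labels(cls, labels):
        return cls(np.asarray(labels, dtype=int))

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def sizes(self) -> dict:
        return {int(l): int((self.labels == l).sum())
                for l in range(1, self.n_modules + 1)}

    @property
    def n_features(self) -> int:
        return self.labels.size


@dataclass
class PartitionScore:
    tpr: float
    fnr: float
    fpr: float
    matched_label: int


def topological_overlap(net: WeightedNetwork) -> TomMatrix:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    The diagonal of the adjacency is zero, so the matrix product already
    excludes u = i, j from the shared-neighbor sum.  Diagonal TOM is 1 by
    convention; isolated node pairs get TOM 0 through the +1 in the
    denominator.
    """
    A = net.weights
    k = net.connectivity
    num = A @ A + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TomMatrix(tom=tom, diss=1.0 - tom)


def _cluster_merge_heights(Z, labels0, n):
    """Max internal merge height of each static-cut cluster."""
    node_cluster = {i: labels0[i] for i in range(n)}
    heights = {}
    for i, (a, b, h, _) in enumerate(Z):
        ca = node_cluster.get(int(a))
        cb = node_cluster.get(int(b))
        c = ca if (ca == cb and ca is not None) else None
        node_cluster[n + i] = c
        if c is not None:
            heights[c] = max(heights.get(c, 0.0), float(h))
    return heights


def cut_modules(tomm: TomMatrix, min_size: int = 20,
                deep_split: int = 2) -> ModulePartition:
    """Partition features by average-linkage clustering and a hybrid cut.

    TOM dendrograms concentrate most merge heights near the top, so no
    single pre-set cut height separates modules reliably.  The static cut is
    therefore chosen adaptively: candidate heights between the
    ``deep_split``-controlled lower quantile of merge heights (5% at the
    default level 2) and the top of the dendrogram are scanned, and the cut
    retaining the largest number of clusters of size >= ``min_size`` wins
    (ties go to the higher, more inclusive cut).  Clusters smaller than
    ``min_size`` are then dissolved; their members join the nearest retained
    cluster (smallest average dissimilarity) provided that distance does not
    exceed the cluster's own internal merge height, and are otherwise left
    unassigned (label 0).  Re-assignment iterates until stable.  Retained
    clusters are renumbered by decreasing size.

    A dendrogram with no height spread (e.g. an empty network, all
    dissimilarities equal) has no meaningful cut: everything is unassigned.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    D = np.asarray(tomm.diss, dtype=float)
    p = D.shape[0]
    if p == 1:
        return ModulePartition(np.zeros(1, dtype=int))
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)

    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    if isinstance(deep_split, (int, np.integer)) and not isinstance(
            deep_split, bool) and deep_split in DEEP_SPLIT_BASE_QUANTILES:
        base_q = DEEP_SPLIT_BASE_QUANTILES[deep_split]
    elif 0 < float(deep_split) < 1:
        base_q = float(deep_split)
    else:
        raise ValueError("deep_split must be a level in 0..4 or a quantile")
    lo = float(np.quantile(heights, base_q))
    hi = float(heights.max())
    if hi - lo < 1e-12:
        return ModulePartition(np.zeros(p, dtype=int))
    best_n, labels0 = 0, None
    for t in np.linspace(lo, hi, N_CUT_CANDIDATES, endpoint=False):
        lab = fcluster(Z, t=t, criterion="distance")
        nbig = int((np.bincount(lab)[1:] >= min_size).sum())
        if nbig >= best_n and nbig > 0:
            best_n, labels0 = nbig, lab
    if labels0 is None:
        return ModulePartition(np.zeros(p, dtype=int))

    sizes = np.bincount(labels0)
    retained = [c for c in np.unique(labels0) if sizes[c] >= min_size]
    merge_h = _cluster_merge_heights(Z, labels0, p)

    assign = np.zeros(p, dtype=int)
    for c in retained:
        assign[labels0 == c] = c
    pool = np.flatnonzero(assign == 0)

    if retained:
        for _ in range(100):
            changed = False
            members = {c: np.flatnonzero(assign == c) for c in retained}
            for i in pool:
                if assign[i] != 0:
                    continue
                best_c, best_d = 0, np.inf
                for c in retained:
                    d = D[i, members[c]].mean()
                    if d < best_d:
                        best_c, best_d = c, d
                if best_c and best_d <= merge_h.get(best_c, 0.0):
                    assign[i] = best_c
                    changed = True
            if not changed:
                break

    # renumber by decreasing size (ties: original cluster id)
    final_sizes = [(int((assign == c).sum()), c) for c in retained
                   if (assign == c).any()]
    final_sizes.sort(key=lambda t: (-t[0], t[1]))
    relabel = {c: i + 1 for i, (_, c) in enumerate(final_sizes)}
    out = np.array([relabel.get(c, 0) for c in assign], dtype=int)
    return ModulePartition(out)


def score_partition(partition: ModulePartition, truth_labels,
                    reference_module: int) -> PartitionScore:
    """TPR/FNR/FPR of the best-overlap estimated cluster vs a true module.

    The estimated cluster matched to the reference is the label (>= 1) with
    the largest overlap (ties broken toward the smaller label).  TPR is the
    fraction of the reference module recovered; FPR the fraction of
    non-reference features swept into the matched cluster.
    """
    truth = np.asarray(truth_labels, dtype=int)
    if truth.size != partition.n_features:
        raise ValueError("label vectors must have equal length")
    ref_mask = truth == reference_module
    n_ref = int(ref_mask.sum())
    if n_ref == 0:
        raise ValueError(f"reference module {reference_module} is empty")

    best_label, best_overlap = 0, -1
    for l in range(1, partition.n_modules + 1):
        ov = int(((partition.labels == l) & ref_mask).sum())
        if ov > best_overlap:
            best_label, best_overlap = l, ov
    if best_label == 0:
        return PartitionScore(tpr=0.0, fnr=1.0, fpr=0.0, matched_label=0)

    matched = partition.labels == best_label
    tpr = int((matched & ref_mask).sum()) / n_ref
    fp = int((matched & ~ref_mask).sum())
    denom = truth.size - n_ref
    fpr = fp / denom if denom else 0.0
    return PartitionScore(tpr=float(tpr), fnr=float(1 - tpr),
                          fpr=float(fpr), matched_label=best_label)
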