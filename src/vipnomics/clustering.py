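"""Hierarchical clustering of samples across treatment time points.

Ward.D2 agglomeration (Ward's criterion applied to Euclidean distances with
the squared Lance-Williams update, i.e. scipy's ``ward`` method) is used to
test whether metabolite profiles group by time point rather than by
phenotype, and :func:`cut_purity` quantifies that visual claim as the purity
of a flat cut of the tree against any sample grouping (time point, puberty
age group, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy.cluster import hierarchy

from .containers import ProfileMatrix, ValidationError

__all__ = ["Dendrogram", "ward_cluster", "cut_purity", "stack_timepoints"]


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format merge history plus leaf labels.

    ``linkage`` is the (n-1) x 4 scipy matrix (merged indices, merge height,
    cluster size); ``leaf_labels`` are ``sample_id@timepoint`` strings.
    """

    linkage: np.ndarray
    leaf_labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster assignment (1..n_clusters) per leaf."""
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        if tree.is_leaf():  # single sample; not reachable via ward_cluster
            return f"{self.leaf_labels[tree.id]};"
        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def ward_cluster(stacked: ProfileMatrix) -> Dendrogram:
    """Ward.D2 / Euclidean agglomeration of the stacked sample matrix.

    Requires a complete (imputed) matrix and at least two samples.  The merge
    history is deterministic given the input matrix, and merge heights do not
    depend on sample order.
    """
    if stacked.n_samples < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if np.isnan(stacked.values).any():
        raise ValidationError("clustering requires an imputed (complete) matrix")
    z = hierarchy.linkage(stacked.values, method="ward", metric="euclidean")
    labels = [
        f"{s}@{stacked.timepoint}" if "@" not in s else s for s in stacked.sample_ids
    ]
    return Dendrogram(z, labels)


def cut_purity(d: Dendrogram, n_clusters: int, grouping: dict[str, str]) -> float:
    """Purity of an ``n_clusters`` flat cut against a sample->category map.

    purity = (sum over clusters of the majority-category count) / n_samples;
    1.0 means every cluster is single-category.  Monotone non-decreasing in
    ``n_clusters``.
    """
    n = len(d.leaf_labels)
    if not (2 <= n_clusters <= n):
        raise ValidationError(f"n_clusters must lie in [2, {n}]")
    missing = [s for s in d.leaf_labels if s not in grouping]
    if missing:
        raise ValidationError(f"grouping lacks categories for samples: {missing}")
    assign = d.cut(n_clusters)
    total = 0
    for c in np.unique(assign):
        cats = [grouping[d.leaf_labels[i]] for i in np.flatnonzero(assign == c)]
        counts: dict[str, int] = {}
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
        total += max(counts.values())
    return total / n


def stack_timepoints(matrices: list[ProfileMatrix]) -> ProfileMatrix:
    """Stack per-time-point matrices on the intersection of their features.

    Sample ids are suffixed ``@timepoint`` so each profile is one leaf.
    Missing values are carried through (impute jointly afterwards).
    """
    if not matrices:
        raise ValidationError("no matrices to stack")
    common = reduce(
        lambda a, b: [f for f in a if f in set(b)],
        [m.feature_ids for m in matrices],
    )
    if not common:
        raise ValidationError("time points share no features after filtering")
    parts = [m.subset_features(common) for m in matrices]
    values = np.vstack([p.values for p in parts])
    ids = [f"{s}@{p.timepoint}" for p in parts for s in p.sample_ids]
    labels = [l for p in parts for l in p.labels]
    return ProfileMatrix(ids, common, values, labels, "stacked")
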