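"""Sample clustering on selected genes with bootstrap clade support.

Samples (array or subject columns) are clustered by average-linkage (UPGMA)
agglomeration on Euclidean distances over a selected gene set — typically
the differentially expressed genes at a chosen significance level.  Clade
reliability is assessed by resampling *genes* with replacement: a node's
support is the fraction of bootstrap trees in which its exact leaf set
reappears as a clade.  Trees export to Newick with supports as internal
node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["Dendrogram", "ClusterSupport", "average_linkage", "cut_to_k", "bootstrap_support"]


@dataclass
class Dendrogram:
    """A binary merge tree over sample columns (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self, include_leaves: bool = False) -> list[frozenset]:
        """Leaf-label sets of every internal node (root included)."""
        sets: list[frozenset] = [frozenset([l]) for l in self.labels]
        for left, right, _, _ in self.linkage:
            sets.append(sets[int(left)] | sets[int(right)])
        internal = sets[self.n_leaves:]
        return sets if include_leaves else internal

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_newick(self, support: dict[frozenset, float] | None = None) -> str:
        """Newick string; internal node labels carry support when given."""
        sets = self.clades(include_leaves=True)

        def fmt(node, parent_height: float) -> str:
            height = 0.0 if node.is_leaf() else float(node.dist)
            length = max(parent_height - height, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(fmt(c, height) for c in (node.left, node.right))
            label = ""
            if support is not None and sets[node.id] in support:
                label = f"{support[sets[node.id]]:.3f}"
            return f"({children}){label}:{length:.6g}"

        root = hierarchy.to_tree(self.linkage)
        return fmt(root, float(root.dist)).rsplit(":", 1)[0] + ";"


@dataclass
class ClusterSupport:
    """Bootstrap support fraction per internal node (keyed by leaf set)."""

    support: dict[frozenset, float]
    n_bootstrap: int

    def of(self, leaves) -> float:
        return self.support[frozenset(leaves)]


def _sample_matrix(values: pd.DataFrame, selected_genes) -> pd.DataFrame:
    sub = values if selected_genes is None else values.loc[list(selected_genes)]
    if sub.isna().all(axis=0).any():
        bad = sub.columns[sub.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing sample column(s): {bad}")
    sub = sub.dropna(axis=0, how="any")  # distances need complete rows
    if sub.shape[0] < 1:
        raise ValueError("no complete genes available for clustering")
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 sample columns")
    return sub


def average_linkage(values: pd.DataFrame, selected_genes=None) -> Dendrogram:
    """UPGMA tree on Euclidean distances between sample columns.

    Genes with any missing value among the selection are excluded from the
    distance computation (distances require complete vectors).
    """
    sub = _sample_matrix(values, selected_genes)
    Z = hierarchy.linkage(sub.T.to_numpy(), method="average", metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(sub.columns))


def cut_to_k(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into k clusters by removing the k-1 highest merges."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return dict(zip(dendrogram.labels, (int(c) for c in flat)))


def bootstrap_support(
    values: pd.DataFrame,
    selected_genes=None,
    n_boot: int = 1000,
    seed: int = 0,
    resample: str = "genes",
) -> tuple[Dendrogram, ClusterSupport]:
    """Gene-resampling bootstrap support for every clade of the UPGMA tree.

    Each replicate redraws the selected genes with replacement, reclusters
    the samples, and checks which reference clades reappear.  With
    ``resample="samples"`` the replicate instead redraws sample columns and
    a reference clade counts as recovered when its restriction to the drawn
    (de-duplicated) leaves reappears as a clade.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if resample not in ("genes", "samples"):
        raise ValueError(f"unknown resample mode {resample!r}")
    sub = _sample_matrix(values, selected_genes)
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 selected genes for bootstrap")
    ref = Dendrogram(
        linkage=hierarchy.linkage(sub.T.to_numpy(), method="average", metric="euclidean"),
        labels=list(sub.columns),
    )
    ref_clades = ref.clades()
    counts = {c: 0 for c in ref_clades}
    rng = np.random.default_rng(seed)
    X = sub.to_numpy()
    labels = list(sub.columns)
    for _ in range(n_boot):
        if resample == "genes":
            rows = rng.integers(0, X.shape[0], size=X.shape[0])
            Zb = hierarchy.linkage(X[rows].T, method="average", metric="euclidean")
            boot = Dendrogram(Zb, labels)
            present = set(boot.clades())
            for c in ref_clades:
                if c in present:
                    counts[c] += 1
        else:
            cols = sorted(set(rng.integers(0, X.shape[1], size=X.shape[1])))
            if len(cols) < 2:
                continue
            sub_labels = [labels[j] for j in cols]
            Zb = hierarchy.linkage(X[:, cols].T, method="average", metric="euclidean")
            present = set(Dendrogram(Zb, sub_labels).clades())
            kept = set(sub_labels)
            for c in ref_clades:
                r = frozenset(c & kept)
                if len(r) >= 2 and r in present:
                    counts[c] += 1
    support = {c: counts[c] / n_boot for c in ref_clades}
    return ref, ClusterSupport(support=support, n_bootstrap=n_boot)
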