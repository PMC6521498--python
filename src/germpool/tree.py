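"""Shared-allele distances, Ward dendrograms, and locus-bootstrap support.

The genetic distance between two accessions is ``D = 1 - PSA`` where PSA
is the proportion of shared alleles: at each locus called in both
accessions the number of alleles shared counting multiplicity (0, 1, or
2) is summed and divided by twice the number of co-called loci.  For alt
dosages ``g_i, g_j`` the shared count is simply ``2 - |g_i - g_j|``.

Hierarchical clustering uses Ward's agglomerative criterion; confidence
in the tree topology comes from bootstrapping loci (resample loci with
replacement, recompute distances and the tree, count how many replicate
trees contain each original bipartition as a leaf-set split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from germpool.io import GenotypeMatrix


@dataclass
class DistanceMatrix:
    accessions: list[str]
    D: np.ndarray  # (n, n) symmetric, zero diagonal
    pair_loci: np.ndarray | None = None  # per-pair co-called locus counts

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.accessions)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


@dataclass
class Dendrogram:
    """Rooted binary merge tree (scipy linkage encoding) with supports.

    ``linkage`` rows are scipy-style merges; ``support`` maps internal
    nodes (by linkage row) to bootstrap counts out of ``n_boot``.
    """

    leaf_names: list[str]
    linkage: np.ndarray  # (n-1, 4)
    support: dict[int, int] = field(default_factory=dict)
    n_boot: int = 0
    presented_min: int = 650  # supports above this are flagged for display

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf-name set under each internal node (root and leaves excluded
        from 'informative' use but the full list is returned per node)."""
        n = self.n_leaves
        clusters: list[set[int]] = [{i} for i in range(n)]
        out: list[frozenset[str]] = []
        for a, b, _, _ in self.linkage:
            merged = clusters[int(a)] | clusters[int(b)]
            clusters.append(merged)
            out.append(frozenset(self.leaf_names[i] for i in merged))
        return out

    def presented_supports(self) -> dict[int, int]:
        return {k: v for k, v in self.support.items() if v > self.presented_min}

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = self.linkage[:, 2]

        def node_height(idx: int) -> float:
            return 0.0 if idx < n else heights[idx - n]

        def render(idx: int, parent_h: float) -> str:
            bl = max(parent_h - node_height(idx), 0.0) / 2.0  # split height between children
            if idx < n:
                return f"{self.leaf_names[idx]}:{bl:.6g}"
            row = idx - n
            a, b = int(self.linkage[row, 0]), int(self.linkage[row, 1])
            h = heights[row]
            label = str(self.support[row]) if row in self.support else ""
            return f"({render(a, h)},{render(b, h)}){label}:{bl:.6g}"

        root = n + len(self.linkage) - 1
        row = root - n
        a, b = int(self.linkage[row, 0]), int(self.linkage[row, 1])
        h = heights[row]
        label = str(self.support[row]) if row in self.support else ""
        return f"({render(a, h)},{render(b, h)}){label};"

    def cluster_labels(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")


def psa_distance(genos: GenotypeMatrix, allow_missing_pairs: bool = False) -> DistanceMatrix:
    """Pairwise 1 - PSA distances with pairwise-complete locus handling.

    Loci missing in either member of a pair are dropped for that pair and
    the per-pair locus count L is recorded.  A pair with zero co-called
    loci is an error unless ``allow_missing_pairs`` (then NaN).
    """
    if genos.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    g = genos.geno.astype(np.int16)
    called = genos.called_mask()
    n = genos.n_accessions
    D = np.zeros((n, n))
    L = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = called[i] & called[i + 1 :]
        diff = np.abs(g[i] - g[i + 1 :]) * both
        li = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = diff.sum(axis=1) / (2.0 * li)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
        L[i, i + 1 :] = li
        L[i + 1 :, i] = li
    if np.isnan(D).any() and not allow_missing_pairs:
        raise ValueError("some accession pair shares no called loci")
    return DistanceMatrix(accessions=list(genos.accessions), D=D, pair_loci=L)


def ward_tree(dist: DistanceMatrix, squared: bool = True) -> Dendrogram:
    """Ward agglomerative tree from a distance matrix.

    With ``squared=True`` the standard Ward.D2 criterion is used (scipy's
    ``ward`` on the distances directly); ``squared=False`` applies the
    unsquared variant by feeding sqrt-transformed distances.
    """
    cond = dist.condensed()
    if np.isnan(cond).any():
        raise ValueError("cannot build a tree from missing distances")
    Z = hierarchy.linkage(cond if squared else np.sqrt(cond), method="ward")
    return Dendrogram(leaf_names=list(dist.accessions), linkage=Z)


def _bipartition_set(dend: Dendrogram) -> set[frozenset[str]]:
    all_leaves = frozenset(dend.leaf_names)
    out = set()
    for clade in dend.bipartitions():
        if 1 < len(clade) < len(all_leaves):
            # canonical form: the smaller side (ties: lexicographically first)
            other = all_leaves - clade
            key = min(clade, other, key=lambda s: (len(s), sorted(s)))
            out.add(frozenset(key))
    return out


def bootstrap_support(
    genos: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    squared: bool = True,
    tree: Dendrogram | None = None,
) -> Dendrogram:
    """Locus-bootstrap bipartition support for the Ward tree.

    Each replicate resamples loci with replacement, recomputes PSA
    distances and the Ward tree; an original bipartition's support is the
    number of replicates whose tree contains it (topological containment,
    branch lengths ignored).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if tree is None:
        tree = ward_tree(psa_distance(genos), squared=squared)
    all_leaves = frozenset(tree.leaf_names)

    def canon(clade: frozenset[str]) -> frozenset[str]:
        other = all_leaves - clade
        return frozenset(min(clade, other, key=lambda s: (len(s), sorted(s))))

    originals = tree.bipartitions()
    counts = {row: 0 for row in range(len(originals))}
    rng = np.random.default_rng(seed)
    L = genos.n_loci
    # canonical accession order makes replicate tie-breaks (frequent with
    # discrete genotype distances) independent of input row order
    order = np.argsort(genos.accessions)
    canonical = genos.subset_accessions(order)
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        rep = ward_tree(psa_distance(canonical.subset_loci(idx), allow_missing_pairs=False), squared=squared)
        rep_parts = _bipartition_set(rep)
        for row, clade in enumerate(originals):
            if len(clade) == len(all_leaves):
                counts[row] += 1  # root: trivially present
            elif len(clade) > 1 and canon(clade) in rep_parts:
                counts[row] += 1
    tree.support = counts
    tree.n_boot = n_boot
    return tree


def cut_k_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into k clusters; returns accession -> cluster id."""
    labels = tree.cluster_labels(k)
    return {name: int(lab) for name, lab in zip(tree.leaf_names, labels)}
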