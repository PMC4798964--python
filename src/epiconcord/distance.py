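"""Sample-to-sample epigenomic distance matrices (1 - Pearson r over binned
methylation; 1 - Jaccard over peak sets) and hierarchical clustering with a
deterministic leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomic import RegionSet, jaccard
from .methylome import Methylome, bin_meth_levels

__all__ = [
    "DistanceMatrix",
    "ClusterParams",
    "ClusterResult",
    "pearson_distance_matrix",
    "jaccard_distance_matrix",
    "hierarchical_cluster",
]


@dataclass
class ClusterParams:
    bin_size: int = 500
    linkage: str = "average"
    min_common_bins: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.linkage not in ("average", "complete", "single"):
            raise ValueError("linkage must be average, complete, or single")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str  # "one_minus_r" or "one_minus_jaccard"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")
        lo, hi = (0.0, 2.0) if self.metric == "one_minus_r" else (0.0, 1.0)
        if (v < lo - 1e-9).any() or (v > hi + 1e-9).any():
            raise ValueError(f"distances out of range for metric {self.metric}")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def pearson_distance_matrix(
    methylomes: list[Methylome], p: ClusterParams | None = None
) -> DistanceMatrix:
    """1 - Pearson r of binned CG methylation levels, per sample pair.

    Bins missing in either member of a pair are excluded pairwise; a pair must
    share >= ``min_common_bins`` informative bins.
    """
    p = p or ClusterParams()
    if len(methylomes) < 2:
        raise ValueError("need at least two methylomes")
    labels = [m.sample_label or f"sample_{i}" for i, m in enumerate(methylomes)]
    binned = [bin_meth_levels(m, bin_size=p.bin_size) for m in methylomes]
    chroms = sorted(set().union(*[set(b.mc) for b in binned]))
    n_bins = {
        c: max(len(b.mc[c]) if c in b.mc else 0 for b in binned) for c in chroms
    }
    vecs = []
    for b in binned:
        parts = []
        for c in chroms:
            arr = b.level(c) if c in b.mc else np.array([])
            pad = np.full(n_bins[c] - len(arr), np.nan)
            parts.append(np.concatenate([arr, pad]))
        vecs.append(np.concatenate(parts))
    n = len(vecs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(vecs[i]) & ~np.isnan(vecs[j])
            if ok.sum() < p.min_common_bins:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) shares only {int(ok.sum())} "
                    f"bins (< {p.min_common_bins})"
                )
            r = float(np.corrcoef(vecs[i][ok], vecs[j][ok])[0, 1])
            d[i, j] = d[j, i] = 1.0 - r
    return DistanceMatrix(labels=labels, values=d, metric="one_minus_r")


def jaccard_distance_matrix(peak_sets: list[RegionSet]) -> DistanceMatrix:
    """1 - base-pair Jaccard index per pair of peak sets; empty sets get
    distance 1 to every other set."""
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    labels = [rs.label or f"set_{i}" for i, rs in enumerate(peak_sets)]
    n = len(peak_sets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(peak_sets[i]) == 0 or len(peak_sets[j]) == 0:
                d[i, j] = d[j, i] = 1.0
            else:
                d[i, j] = d[j, i] = 1.0 - jaccard(peak_sets[i], peak_sets[j])
    return DistanceMatrix(labels=labels, values=d, metric="one_minus_jaccard")


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    leaf_order: list[str]
    newick: str

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


class _Node:
    __slots__ = ("left", "right", "height", "label")

    def __init__(self, label=None, left=None, right=None, height=0.0):
        self.label = label
        self.left = left
        self.right = right
        self.height = height

    @property
    def min_label(self) -> str:
        if self.label is not None:
            return self.label
        return min(self.left.min_label, self.right.min_label)

    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def newick(self, parent_height: float | None = None) -> str:
        bl = (
            f":{max(parent_height - self.height, 0.0):.6g}"
            if parent_height is not None
            else ""
        )
        if self.label is not None:
            return f"{self.label}{bl}"
        return f"({self.left.newick(self.height)},{self.right.newick(self.height)}){bl}"


def hierarchical_cluster(
    d: DistanceMatrix, p: ClusterParams | None = None
) -> ClusterResult:
    """Agglomerative clustering of a distance matrix.

    Children of every internal node are ordered by their smallest leaf label,
    so the leaf order is deterministic and invariant to input permutation
    (up to tree isomorphism)."""
    p = p or ClusterParams()
    condensed = squareform(d.values, checks=True)
    Z = hierarchy.linkage(condensed, method=p.linkage)
    nodes: list[_Node] = [_Node(label=lab) for lab in d.labels]
    for li, (a, b, h, _cnt) in enumerate(Z):
        left, right = nodes[int(a)], nodes[int(b)]
        if right.min_label < left.min_label:
            left, right = right, left
        nodes.append(_Node(left=left, right=right, height=float(h)))
    root = nodes[-1]
    return ClusterResult(
        linkage=Z,
        labels=list(d.labels),
        leaf_order=root.leaves(),
        newick=root.newick() + ";",
    )
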