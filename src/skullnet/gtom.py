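"""GTOM similarity and the UPGMA dendrogram underlying module detection.

The generalized topological overlap measure (GTOM) scores two bones as similar
when they articulate with the same neighbours; 1 - GTOM is then a clustering
distance and average-linkage (UPGMA) agglomeration turns it into an
ultrametric dendrogram whose subtrees are the candidate skull modules.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .net_io import AnatomicalNetwork

__all__ = [
    "GtomMatrix",
    "Dendrogram",
    "gtom",
    "dissimilarity",
    "upgma",
    "network_dendrogram",
]


@dataclasses.dataclass(frozen=True)
class GtomMatrix:
    """Topological overlap t_ij in [0, 1]; diagonal 1; symmetric."""

    nodes: tuple[str, ...]
    overlap: np.ndarray
    steps: int


@dataclasses.dataclass(frozen=True)
class Dendrogram:
    """A UPGMA merge tree in scipy linkage convention.

    ``merges`` holds N-1 rows (a, b, height, size) where a and b index either
    leaves (0..N-1, in ``leaves`` order) or earlier merges (N+i). Heights are
    non-decreasing (average linkage is monotonic, so the tree is ultrametric).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        object.__setattr__(self, "merges", tuple(tuple(m) for m in self.merges))
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def linkage_matrix(self) -> np.ndarray:
        return np.asarray([list(m) for m in self.merges], dtype=float)

    def _member_lists(self) -> list[list[int]]:
        """Leaf index members for every cluster id (leaves then merges)."""
        n = len(self.leaves)
        members: list[list[int]] = [[i] for i in range(n)]
        for a, b, _, _ in self.merges:
            members.append(members[int(a)] + members[int(b)])
        return members

    def clusters(self) -> list[tuple[frozenset[str], float]]:
        """Every internal cluster as (leaf-label set, merge height)."""
        members = self._member_lists()
        n = len(self.leaves)
        out = []
        for i, (_, _, h, _) in enumerate(self.merges):
            out.append((frozenset(self.leaves[j] for j in members[n + i]), float(h)))
        return out

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k clusters by undoing the last k-1 merges."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        members = self._member_lists()
        for a, b, _, _ in self.merges[: n - k]:
            ra = find(members[int(a)][0])
            rb = find(members[int(b)][0])
            parent[rb] = ra
        roots: dict[int, int] = {}
        out: dict[str, int] = {}
        for i, label in enumerate(self.leaves):
            r = find(i)
            out[label] = roots.setdefault(r, len(roots))
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Cophenetic distances: the height at which each leaf pair first merges."""
        n = len(self.leaves)
        members = self._member_lists()
        coph = np.zeros((n, n))
        for idx, (a, b, h, _) in enumerate(self.merges):
            left = members[int(a)]
            right = members[int(b)]
            for i in left:
                coph[i, right] = h
                coph[right, i] = h
        return coph

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths from merge heights."""
        n = len(self.leaves)
        height = [0.0] * n + [m[2] for m in self.merges]

        def render(i: int) -> str:
            if i < n:
                return self.leaves[i]
            a, b, h, _ = self.merges[i - n]
            parts = ",".join(
                f"{render(int(c))}:{h - height[int(c)]:.10g}" for c in (a, b)
            )
            return f"({parts})"

        return render(n + len(self.merges) - 1) + ";"


def gtom(net: AnatomicalNetwork, m: int = 1) -> GtomMatrix:
    """Generalized topological overlap matrix of order m.

    For m=1, t_ij = (|shared neighbours| + a_ij) / (min(k_i, k_j) + 1 - a_ij);
    for m>1 the same formula is applied to the m-step neighbourhoods (nodes
    reachable within m edges, excluding the node itself). t_ii = 1. Pairs of
    isolated nodes, where the denominator vanishes, get t_ij = 0 so that
    isolates are maximally distant from everything.
    """
    if m < 1:
        raise ValueError("neighborhood order m must be >= 1")
    a = net.adjacency.astype(bool)
    n = net.n_nodes
    if m == 1:
        nb = a.copy()
    else:
        reach = a | np.eye(n, dtype=bool)
        nb = np.linalg.matrix_power(reach.astype(np.int64), m) > 0
        np.fill_diagonal(nb, False)
    shared = (nb.astype(np.int64) @ nb.astype(np.int64)).astype(float)
    k = nb.sum(axis=0).astype(float)
    a_f = net.adjacency.astype(float)
    denom = np.minimum.outer(k, k) + 1.0 - a_f
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (shared + a_f) / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    return GtomMatrix(nodes=net.nodes, overlap=t, steps=m)


def dissimilarity(g: GtomMatrix) -> np.ndarray:
    """Distance matrix d_ij = 1 - t_ij with a zero diagonal."""
    d = 1.0 - g.overlap
    np.fill_diagonal(d, 0.0)
    return d


def upgma(dist: np.ndarray, labels) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the two clusters with smallest average inter-cluster distance
    merge at a height equal to that average; the Lance-Williams update keeps
    averages exact. Ties are broken deterministically toward the candidate
    merge whose combined, sorted member-label tuple is lexicographically
    smallest, so reruns and relabelings behave predictably.
    """
    d = np.asarray(dist, dtype=float)
    labels = tuple(str(x) for x in labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(d).any():
        raise ValueError("NaN distances")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    # active clusters: id -> (sorted member-label tuple, size, linkage id)
    work = d.copy()
    active = list(range(n))
    members = {i: (labels[i],) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    link_id = {i: i for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                p, q = active[ii], active[jj]
                dist_pq = work[p, q]
                key = (dist_pq, tuple(sorted(members[p] + members[q])))
                if best is None or key < best[0]:
                    best = (key, p, q)
        (dist_pq, _), p, q = best
        # Lance-Williams average-linkage update
        for r in active:
            if r in (p, q):
                continue
            work[p, r] = work[r, p] = (
                sizes[p] * work[p, r] + sizes[q] * work[q, r]
            ) / (sizes[p] + sizes[q])
        merges.append((link_id[p], link_id[q], float(dist_pq), sizes[p] + sizes[q]))
        members[p] = tuple(sorted(members[p] + members[q]))
        sizes[p] = sizes[p] + sizes[q]
        link_id[p] = next_id
        next_id += 1
        active.remove(q)
    return Dendrogram(leaves=labels, merges=tuple(merges))


def network_dendrogram(net: AnatomicalNetwork, m: int = 1) -> Dendrogram:
    """Convenience pipeline: GTOM -> dissimilarity -> UPGMA."""
    return upgma(dissimilarity(gtom(net, m=m)), net.nodes)
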