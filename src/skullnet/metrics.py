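"""Whole-network parameters of an anatomical network.

Seven descriptors summarize each skull network and together form one row of
the topospace parameter table:

- N: number of nodes (bones), isolated bones included;
- K: number of undirected connections (articulations);
- D: density, K over the N(N-1)/2 possible connections;
- C: mean clustering coefficient (local transitivity averaged over nodes);
- L: mean shortest path length over finite (same-component) pairs;
- H: heterogeneity of connections, the coefficient of variation of the degree
  sequence — a proxy for anisomerism;
- P: parcellation, 1 - sum((N_i/N)^2) over communities found by leading
  eigenvector community detection, measuring how extensively and how evenly
  the network is subdivided.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import networkx as nx
import scipy.linalg

from .net_io import AnatomicalNetwork

__all__ = [
    "NetworkParameters",
    "CommunityPartition",
    "UndefinedParameterError",
    "density",
    "mean_clustering",
    "mean_path_length",
    "heterogeneity",
    "detect_communities_leading_eigenvector",
    "parcellation",
    "compute_all_parameters",
]

_EIG_TOL = 1e-10


class UndefinedParameterError(ValueError):
    """A parameter is undefined for this network (e.g. K=0 path length)."""


@dataclasses.dataclass(frozen=True)
class NetworkParameters:
    """One taxon's row of whole-network descriptors."""

    taxon: str
    N: int
    K: int
    D: float
    C: float
    L: float
    H: float
    P: float


@dataclasses.dataclass(frozen=True)
class CommunityPartition:
    """A disjoint cover of the nodes by communities."""

    assignment: dict[str, int]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for c in self.assignment.values():
            counts[c] = counts.get(c, 0) + 1
        object.__setattr__(self, "sizes", tuple(sorted(counts.values(), reverse=True)))

    @property
    def n_communities(self) -> int:
        return len(self.sizes)


def density(net: AnatomicalNetwork) -> float:
    """Connection density D = 2K / (N(N-1))."""
    n = net.n_nodes
    if n < 2:
        raise UndefinedParameterError("density undefined for N < 2")
    return 2.0 * net.n_edges / (n * (n - 1))


def mean_clustering(net: AnatomicalNetwork, low_degree: str = "exclude") -> float:
    """Mean clustering coefficient C.

    ``low_degree`` controls nodes with fewer than two neighbours, whose local
    coefficient is undefined: ``"exclude"`` (default) omits them from the
    average; ``"zero"`` counts them as 0.
    """
    if low_degree not in ("exclude", "zero"):
        raise ValueError("low_degree must be 'exclude' or 'zero'")
    g = net.to_networkx()
    local = nx.clustering(g)
    deg = dict(g.degree())
    if low_degree == "exclude":
        vals = [local[v] for v in g if deg[v] >= 2]
        if not vals:
            raise UndefinedParameterError("no node with degree >= 2")
        return float(np.mean(vals))
    return float(np.mean([local[v] for v in g]))


def mean_path_length(net: AnatomicalNetwork) -> float:
    """Mean shortest path length L over all finite unordered pairs.

    Pairs in different connected components have no path and are excluded —
    skull networks with isolated bones still print a finite L.
    """
    if net.n_edges == 0:
        raise UndefinedParameterError("path length undefined with K = 0")
    g = net.to_networkx()
    total = 0
    count = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            count += len(dists) - 1  # drop the self distance
    # ordered pairs counted twice; ratio unaffected but keep unordered semantics
    return total / count


def heterogeneity(net: AnatomicalNetwork, sd: str = "sample") -> float:
    """Heterogeneity H = sd(degree) / mean(degree).

    Degree-0 nodes are included in the degree sequence. ``sd`` selects the
    sample (n-1, default) or population (n) standard deviation.
    """
    if sd not in ("sample", "population"):
        raise ValueError("sd must be 'sample' or 'population'")
    k = net.degrees()
    if k.mean() == 0:
        raise UndefinedParameterError("heterogeneity undefined when all degrees are 0")
    ddof = 1 if sd == "sample" else 0
    return float(np.std(k, ddof=ddof) / k.mean())


def _leading_eigen_split(b_sub: np.ndarray) -> np.ndarray | None:
    """Sign split from the leading eigenvector of a subgraph modularity matrix.

    Returns the +/-1 membership vector, or None when the leading eigenvalue is
    non-positive (subgraph indivisible). Zero entries go to the positive side;
    the eigenvector's global sign is fixed by its largest-magnitude entry.
    """
    vals, vecs = scipy.linalg.eigh(b_sub)
    lead = np.argmax(vals)
    if vals[lead] <= _EIG_TOL:
        return None
    v = vecs[:, lead]
    anchor = np.argmax(np.abs(v))
    if v[anchor] < 0:
        v = -v
    s = np.where(v >= 0, 1.0, -1.0)
    return s


def detect_communities_leading_eigenvector(net: AnatomicalNetwork) -> CommunityPartition:
    """Newman's leading-eigenvector community detection by recursive bisection.

    The modularity matrix B = A - k k^T / 2K is bisected along the sign
    pattern of its leading eigenvector; each half is re-bisected using the
    generalized modularity matrix B^(g) = B_g - diag(rowsums of B_g) until the
    leading eigenvalue is non-positive or the split no longer increases Q.
    Degree-0 nodes each form their own singleton community (the algorithm's
    null model has nothing to say about them and the skull networks contain
    genuinely isolated bones).
    """
    a = net.adjacency.astype(float)
    k = a.sum(axis=0)
    two_k = k.sum()
    labels: dict[str, int] = {}
    next_label = 0
    isolated = np.where(k == 0)[0]
    for i in isolated:
        labels[net.nodes[i]] = next_label
        next_label += 1
    active = np.where(k > 0)[0]
    if active.size == 0:
        return CommunityPartition(assignment=labels, sizes=())
    b_full = a - np.outer(k, k) / two_k

    stack = [active]
    while stack:
        group = stack.pop()
        if group.size == 1:
            labels[net.nodes[group[0]]] = next_label
            next_label += 1
            continue
        b_g = b_full[np.ix_(group, group)]
        b_sub = b_g - np.diag(b_g.sum(axis=1))
        s = _leading_eigen_split(b_sub)
        if s is None:
            split_ok = False
        else:
            delta_q = s @ b_sub @ s / (2.0 * two_k)
            split_ok = delta_q > _EIG_TOL and (s > 0).any() and (s < 0).any()
        if not split_ok:
            for i in group:
                labels[net.nodes[i]] = next_label
            next_label += 1
            continue
        stack.append(group[s > 0])
        stack.append(group[s < 0])
    return CommunityPartition(assignment=labels, sizes=())


def parcellation(net: AnatomicalNetwork, partition: CommunityPartition | None = None) -> float:
    """Parcellation P = 1 - sum((N_i/N)^2) over detected communities.

    P is 0 for a single community and approaches 1 - 1/N as the network
    fragments into many evenly-sized communities.
    """
    if partition is None:
        partition = detect_communities_leading_eigenvector(net)
    n = net.n_nodes
    return 1.0 - sum((s / n) ** 2 for s in partition.sizes)


def compute_all_parameters(
    net: AnatomicalNetwork,
    low_degree: str = "exclude",
    sd: str = "sample",
) -> NetworkParameters:
    """All seven whole-network parameters as one table row."""
    return NetworkParameters(
        taxon=net.specimen_id,
        N=net.n_nodes,
        K=net.n_edges,
        D=density(net),
        C=mean_clustering(net, low_degree=low_degree),
        L=mean_path_length(net),
        H=heterogeneity(net, sd=sd),
        P=parcellation(net),
    )
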