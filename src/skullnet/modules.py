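"""Q-module and S-module detection on GTOM-UPGMA dendrograms.

Two complementary module definitions are used on each skull dendrogram:

* Q-modules: the dendrogram cut (over every possible number of clusters)
  whose induced node partition maximizes Newman-Girvan modularity Q computed
  on the original binary articulation network.
* S-modules: dendrogram clusters whose members have significantly more
  connections inside the cluster than outside, by a one-sided two-sample
  Mann-Whitney (Wilcoxon rank-sum) test, tiered at p < 0.001 / 0.01 / 0.05.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import scipy.stats

from .net_io import AnatomicalNetwork
from .gtom import Dendrogram

__all__ = [
    "QModuleResult",
    "SModuleResult",
    "newman_girvan_q",
    "q_modules",
    "mann_whitney_one_sided",
    "s_modules",
    "significance_tier",
    "module_report",
]

TIERS = ("p<0.001", "0.001<=p<0.01", "0.01<=p<0.05", "ns")


@dataclasses.dataclass(frozen=True)
class QModuleResult:
    """Q-maximizing dendrogram cut with the full (k, Q) profile."""

    partition: dict[str, int]
    q_value: float
    q_profile: tuple[tuple[int, float], ...]


@dataclasses.dataclass(frozen=True)
class SModuleResult:
    """One dendrogram cluster with its internal-vs-external connectivity test."""

    cluster: frozenset[str]
    internal_counts: tuple[int, ...]
    external_counts: tuple[int, ...]
    u_statistic: float
    p_value: float
    tier: str
    degenerate: bool = False  # cluster == whole network, no outside sample


def significance_tier(p: float) -> str:
    if p < 0.001:
        return TIERS[0]
    if p < 0.01:
        return TIERS[1]
    if p < 0.05:
        return TIERS[2]
    return TIERS[3]


def newman_girvan_q(net: AnatomicalNetwork, partition: dict[str, int]) -> float:
    """Modularity Q = sum_s (e_ss - a_s^2).

    e_ss is the fraction of edges with both endpoints in module s and a_s the
    fraction of edge endpoints in s. Q is 0 when within-module connectivity
    matches the random expectation and grows with excess internal wiring.
    """
    missing = set(net.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    k_total = net.n_edges
    if k_total == 0:
        raise ValueError("Q undefined for a network with no connections")
    mods = sorted(set(partition[v] for v in net.nodes))
    mod_index = {m: i for i, m in enumerate(mods)}
    labels = np.array([mod_index[partition[v]] for v in net.nodes])
    a = net.adjacency
    q = 0.0
    two_k = 2.0 * k_total
    for s in range(len(mods)):
        mask = labels == s
        e_ss = a[np.ix_(mask, mask)].sum() / two_k
        a_s = a[mask, :].sum() / two_k
        q += e_ss - a_s**2
    return float(q)


def q_modules(net: AnatomicalNetwork, dend: Dendrogram) -> QModuleResult:
    """Cut the dendrogram at the modularity-maximizing partition.

    Q is evaluated on the partition induced by every cut (k = 1..N clusters);
    the arg-max is returned with the full profile. Ties are broken toward
    fewer clusters.
    """
    if set(dend.leaves) != set(net.nodes):
        raise ValueError("dendrogram leaves do not match network nodes")
    n = len(dend.leaves)
    best_partition = None
    best_q = -np.inf
    profile = []
    for k in range(1, n + 1):
        part = dend.cut(k)
        q = newman_girvan_q(net, part)
        profile.append((k, q))
        if q > best_q + 1e-12:
            best_q = q
            best_partition = part
    return QModuleResult(
        partition=best_partition, q_value=float(best_q), q_profile=tuple(profile)
    )


def _exact_mwu_p(ranks2: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact P(U >= u_obs) by counting n1-subsets via a rank-sum DP.

    ``ranks2`` are doubled mid-ranks (integers even under ties). U is a
    monotone shift of the internal rank sum, so counting subsets whose rank
    sum reaches the observed one enumerates the permutation null exactly —
    including tied data, where the null conditions on the observed values.
    """
    total_target = 2 * u_obs + n1 * (n1 + 1)  # doubled rank-sum threshold
    max_sum = int(ranks2.sum())
    # dp[k][s]: number of size-k subsets with doubled rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)  # doubled mid-ranks are >= 2
        for k in range(n1, 0, -1):  # 0/1-knapsack order: each item used once
            dp[k, r:] += dp[k - 1, :-r]
    counts = dp[n1]
    total = counts.sum()
    threshold = int(np.ceil(total_target - 1e-9))
    return float(counts[threshold:].sum() / total)


def mann_whitney_one_sided(sample_internal, sample_external) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of internal > external.

    The U statistic counts (internal, external) pairs with internal larger
    (ties count 1/2). For combined sample sizes up to 20 the p-value is the
    exact permutation null, enumerated by dynamic programming over rank sums
    (valid with or without ties); larger samples use the normal approximation
    with tie and continuity corrections. Returns (U, one-sided p).
    """
    x = np.asarray(sample_internal, dtype=float)
    y = np.asarray(sample_external, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= 20:
        ranks2 = np.rint(2 * ranks).astype(int)
        return u, _exact_mwu_p(ranks2, n1, u)
    res = scipy.stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _cluster_counts(net: AnatomicalNetwork, cluster: frozenset[str]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([net.index_of(v) for v in sorted(cluster)])
    a = net.adjacency
    internal = a[np.ix_(idx, idx)].sum(axis=1)
    external = a[idx, :].sum(axis=1) - internal
    return internal.astype(int), external.astype(int)


def s_modules(net: AnatomicalNetwork, dend: Dendrogram) -> list[SModuleResult]:
    """Test every dendrogram cluster for internal > external connectivity.

    For each internal node of the merge tree (cluster size >= 2) the per-bone
    counts of within-cluster and outside-cluster articulations form the two
    samples of a one-sided Mann-Whitney test. The root cluster (the whole
    network) has no outside and is reported with ``degenerate=True`` and
    p = 1. Raw p-values are reported without multiple-testing correction and
    tiered as in the standard figure convention.
    """
    if set(dend.leaves) != set(net.nodes):
        raise ValueError("dendrogram leaves do not match network nodes")
    out = []
    all_nodes = frozenset(net.nodes)
    for cluster, _height in dend.clusters():
        internal, external = _cluster_counts(net, cluster)
        if cluster == all_nodes:
            out.append(
                SModuleResult(
                    cluster=cluster,
                    internal_counts=tuple(internal),
                    external_counts=tuple(external),
                    u_statistic=float("nan"),
                    p_value=1.0,
                    tier="ns",
                    degenerate=True,
                )
            )
            continue
        u, p = mann_whitney_one_sided(internal, external)
        out.append(
            SModuleResult(
                cluster=cluster,
                internal_counts=tuple(internal),
                external_counts=tuple(external),
                u_statistic=u,
                p_value=p,
                tier=significance_tier(p),
            )
        )
    return out


def module_report(net: AnatomicalNetwork, dend: Dendrogram) -> dict:
    """JSON-serializable per-specimen module report."""
    qres = q_modules(net, dend)
    sres = s_modules(net, dend)
    mods: dict[int, list[str]] = {}
    for node, mid in qres.partition.items():
        mods.setdefault(mid, []).append(node)
    report = {
        "specimen": net.specimen_id,
        "q_max": qres.q_value,
        "modules": [
            {"id": mid, "members": sorted(members)}
            for mid, members in sorted(mods.items())
        ],
        "s_modules": [
            {
                "members": sorted(s.cluster),
                "U": None if np.isnan(s.u_statistic) else s.u_statistic,
                "p": s.p_value,
                "tier": s.tier,
                "degenerate": s.degenerate,
            }
            for s in sres
        ],
    }
    json.dumps(report)  # guarantee serializability
    return report
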