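"""Synthetic skull-like networks, trees and trait tables.

Real inputs to the pipeline are CT-derived articulation matrices, a dated
phylogeny and per-taxon trait tables; the generators here emulate their
statistical structure so every stage is testable without downloads:

* bilaterally symmetric networks with paired left/right bones plus unpaired
  midline bones, planted modules of differing within/between connection
  density, and optional isolated bones (the anomalepidid jugal has degree 0);
* pure-birth (Yule) ultrametric trees;
* trait tables evolved by Brownian motion on a tree with additive group
  effects, the model under which the phylogenetic PCA corrects and the
  group-separation PERMANOVA rejects.

Defaults mirror the empirical study conditions: networks of roughly 30-57
bones and trees of about 53 tips.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import dendropy

from .net_io import AnatomicalNetwork, LateralityMap, write_adjacency
from .topospace import shared_path_matrix

__all__ = [
    "SkullNetSpec",
    "TraitSimSpec",
    "generate_skull_network",
    "generate_pure_birth_tree",
    "simulate_bm_traits",
    "make_fixture_suite",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ("N", "K", "D", "C", "L", "H", "P")


@dataclasses.dataclass(frozen=True)
class SkullNetSpec:
    """Recipe for one bilaterally symmetric planted-module skull network.

    ``n_paired`` left/right bone pairs and ``n_midline`` unpaired bones are
    assigned to ``n_modules`` planted modules (mirror-consistently: both
    members of a pair share a module). Edges are Bernoulli with probability
    ``p_in`` within a module and ``p_out`` between modules, sampled on the
    left hemisphere + midline and mirrored. ``n_isolates`` bones receive no
    edges at all.
    """

    n_paired: int = 14
    n_midline: int = 5
    n_modules: int = 4
    p_in: float = 0.8
    p_out: float = 0.05
    n_isolates: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_modules < 1 or self.n_paired < 1:
            raise ValueError("need at least one module and one bone pair")
        if self.n_isolates > 2 * self.n_paired + self.n_midline:
            raise ValueError("more isolates than bones")


@dataclasses.dataclass(frozen=True)
class TraitSimSpec:
    """Recipe for Brownian-motion trait evolution with group effects.

    ``sigma2`` is the BM rate per variable (trait variance accrued per unit
    branch length); ``group_effects`` maps category -> per-variable additive
    offsets, applied according to ``group_of_tip``.
    """

    tree: dendropy.Tree
    sigma2: tuple[float, ...] = (1.0,) * len(TRAIT_COLUMNS)
    group_effects: dict[str, tuple[float, ...]] | None = None
    group_of_tip: dict[str, str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma2):
            raise ValueError("sigma2 must be positive")


def _module_sizes(total: int, n_modules: int) -> list[int]:
    base, extra = divmod(total, n_modules)
    return [base + (1 if i < extra else 0) for i in range(n_modules)]


def generate_skull_network(spec: SkullNetSpec) -> tuple[AnatomicalNetwork, LateralityMap, dict[str, int]]:
    """Sample one symmetric planted-module network.

    Returns the network, its laterality map and the planted module labels
    (isolates get module id -1). The mirror relabeling partitions unordered
    bone pairs into orbits of size one or two; one Bernoulli draw per orbit
    decides both mirrored edges at once, so bilateral symmetry is exact by
    construction while every within-module bone pair still has marginal edge
    probability p_in (and every between-module pair p_out), including
    cross-hemisphere contacts such as the junction of paired midline-adjacent
    bones.
    """
    rng = np.random.default_rng(spec.seed)
    lefts = [f"bone{i:02d}_L" for i in range(spec.n_paired)]
    rights = [f"bone{i:02d}_R" for i in range(spec.n_paired)]
    midline = [f"mid{i:02d}" for i in range(spec.n_midline)]
    nodes = lefts + rights + midline

    # mirror-consistent planted modules over pair slots and midline bones
    slots = spec.n_paired + spec.n_midline
    sizes = _module_sizes(slots, spec.n_modules)
    slot_module = np.repeat(np.arange(spec.n_modules), sizes)
    slot_module = rng.permutation(slot_module)
    planted: dict[str, int] = {}
    for i in range(spec.n_paired):
        planted[lefts[i]] = planted[rights[i]] = int(slot_module[i])
    for j in range(spec.n_midline):
        planted[midline[j]] = int(slot_module[spec.n_paired + j])

    # isolates: bone pairs first (both sides), then midline bones
    isolate_order = [x for pair in zip(lefts[::-1], rights[::-1]) for x in pair]
    isolate_order += midline[::-1]
    isolates = set(isolate_order[: spec.n_isolates])
    for iso in isolates:
        planted[iso] = -1

    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=int)
    mirror = {**{l: r for l, r in zip(lefts, rights)},
              **{r: l for l, r in zip(lefts, rights)},
              **{m: m for m in midline}}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            orbit = {frozenset((u, v)), frozenset((mirror[u], mirror[v]))}
            if min(orbit, key=lambda fs: tuple(sorted(fs))) != frozenset((u, v)):
                continue  # the mirrored pair is the orbit's representative
            if u in isolates or v in isolates:
                continue
            p = spec.p_in if planted[u] == planted[v] else spec.p_out
            if rng.random() < p:
                for fs in orbit:  # mirror is a bijection, so both pairs are edges
                    x, y = tuple(fs)
                    adj[idx[x], idx[y]] = adj[idx[y], idx[x]] = 1
    np.fill_diagonal(adj, 0)
    net = AnatomicalNetwork(
        specimen_id=f"synthetic_seed{spec.seed}", nodes=tuple(nodes), adjacency=adj
    )
    lat = LateralityMap(pairs=tuple(zip(lefts, rights)), midline=tuple(midline))
    return net, lat, planted


def generate_pure_birth_tree(n_tips: int, seed: int | None = None, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate an ultrametric Yule tree with exponential waiting times.

    Starting from two lineages at the root, each speciation waits an
    Exp(birth_rate * k) time with k the current lineage count, and a uniform
    lineage splits; all tips extend to the present.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # active lineage records: (birth_time,)
    birth = {0: 0.0, 1: 0.0}
    children: dict[int, tuple[int, int]] = {}
    active = [0, 1]
    next_id = 2
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        split = active[rng.integers(k)]
        a, b = next_id, next_id + 1
        next_id += 2
        birth[a] = birth[b] = t
        children[split] = (a, b)
        active.remove(split)
        active += [a, b]
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    tip_names = iter(f"t{i + 1}" for i in range(n_tips))

    def newick(node: int) -> str:
        if node in children:
            a, b = children[node]
            end_a = birth[children[a][0]] if a in children else t_end
            end_b = birth[children[b][0]] if b in children else t_end
            return (f"({newick(a)}:{end_a - birth[a]:.12g},"
                    f"{newick(b)}:{end_b - birth[b]:.12g})")
        return next(tip_names)

    end_0 = birth[children[0][0]] if 0 in children else t_end
    end_1 = birth[children[1][0]] if 1 in children else t_end
    s = (f"({newick(0)}:{end_0:.12g},{newick(1)}:{end_1:.12g});")
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


def simulate_bm_traits(spec: TraitSimSpec) -> pd.DataFrame:
    """Draw tip traits under Brownian motion plus additive group offsets.

    Each column j is multivariate normal with covariance sigma2[j] * C, where
    C is the tree's shared-path-length matrix; group offsets are added to the
    tips listed in ``group_of_tip``. Returns a parameter-table-shaped
    DataFrame (tip x trait) with the group column attached when groups are
    supplied.
    """
    tips = [leaf.taxon.label for leaf in spec.tree.leaf_node_iter()]
    c = shared_path_matrix(spec.tree, tips)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(c)
    p = len(spec.sigma2)
    z = rng.standard_normal((len(tips), p))
    x = chol @ z * np.sqrt(np.asarray(spec.sigma2))
    df = pd.DataFrame(x, index=pd.Index(tips, name="taxon"),
                      columns=list(TRAIT_COLUMNS)[:p])
    if spec.group_effects:
        if not spec.group_of_tip:
            raise ValueError("group_effects given without group_of_tip")
        for tip in tips:
            g = spec.group_of_tip[tip]
            df.loc[tip] += np.asarray(spec.group_effects[g])[:p]
        df["group"] = [spec.group_of_tip[t] for t in tips]
    return df


def _path_network() -> AnatomicalNetwork:
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return AnatomicalNetwork("path_ABC", ("A", "B", "C"), adj)


def _two_cliques(k: int = 4) -> AnatomicalNetwork:
    n = 2 * k
    adj = np.zeros((n, n), dtype=int)
    adj[:k, :k] = 1
    adj[k:, k:] = 1
    np.fill_diagonal(adj, 0)
    adj[k - 1, k] = adj[k, k - 1] = 1  # single bridge
    nodes = tuple(f"a{i}" for i in range(k)) + tuple(f"b{i}" for i in range(k))
    return AnatomicalNetwork("two_cliques", nodes, adj)


# (p_in, p_out) contrasts spanning easy / medium / hard module recovery
RECOVERY_REGIMES = {"easy": (0.9, 0.02), "medium": (0.6, 0.15), "hard": (0.3, 0.25)}


def make_fixture_suite(out_dir, seed: int = 0) -> list[Path]:
    """Write the deterministic fixture files used by tests and examples.

    Contents: a 3-bone path, two bridged 4-cliques, one planted-module skull
    network per recovery regime (easy/medium/hard), a 53-tip Yule tree and a
    matched Brownian trait table with habitat and size-class labels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_net(net: AnatomicalNetwork, name: str) -> None:
        path = out / f"{name}.csv"
        write_adjacency(net, path)
        written.append(path)

    save_net(_path_network(), "path")
    save_net(_two_cliques(), "two_cliques")
    for i, (regime, (p_in, p_out)) in enumerate(sorted(RECOVERY_REGIMES.items())):
        net, _, planted = generate_skull_network(
            SkullNetSpec(p_in=p_in, p_out=p_out, n_isolates=2, seed=seed + i)
        )
        save_net(
            AnatomicalNetwork(f"planted_{regime}", net.nodes, net.adjacency),
            f"planted_{regime}",
        )
        labels = out / f"planted_{regime}_modules.tsv"
        pd.Series(planted, name="module").rename_axis("node").to_csv(labels, sep="\t")
        written.append(labels)

    tree = generate_pure_birth_tree(53, seed=seed + 100)
    tree_path = out / "tree.nwk"
    tree_path.write_text(tree.as_string(schema="newick", suppress_rooting=True))
    written.append(tree_path)

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rng = np.random.default_rng(seed + 200)
    habitats = rng.choice(["fossorial", "semi-fossorial", "non-fossorial"],
                          size=len(tips), p=[0.55, 0.15, 0.30])
    effects = {
        "fossorial": tuple([-1.0] * 7),
        "semi-fossorial": tuple([0.0] * 7),
        "non-fossorial": tuple([1.0] * 7),
    }
    traits = simulate_bm_traits(
        TraitSimSpec(
            tree=tree,
            group_effects=effects,
            group_of_tip=dict(zip(tips, habitats)),
            seed=seed + 300,
        )
    )
    sizes = np.where(
        rng.random(len(tips)) < 0.5, rng.uniform(5.0, 11.74, len(tips)),
        rng.uniform(14.05, 60.0, len(tips))
    )
    traits["size_class"] = np.where(sizes <= 11.74, "miniaturized", "non-miniaturized")
    traits["skull_length_mm"] = np.round(sizes, 2)
    traits_path = out / "traits.tsv"
    traits.to_csv(traits_path, sep="\t", float_format="%.10g")
    written.append(traits_path)
    return written
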