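"""Topospace: ordinary and phylogenetically corrected PCA of network parameters.

The seven whole-network parameters (N, K, D, C, L, H, P) per taxon define a
connectivity morphospace ("topospace"). Because the variables are on very
different scales, both ordinary PCA and phylogenetic PCA operate on the
correlation matrix. The phylogenetic version removes the trait covariance
expected from shared ancestry under Brownian motion on a dated tree:
with C the matrix of shared root-to-tip path lengths,

    a = (1' C^-1 1)^-1 1' C^-1 X          (GLS estimate of the ancestral mean)
    V = (X - 1a)' C^-1 (X - 1a) / (n - 1)  (evolutionary covariance)

V is rescaled to a correlation matrix, eigen-decomposed, and scores are the
centred, sd-scaled data projected on the eigenvectors.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import dendropy
from shapely.geometry import MultiPoint

__all__ = [
    "TopospaceResult",
    "match_taxa_to_tree",
    "pca_correlation",
    "phylogenetic_pca",
    "shared_path_matrix",
    "convex_hull_overlap",
    "read_tree",
    "read_synonym_map",
]

DROP = "drop"


@dataclasses.dataclass(frozen=True)
class TopospaceResult:
    """Scores, loadings and per-component variance shares of a (p)PCA."""

    scores: pd.DataFrame         # taxa x components
    loadings: pd.DataFrame       # variables x components
    variance_fraction: np.ndarray  # percent, sums to 100
    kind: str                    # "pca" | "ppca"


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and (edge.length is None or edge.length <= 0):
            raise ValueError("tree must have strictly positive branch lengths")
    return tree


def read_synonym_map(path) -> dict[str, str]:
    """Two-column TSV mapping table taxa to tree tip labels (or 'drop')."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "tip"], dtype=str)
    return dict(zip(df["taxon"], df["tip"]))


def match_taxa_to_tree(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    synonym_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dendropy.Tree, list[str]]:
    """Match parameter-table taxa to tree tips and prune both to the overlap.

    Each table taxon maps to a tip label via ``synonym_map`` (identity where
    absent; the study mapped missing species to congeners). A taxon mapped to
    ``"drop"`` or whose tip is absent from the tree is dropped and listed.
    Unmatched tips are pruned from the (cloned) tree. Two taxa mapping to one
    tip is an error.
    """
    synonym_map = synonym_map or {}
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    mapping: dict[str, str] = {}
    dropped: list[str] = []
    for taxon in table.index:
        target = synonym_map.get(taxon, taxon)
        if target == DROP or target not in tip_labels:
            dropped.append(taxon)
        else:
            mapping[taxon] = target
    used: dict[str, str] = {}
    for taxon, tip in mapping.items():
        if tip in used:
            raise ValueError(
                f"taxa {used[tip]!r} and {taxon!r} both map to tip {tip!r}"
            )
        used[tip] = taxon
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(list(used))
    matched = table.loc[list(mapping)].copy()
    matched.index = pd.Index(list(mapping), name=table.index.name)
    matched.attrs["tip_of_taxon"] = dict(mapping)
    return matched, pruned, dropped


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude loading is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        anchor = np.argmax(np.abs(out[:, j]))
        if out[anchor, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _component_frames(taxa, variables, scores, loadings, eigvals, kind):
    names = [f"{'p' if kind == 'ppca' else ''}PC{i + 1}" for i in range(len(eigvals))]
    return TopospaceResult(
        scores=pd.DataFrame(scores, index=taxa, columns=names),
        loadings=pd.DataFrame(loadings, index=variables, columns=names),
        variance_fraction=100.0 * eigvals / eigvals.sum(),
        kind=kind,
    )


def pca_correlation(table: pd.DataFrame) -> TopospaceResult:
    """PCA on the correlation matrix of the parameter table.

    Variables are standardized (sample sd), the correlation matrix is
    eigen-decomposed, and scores are the standardized data projected on the
    unit-norm eigenvectors. Component signs are fixed by making each
    component's largest-magnitude loading positive.
    """
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("PCA requires at least 3 taxa")
    sd = x.std(axis=0, ddof=1)
    constant = np.where(sd == 0)[0]
    if constant.size:
        names = [table.columns[i] for i in constant]
        raise ValueError(f"constant column(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    r = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    scores = z @ eigvecs
    return _component_frames(table.index, table.columns, scores, eigvecs, eigvals, "pca")


def shared_path_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance structure C: shared root-to-MRCA path lengths.

    C_ii is the root-to-tip distance and C_ij the root-to-MRCA distance,
    computed as (depth_i + depth_j - d_ij) / 2 from patristic distances.
    """
    pdm = tree.phylogenetic_distance_matrix()
    tips = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"tips absent from tree: {missing}")
    tree.calc_node_root_distances()
    depth = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    n = len(taxa)
    c = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        c[i, i] = depth[ti]
        for j in range(i + 1, n):
            tj = taxa[j]
            d = pdm.patristic_distance(tips[ti], tips[tj])
            c[i, j] = c[j, i] = 0.5 * (depth[ti] + depth[tj] - d)
    return c


def phylogenetic_pca(table: pd.DataFrame, tree: dendropy.Tree) -> TopospaceResult:
    """Phylogenetic PCA under Brownian motion, correlation mode.

    ``table`` and ``tree`` should come from :func:`match_taxa_to_tree`; tip
    labels are taken from the table's recorded taxon->tip mapping (identity
    when absent).
    """
    tip_of = table.attrs.get("tip_of_taxon") or {t: t for t in table.index}
    tips = [tip_of[t] for t in table.index]
    c = shared_path_matrix(tree, tips)
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("pPCA requires at least 3 matched taxa")
    try:
        c_inv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance matrix: {exc}") from exc
    ones = np.ones((n, 1))
    denom = (ones.T @ c_inv @ ones).item()
    a = (ones.T @ c_inv @ x) / denom          # 1 x p ancestral mean
    xc = x - ones @ a
    v = xc.T @ c_inv @ xc / (n - 1)           # evolutionary covariance
    sd = np.sqrt(np.diag(v))
    if (sd == 0).any():
        names = [table.columns[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero evolutionary variance column(s): {names}")
    r = v / np.outer(sd, sd)
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    scores = (xc / sd) @ eigvecs
    return _component_frames(table.index, table.columns, scores, eigvecs, eigvals, "ppca")


def convex_hull_overlap(
    scores: pd.DataFrame,
    labels: pd.Series | dict,
    axes: tuple[int, int] = (0, 1),
) -> dict:
    """Per-group 2-D convex hull areas and pairwise intersection areas.

    Groups with fewer than 3 points (or collinear points) get a degenerate
    hull of area 0. Returns ``{"areas": {group: area}, "intersections":
    {(g1, g2): area}, "degenerate": [groups]}``.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("labels missing for some taxa")
    pts = scores.iloc[:, list(axes)].to_numpy(dtype=float)
    hulls = {}
    areas = {}
    degenerate = []
    for group in sorted(labels.unique()):
        sub = pts[(labels == group).to_numpy()]
        hull = MultiPoint([tuple(p) for p in sub]).convex_hull
        hulls[group] = hull
        areas[group] = float(hull.area)
        if sub.shape[0] < 3 or hull.area == 0.0:
            degenerate.append(group)
    groups = sorted(hulls)
    inter = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            inter[(g1, g2)] = float(hulls[g1].intersection(hulls[g2]).area)
    return {"areas": areas, "intersections": inter, "degenerate": degenerate}
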