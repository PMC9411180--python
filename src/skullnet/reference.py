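"""Published squamate skull network parameters and the replication workflow.

The packaged table ``data/squamate_skull_parameters.tsv`` holds the printed
whole-network parameters (N, K, D, C, L, H, P) for the 57 squamate taxa of
the source study's per-taxon parameter table. The adjacency matrices, dated
phylogeny and per-taxon groupings behind that table are external supplementary
data; :func:`replication_workflow` runs as much of the downstream analysis as
the supplied inputs allow.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from . import topospace
from . import groups as group_tests

__all__ = [
    "load_reference_parameters",
    "check_density_identity",
    "replication_workflow",
]


def load_reference_parameters() -> pd.DataFrame:
    """The published 57-taxon parameter table, indexed by taxon."""
    ref = importlib.resources.files("skullnet.data").joinpath(
        "squamate_skull_parameters.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t").set_index("taxon")
    return df[["N", "K", "D", "C", "L", "H", "P"]]


def check_density_identity(table: pd.DataFrame | None = None, decimals: int = 4) -> pd.DataFrame:
    """Recompute D = K / (N(N-1)/2) per taxon and compare to the printed D.

    Returns a frame with computed density, printed density and their match at
    ``decimals`` decimal places.
    """
    if table is None:
        table = load_reference_parameters()
    computed = table["K"] / (table["N"] * (table["N"] - 1) / 2.0)
    out = pd.DataFrame(
        {
            "D_printed": table["D"],
            "D_computed": computed,
            "match": np.round(computed, decimals) == np.round(table["D"], decimals),
        }
    )
    return out


def replication_workflow(
    tree=None,
    synonym_map: dict[str, str] | None = None,
    groupings: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Re-run the topospace stage on the published parameter table.

    Always performs the ordinary correlation PCA of the 57-taxon table.
    Phylogenetic PCA additionally needs the external dated phylogeny (and a
    taxon-to-tip synonym map for congener matching); PERMANOVA additionally
    needs the external per-taxon groupings. Each extra analysis is run only
    when its input is supplied, so the desk-scale part works offline and the
    full replication slots in when a user provides the external files.
    """
    table = load_reference_parameters()
    results: dict = {"density_identity": check_density_identity(table)}
    results["pca"] = topospace.pca_correlation(table)
    if tree is not None:
        matched, pruned, dropped = topospace.match_taxa_to_tree(
            table, tree, synonym_map
        )
        results["ppca"] = topospace.phylogenetic_pca(matched, pruned)
        results["dropped_taxa"] = dropped
    if groupings is not None:
        scores = (
            results["ppca"].scores if "ppca" in results else results["pca"].scores
        )
        permanovas = {}
        for column in groupings.columns:
            labels = groupings[column].reindex(scores.index).dropna()
            sub = scores.loc[labels.index]
            permanovas[column] = group_tests.permanova(
                sub, labels, n_permutations=n_permutations, seed=seed
            )
            if labels.nunique() > 2:
                permanovas[f"{column}_pairwise"] = group_tests.pairwise_permanova(
                    sub, labels, n_permutations=n_permutations, seed=seed
                )
        results["permanova"] = permanovas
    return results
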