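"""Reading, validating and writing anatomical networks and the tables around them.

An anatomical network codes a skull as an unweighted, undirected graph: bones
are nodes and articulations (osseous contact or close functional integration)
are edges, stored as a symmetric binary adjacency matrix with a zero diagonal.
Isolated bones (degree 0, e.g. the anomalepidid jugal) are legal nodes.

The primary interchange format is a headered CSV/TSV whose first row and first
column both carry the node labels in identical order; XLSX workbooks (one sheet
per specimen) are supported read-only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "AnatomicalNetwork",
    "LateralityMap",
    "NetworkValidationError",
    "read_adjacency",
    "read_adjacency_workbook",
    "write_adjacency",
    "infer_laterality",
    "check_bilateral_symmetry",
    "write_parameter_table",
    "read_parameter_table",
    "read_grouping_table",
    "HABITAT_CATEGORIES",
    "SIZE_CATEGORIES",
]

HABITAT_CATEGORIES = ("fossorial", "semi-fossorial", "non-fossorial")
SIZE_CATEGORIES = ("miniaturized", "non-miniaturized")

PARAMETER_COLUMNS = ("N", "K", "D", "C", "L", "H", "P")


class NetworkValidationError(ValueError):
    """An adjacency matrix violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class AnatomicalNetwork:
    """A node-labelled symmetric binary articulation graph.

    Parameters
    ----------
    specimen_id:
        Label for the specimen/taxon this network was scored from.
    nodes:
        Ordered bone labels; must be unique.
    adjacency:
        Square 0/1 matrix aligned with ``nodes``; symmetric, zero diagonal.
    """

    specimen_id: str
    nodes: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        nodes = tuple(str(n) for n in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkValidationError(
                f"adjacency must be square, got shape {a.shape}"
            )
        if a.shape[0] != len(nodes):
            raise NetworkValidationError(
                f"{len(nodes)} node labels but adjacency is {a.shape[0]}x{a.shape[1]}"
            )
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
            raise NetworkValidationError(f"duplicate node labels: {dupes}")
        bad = ~np.isin(a, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise NetworkValidationError(
                f"non-binary entry {a[i, j]!r} at ({nodes[i]}, {nodes[j]})"
            )
        a = a.astype(np.int8)
        asym = a != a.T
        if asym.any():
            i, j = np.argwhere(asym)[0]
            raise NetworkValidationError(
                f"asymmetric adjacency at pair ({nodes[i]}, {nodes[j]}): "
                f"a_ij={a[i, j]}, a_ji={a[j, i]}"
            )
        if np.diag(a).any():
            i = int(np.argwhere(np.diag(a))[0][0])
            raise NetworkValidationError(f"nonzero diagonal at node {nodes[i]}")
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Number of undirected articulations (each counted once)."""
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def index_of(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} not in network {self.specimen_id!r}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in idx)
        return g

    def edges(self) -> list[tuple[str, str]]:
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        return [(self.nodes[i], self.nodes[j]) for i, j in idx]


@dataclasses.dataclass(frozen=True)
class LateralityMap:
    """Pairing of left/right bone labels plus the unpaired midline bones.

    Every node of the network it describes must appear exactly once across
    ``pairs`` and ``midline``.
    """

    pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs)
        )
        object.__setattr__(self, "midline", tuple(str(m) for m in self.midline))
        seen: list[str] = [x for p in self.pairs for x in p] + list(self.midline)
        if len(set(seen)) != len(seen):
            raise NetworkValidationError("laterality map mentions a label twice")

    def labels(self) -> set[str]:
        return {x for p in self.pairs for x in p} | set(self.midline)

    def mirror(self) -> dict[str, str]:
        """The left<->right relabeling; midline bones map to themselves."""
        m = {x: x for x in self.midline}
        for left, right in self.pairs:
            m[left] = right
            m[right] = left
        return m


def infer_laterality(nodes, left_suffix: str = "_L", right_suffix: str = "_R") -> LateralityMap:
    """Build a LateralityMap from the default ``_L``/``_R`` suffix convention.

    Labels carrying neither suffix are treated as midline. Raises if a suffixed
    label lacks its partner.
    """
    nodes = list(nodes)
    pairs = []
    midline = []
    node_set = set(nodes)
    for n in nodes:
        if n.endswith(left_suffix):
            partner = n[: -len(left_suffix)] + right_suffix
            if partner not in node_set:
                raise NetworkValidationError(f"{n!r} has no right partner {partner!r}")
            pairs.append((n, partner))
        elif n.endswith(right_suffix):
            partner = n[: -len(right_suffix)] + left_suffix
            if partner not in node_set:
                raise NetworkValidationError(f"{n!r} has no left partner {partner!r}")
        else:
            midline.append(n)
    return LateralityMap(pairs=tuple(pairs), midline=tuple(midline))


def _frame_to_network(df: pd.DataFrame, specimen_id: str) -> AnatomicalNetwork:
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise NetworkValidationError(
            f"row labels and column labels differ (rows start {row_labels[:3]}, "
            f"columns start {col_labels[:3]})"
        )
    values = df.to_numpy()
    try:
        numeric = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise NetworkValidationError(f"non-numeric adjacency entry: {exc}") from exc
    if not np.isfinite(numeric).all() or (numeric != numeric.astype(int)).any():
        raise NetworkValidationError("adjacency entries must be integers 0/1")
    return AnatomicalNetwork(specimen_id, tuple(row_labels), numeric.astype(int))


def read_adjacency(path, dialect: str | None = None, specimen_id: str | None = None) -> AnatomicalNetwork:
    """Read a validated anatomical network from a CSV/TSV/XLSX adjacency file.

    The first row and first column must carry identical node labels in
    identical order. ``dialect`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv",
                   ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    if dialect == "xlsx":
        df = pd.read_excel(path, index_col=0)
    elif dialect in ("csv", "tsv"):
        df = pd.read_csv(path, index_col=0, sep="," if dialect == "csv" else "\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_network(df, specimen_id or path.stem)


def read_adjacency_workbook(path) -> list[AnatomicalNetwork]:
    """Read every sheet of an XLSX workbook as one network per specimen."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    return [_frame_to_network(df, name) for name, df in sheets.items()]


def write_adjacency(net: AnatomicalNetwork, path, dialect: str = "csv") -> None:
    df = pd.DataFrame(net.adjacency, index=list(net.nodes), columns=list(net.nodes))
    sep = "," if dialect == "csv" else "\t"
    df.to_csv(path, sep=sep)


def check_bilateral_symmetry(net: AnatomicalNetwork, lat: LateralityMap) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Report edges whose mirror image is missing.

    Applies the left/right relabeling from ``lat`` (midline fixed) and lists
    every edge (u, v) whose mirrored pair (m(u), m(v)) is absent. The report is
    empty iff the mirror relabeling is a graph automorphism, i.e. the skull's
    articulation pattern is bilaterally symmetric.
    """
    missing = lat.labels() - set(net.nodes)
    if missing:
        raise KeyError(f"laterality labels not in network: {sorted(missing)}")
    uncovered = set(net.nodes) - lat.labels()
    if uncovered:
        raise KeyError(f"network nodes not covered by laterality map: {sorted(uncovered)}")
    mirror = lat.mirror()
    edge_set = {frozenset(e) for e in net.edges()}
    report = []
    for u, v in net.edges():
        mu, mv = mirror[u], mirror[v]
        if frozenset((mu, mv)) not in edge_set:
            report.append(((u, v), (mu, mv)))
    return report


def write_parameter_table(rows, path) -> None:
    """Write per-taxon network parameters as TSV in the standard layout.

    Columns are Taxon, N, K, D, C, L, H, P with the five real-valued
    parameters rendered to 4 decimals.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no parameter rows to write")
    taxa = [r.taxon for r in rows]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon ids: {dupes}")
    df = pd.DataFrame(
        {
            "Taxon": taxa,
            "N": [r.N for r in rows],
            "K": [r.K for r in rows],
            "D": [f"{r.D:.4f}" for r in rows],
            "C": [f"{r.C:.4f}" for r in rows],
            "L": [f"{r.L:.4f}" for r in rows],
            "H": [f"{r.H:.4f}" for r in rows],
            "P": [f"{r.P:.4f}" for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_parameter_table(path) -> pd.DataFrame:
    """Read a parameter table TSV into a taxon-indexed DataFrame.

    Accepts either the ``Taxon``/``taxon`` header spelling; returns columns
    N, K, D, C, L, H, P with numeric dtypes.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols:
        raise ValueError("parameter table must have a Taxon column")
    df = df.rename(columns={cols["taxon"]: "taxon"}).set_index("taxon")
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    return df[list(PARAMETER_COLUMNS)].astype(float)


def read_grouping_table(path) -> pd.DataFrame:
    """Read the per-taxon categorical grouping table (TSV).

    Validates that habitat and size_class values, when present, come from the
    closed vocabularies used throughout the analysis.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols:
        raise ValueError("grouping table must have a taxon column")
    df = df.rename(columns={cols["taxon"]: "taxon"}).set_index("taxon")
    if df.index.has_duplicates:
        raise ValueError("duplicate taxon ids in grouping table")
    if df.isna().any().any():
        raise ValueError("grouping table has missing cells")
    if "habitat" in df.columns:
        bad = set(df["habitat"]) - set(HABITAT_CATEGORIES)
        if bad:
            raise ValueError(f"unknown habitat categories: {sorted(bad)}")
    if "size_class" in df.columns:
        bad = set(df["size_class"]) - set(SIZE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown size classes: {sorted(bad)}")
    return df
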