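"""Hit-restricted PPI subnetwork and protein-complex completeness annotation.

Pairwise bait-prey interactions (BioPlex-style AP-MS export) are filtered to
pairs where both partners are screen hits, collapsed to undirected edges
(reciprocal bait-prey detection carries no meaning here), and self-loops are
dropped. Hits with no surviving interaction are not network nodes. Protein
complexes (CORUM-style rosters) are filtered to >=2 distinct subunits
(homodimer entries removed), scored for completeness against the hit list
(screen completeness) and against the network node set (network
completeness), and each network protein belonging to several complexes is
assigned the one with the highest screen completeness (ties: larger complex,
then lexicographic id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class Network:
    """Undirected gene-symbol graph: no self-loops, no duplicate pairs."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge ({a!r}, {b!r}) not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({a!r}, {b!r})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def load_interactions(path: str | Path) -> pd.DataFrame:
    """Read a bait/prey interaction TSV (extra columns are kept as-is)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"bait", "prey"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def build_subnetwork(interactions: pd.DataFrame, hits: list[str] | set[str]) -> Network:
    """Restrict interactions to hit-hit pairs and collapse to undirected edges.

    Nodes are the endpoints of surviving edges only: a hit without any
    within-hit interaction does not appear in the network.
    """
    hit_set = {_norm(h) for h in hits}
    if not hit_set:
        raise ValueError("hit list is empty")
    edges: set[tuple[str, str]] = set()
    for bait, prey in zip(interactions["bait"], interactions["prey"]):
        a, b = _norm(bait), _norm(prey)
        if a == b or a not in hit_set or b not in hit_set:
            continue
        edges.add((a, b) if a < b else (b, a))
    nodes = frozenset(x for pair in edges for x in pair)
    return Network(nodes=nodes, edges=frozenset(edges))


@dataclass
class ComplexCatalog:
    """Protein-complex rosters: complex id -> name and subunit symbol set."""

    complexes: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[tuple[str, str, list[str]]]) -> "ComplexCatalog":
        cat = cls()
        for cid, name, subunits in records:
            if cid in cat.complexes:
                raise ValueError(f"duplicate complex id {cid!r}")
            cat.complexes[cid] = {
                "name": name,
                "subunits": frozenset(_norm(s) for s in subunits if str(s).strip()),
            }
        return cat

    def __len__(self) -> int:
        return len(self.complexes)


def load_catalog(path: str | Path) -> ComplexCatalog:
    """Read a complex catalog TSV: complex_id, name, semicolon-joined subunits."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"complex_id", "name", "subunits"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ComplexCatalog.from_records(
        [
            (row.complex_id, row.name, str(row.subunits).split(";"))
            for row in df.itertuples(index=False)
        ]
    )


def filter_catalog(catalog: ComplexCatalog) -> ComplexCatalog:
    """Drop complexes with fewer than two distinct subunits (homodimers etc.)."""
    kept = ComplexCatalog()
    kept.complexes = {
        cid: info for cid, info in catalog.complexes.items() if len(info["subunits"]) >= 2
    }
    return kept


def completeness(
    subunits: frozenset[str] | set[str],
    hits: list[str] | set[str],
    network_nodes: set[str] | frozenset[str] | None = None,
) -> tuple[float, float]:
    """Percent of a complex's subunits among hits and among network nodes.

    Exact fractions are returned; use :func:`round_half_up` for the display
    convention (nearest integer, halves up).
    """
    subs = {_norm(s) for s in subunits}
    if not subs:
        raise ValueError("complex has no subunits")
    hit_set = {_norm(h) for h in hits}
    screen_pct = 100.0 * len(subs & hit_set) / len(subs)
    if network_nodes is None:
        return screen_pct, 0.0
    net = {_norm(n) for n in network_nodes}
    network_pct = 100.0 * len(subs & net) / len(subs)
    return screen_pct, network_pct


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ComplexAnnotation:
    """Per-complex completeness table and the per-protein complex assignment."""

    complexes: pd.DataFrame  # complex_id, name, size, screen_pct, network_pct
    assignment: dict[str, str]  # network node -> complex_id (argmax rule)


def assign_complexes(
    network: Network,
    catalog: ComplexCatalog,
    hits: list[str] | set[str],
) -> ComplexAnnotation:
    """Score every complex and assign each network protein to one complex.

    A protein in several complexes goes to the one with the highest screen
    completeness, ties broken by larger subunit count, then lexicographically
    smaller complex id. Proteins in no catalog complex stay unassigned.
    """
    rows = []
    by_cid: dict[str, tuple[float, int]] = {}
    for cid, info in sorted(catalog.complexes.items()):
        screen_pct, network_pct = completeness(info["subunits"], hits, network.nodes)
        size = len(info["subunits"])
        rows.append(
            {
                "complex_id": cid,
                "name": info["name"],
                "size": size,
                "screen_pct": screen_pct,
                "network_pct": network_pct,
                "screen_pct_display": round_half_up(screen_pct),
                "network_pct_display": round_half_up(network_pct),
            }
        )
        by_cid[cid] = (screen_pct, size)
    table = pd.DataFrame(
        rows,
        columns=[
            "complex_id",
            "name",
            "size",
            "screen_pct",
            "network_pct",
            "screen_pct_display",
            "network_pct_display",
        ],
    )
    assignment: dict[str, str] = {}
    for node in sorted(network.nodes):
        memberships = [
            cid
            for cid, info in catalog.complexes.items()
            if node in info["subunits"]
        ]
        if not memberships:
            continue
        assignment[node] = min(
            memberships, key=lambda cid: (-by_cid[cid][0], -by_cid[cid][1], cid)
        )
    return ComplexAnnotation(complexes=table, assignment=assignment)


def export_network(
    network: Network,
    node_path: str | Path,
    edge_path: str | Path,
    annotation: ComplexAnnotation | None = None,
    gene_stats: pd.DataFrame | None = None,
) -> None:
    """Write Cytoscape-loadable node and edge TSVs in deterministic sorted order.

    The node table carries gene, aLFC (when gene stats are supplied), the
    assigned complex and its completeness percentages; the edge table is
    (source, target) with source < target.
    """
    edges = pd.DataFrame(sorted(network.edges), columns=["source", "target"])
    nodes = pd.DataFrame({"gene": sorted(network.nodes)})
    if gene_stats is not None:
        nodes["alfc"] = nodes["gene"].map(gene_stats["alfc"])
    if annotation is not None:
        by_cid = annotation.complexes.set_index("complex_id")
        nodes["complex_id"] = nodes["gene"].map(annotation.assignment).fillna("")
        for col in ("screen_pct", "network_pct"):
            nodes[col] = [
                by_cid.loc[cid, col] if cid else float("nan")
                for cid in nodes["complex_id"]
            ]
    try:
        edges.to_csv(edge_path, sep="\t", index=False)
        nodes.to_csv(node_path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write network export to {node_path} / {edge_path}: {exc}") from exc


def import_network(edge_path: str | Path) -> Network:
    """Rebuild a :class:`Network` from an exported edge table."""
    df = pd.read_csv(edge_path, sep="\t", dtype=str)
    edges = set()
    for a, b in zip(df["source"], df["target"]):
        a, b = _norm(a), _norm(b)
        if a != b:
            edges.add((a, b) if a < b else (b, a))
    nodes = frozenset(x for pair in edges for x in pair)
    return Network(nodes=nodes, edges=frozenset(edges))


def list_overlap(a: list[str], b: list[str]) -> tuple[int, int, int]:
    """(|a and b|, |a only|, |b only|) after symbol normalization."""
    sa = {_norm(x) for x in a}
    sb = {_norm(x) for x in b}
    return len(sa & sb), len(sa - sb), len(sb - sa)


def write_completeness(annotation: ComplexAnnotation, path: str | Path) -> None:
    annotation.complexes.to_csv(path, sep="\t", index=False)
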