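"""Recompute network statistics and gene lookups from deposited screen tables.

The screen's processed outputs are distributed as supplementary tables: a
per-gene statistics table (gene, aLFC, padj, ...) and an interaction/complex
table (bait, prey pairs restricted to hits, with per-protein complex
assignment). These loaders accept those tables re-saved as TSV and recompute
the headline network quantities -- deduplicated node and edge counts and the
number of network proteins carrying a complex assignment -- plus per-gene
aLFC lookups. The tables themselves are not bundled here; point the loaders
at a local copy of the deposited supplement.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from phagoscreen.network import Network, build_subnetwork


def load_gene_table(path: str | Path) -> pd.DataFrame:
    """Per-gene statistics TSV with at least columns ``gene`` and ``alfc``."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace("-", "_"): c for c in df.columns}
    gene_col = cols.get("gene") or cols.get("gene_symbol")
    alfc_col = cols.get("alfc") or cols.get("average_log2fc") or cols.get("alog2fc")
    if gene_col is None or alfc_col is None:
        raise ValueError(f"{path}: need gene and aLFC columns, found {list(df.columns)}")
    out = df.rename(columns={gene_col: "gene", alfc_col: "alfc"})
    out["gene"] = out["gene"].astype(str).str.strip().str.upper()
    return out.set_index("gene")


def gene_alfc(gene_table: pd.DataFrame, gene: str) -> float:
    return float(gene_table.loc[str(gene).strip().upper(), "alfc"])


def network_from_interaction_table(path: str | Path) -> Network:
    """Deduplicated undirected network from a deposited interaction table.

    The table must have bait/prey (or source/target) columns; every listed
    protein is by construction a hit, so the hit filter is the union of the
    two columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    bait = cols.get("bait") or cols.get("source")
    prey = cols.get("prey") or cols.get("target")
    if bait is None or prey is None:
        raise ValueError(f"{path}: need bait/prey columns, found {list(df.columns)}")
    df = df.rename(columns={bait: "bait", prey: "prey"})
    hits = set(df["bait"].str.upper()) | set(df["prey"].str.upper())
    return build_subnetwork(df, hits)


def count_assigned_proteins(path: str | Path, network: Network) -> int:
    """Network proteins with a non-empty complex assignment in the table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    protein = cols.get("protein") or cols.get("gene") or cols.get("node")
    complex_col = cols.get("complex_id") or cols.get("complex") or cols.get("corum_id")
    if protein is None or complex_col is None:
        raise ValueError(
            f"{path}: need protein and complex columns, found {list(df.columns)}"
        )
    df = df.rename(columns={protein: "protein", complex_col: "complex_id"})
    assigned = df[df["complex_id"].fillna("").str.strip() != ""]
    names = set(assigned["protein"].str.strip().str.upper())
    return len(names & network.nodes)
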