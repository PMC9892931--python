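"""End-to-end orchestration: counts -> guide stats -> gene stats -> hits -> network.

A single declarative YAML config drives a run; all randomness flows from its
one seed field, every output table is written deterministically, and a JSON
manifest records tool version, seed, per-table row counts and SHA-256
checksums so reruns can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from phagoscreen import __version__
from phagoscreen.aggregation import (
    aggregate_genes,
    call_hits,
    write_gene_stats,
    write_hits,
    write_volcano_table,
)
from phagoscreen.differential import (
    estimate_dispersions,
    size_factors,
    wald_test,
    write_sgrna_stats,
)
from phagoscreen.library import (
    CountMatrix,
    count_reads,
    load_library,
    merge_counts,
    read_counts,
    write_counts,
    write_report,
)
from phagoscreen.network import (
    assign_complexes,
    build_subnetwork,
    export_network,
    filter_catalog,
    load_catalog,
    load_interactions,
    write_completeness,
)
from phagoscreen.simulate import SimConfig, simulate_screen

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative run description (see :func:`load_config` for the file form)."""

    out_dir: Path
    seed: int
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    counts_tsv: Path | None = None
    samples_tsv: Path | None = None
    library_tsv: Path | None = None
    fastq: dict[str, Path] = field(default_factory=dict)
    simulate: dict | None = None
    count_mode: str = "substring"
    n_perm: int = 1000
    gsea_weight: int = 0
    padj_cutoff: float = 0.05
    direction: str = "depleted"
    use_raw_p: bool = False
    interactions_tsv: Path | None = None
    catalog_tsv: Path | None = None
    hits_txt: Path | None = None

    def validate(self, for_network: bool = False) -> None:
        for name in ("counts_tsv", "samples_tsv", "library_tsv", "interactions_tsv",
                     "catalog_tsv", "hits_txt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {name} points to missing file {p}")
        for sid, p in self.fastq.items():
            if not Path(p).exists():
                raise PipelineError(f"config: fastq for {sid} missing: {p}")
        if for_network:
            if self.interactions_tsv is None or self.catalog_tsv is None:
                raise PipelineError("network run needs interactions_tsv and catalog_tsv")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = Path(path).parent

    def _p(key: str) -> Path | None:
        return base / raw[key] if key in raw and raw[key] else None

    return RunConfig(
        out_dir=base / raw.get("out_dir", "results"),
        seed=int(raw["seed"]),
        contrasts=[tuple(c) for c in raw.get("contrasts", [])],
        counts_tsv=_p("counts_tsv"),
        samples_tsv=_p("samples_tsv"),
        library_tsv=_p("library_tsv"),
        fastq={k: base / v for k, v in raw.get("fastq", {}).items()},
        simulate=raw.get("simulate"),
        count_mode=raw.get("count_mode", "substring"),
        n_perm=int(raw.get("n_perm", 1000)),
        gsea_weight=int(raw.get("gsea_weight", 0)),
        padj_cutoff=float(raw.get("padj_cutoff", 0.05)),
        direction=raw.get("direction", "depleted"),
        use_raw_p=bool(raw.get("use_raw_p", False)),
        interactions_tsv=_p("interactions_tsv"),
        catalog_tsv=_p("catalog_tsv"),
        hits_txt=_p("hits_txt"),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_entry(path: Path, n_rows: int | None = None) -> dict:
    entry = {"path": str(path), "sha256": _sha256(path)}
    if n_rows is not None:
        entry["n_rows"] = n_rows
    return entry


def _obtain_counts(cfg: RunConfig) -> CountMatrix:
    if cfg.simulate is not None:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulate)
        _, matrix, _ = simulate_screen(sim_cfg)
        return matrix
    if cfg.samples_tsv is None:
        raise PipelineError("stage counts: need samples_tsv (or a simulate block)")
    samples = pd.read_csv(cfg.samples_tsv, sep="\t")
    if cfg.counts_tsv is not None:
        return read_counts(cfg.counts_tsv, samples)
    if cfg.fastq:
        if cfg.library_tsv is None:
            raise PipelineError("stage counts: FASTQ input needs library_tsv")
        index = load_library(cfg.library_tsv)
        columns, reports = {}, {}
        for sid, path in cfg.fastq.items():
            columns[sid], reports[sid] = count_reads(path, index, mode=cfg.count_mode)
        write_report(reports, cfg.out_dir / "counting_report.json")
        return merge_counts(columns, samples, index)
    raise PipelineError("stage counts: no counts_tsv, fastq or simulate input")


def run_screen_pipeline(cfg: RunConfig) -> dict:
    """Counting/ingest, per-guide NB tests, gene aggregation and hit calling.

    Returns the manifest dict (also written to ``manifest.json``). Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    cfg.validate()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "outputs": {}}

    try:
        matrix = _obtain_counts(cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage counts: {exc}") from exc
    counts_path = cfg.out_dir / "counts.tsv"
    write_counts(matrix, counts_path)
    manifest["outputs"]["counts"] = _manifest_entry(counts_path, matrix.n_guides)

    contrasts = cfg.contrasts or _default_contrasts(matrix)
    for cond_a, cond_b in contrasts:
        known = set(matrix.samples["condition"])
        if cond_a not in known or cond_b not in known:
            raise PipelineError(
                f"stage differential: contrast ({cond_a}, {cond_b}) references "
                f"conditions outside {sorted(known)}"
            )
        tag = f"{cond_a}_vs_{cond_b}"
        try:
            sub = matrix.subset(
                matrix.condition_samples(cond_a) + matrix.condition_samples(cond_b)
            )
            norm = size_factors(sub)
            disp = estimate_dispersions(sub, norm)
            stats = wald_test(sub, norm, disp, (cond_a, cond_b))
        except Exception as exc:
            raise PipelineError(f"stage differential ({tag}): {exc}") from exc
        guide_path = cfg.out_dir / f"sgrna_stats.{tag}.tsv"
        write_sgrna_stats(stats, str(guide_path), (cond_a, cond_b))
        manifest["outputs"][f"sgrna_stats.{tag}"] = _manifest_entry(guide_path, len(stats))

        try:
            genes = aggregate_genes(
                stats, n_perm=cfg.n_perm, seed=cfg.seed, weight=cfg.gsea_weight
            )
            hits = call_hits(
                genes,
                direction=cfg.direction,
                padj_cutoff=cfg.padj_cutoff,
                use_raw_p=cfg.use_raw_p,
                contrast=tag,
            )
        except Exception as exc:
            raise PipelineError(f"stage aggregation ({tag}): {exc}") from exc
        gene_path = cfg.out_dir / f"gene_stats.{tag}.tsv"
        write_gene_stats(genes, str(gene_path))
        volcano_path = cfg.out_dir / f"volcano.{tag}.tsv"
        write_volcano_table(genes, str(volcano_path))
        hits_path = cfg.out_dir / f"hits.{tag}.txt"
        write_hits(hits, str(hits_path))
        manifest["outputs"][f"gene_stats.{tag}"] = _manifest_entry(gene_path, len(genes))
        manifest["outputs"][f"volcano.{tag}"] = _manifest_entry(volcano_path, len(genes))
        manifest["outputs"][f"hits.{tag}"] = _manifest_entry(hits_path, len(hits))
        logger.info("%s: %d genes, %d hits (%s)", tag, len(genes), len(hits), cfg.direction)

    manifest_path = cfg.out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _default_contrasts(matrix: CountMatrix) -> list[tuple[str, str]]:
    conds = list(dict.fromkeys(matrix.samples["condition"]))
    if len(conds) != 2:
        raise PipelineError(
            f"stage differential: no contrasts given and {len(conds)} conditions present"
        )
    # Convention: sorted fraction vs reference, e.g. (PhagoLate, PhagoNeg).
    if "PhagoNeg" in conds:
        other = next(c for c in conds if c != "PhagoNeg")
        return [(other, "PhagoNeg")]
    return [tuple(conds)]


def run_network_pipeline(cfg: RunConfig, hits: list[str] | None = None) -> dict:
    """Subnetwork construction, catalog filtering, annotation and export."""
    cfg.validate(for_network=True)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    if hits is None:
        if cfg.hits_txt is None:
            raise PipelineError("stage network: need a hit list (hits_txt)")
        hits = [l.strip() for l in Path(cfg.hits_txt).read_text().splitlines() if l.strip()]
    if not hits:
        raise PipelineError("stage network: hit list is empty")

    try:
        interactions = load_interactions(cfg.interactions_tsv)
        network = build_subnetwork(interactions, hits)
        catalog = filter_catalog(load_catalog(cfg.catalog_tsv))
        annotation = assign_complexes(network, catalog, hits)
    except Exception as exc:
        raise PipelineError(f"stage network: {exc}") from exc

    node_path = cfg.out_dir / "network_nodes.tsv"
    edge_path = cfg.out_dir / "network_edges.tsv"
    comp_path = cfg.out_dir / "complex_completeness.tsv"
    export_network(network, node_path, edge_path, annotation)
    write_completeness(annotation, comp_path)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_hits": len(set(hits)),
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_assigned": len(annotation.assignment),
        "outputs": {
            "network_nodes": _manifest_entry(node_path, network.n_nodes),
            "network_edges": _manifest_entry(edge_path, network.n_edges),
            "complex_completeness": _manifest_entry(comp_path, len(annotation.complexes)),
        },
    }
    (cfg.out_dir / "network_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
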