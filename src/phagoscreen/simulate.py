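"""Synthetic screens and PPI networks with known ground truth.

The screen generator emulates a FACS-sorted knockout screen at desk scale: a
TKOv3-like library (four guides per gene plus non-targeting controls, scaled
from the 142 controls of the genome-wide design), log-normally spread guide
abundances, negative-binomial counts across sorted fractions with replicate
structure, and a planted set of depleted genes whose guides lose abundance in
the sorted ("PhagoLate") fraction with per-guide effect heterogeneity. The
network generator plants protein complexes with dense within-complex
bait-prey edges over sparse background interactions and samples hits
preferentially from complexes so completeness varies.

Everything is reproducible from the config seed; one generator call uses one
RNG stream and touches no global state. What the generator deliberately does
not model: sorting impurity, PCR jackpotting, off-target guide effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phagoscreen.library import CONTROL_GENE, CountMatrix, LibraryEntry, LibraryIndex

#: Genome-wide control-to-gene ratio of the emulated library (142 / 18,053).
_CONTROL_RATE = 142.0 / 18053.0


@dataclass
class SimConfig:
    """Study conditions of a simulated screen.

    Defaults are the desk-scale stand-in for the genome-wide design: 1,000
    genes x 4 guides, controls scaled from the genome-wide control rate, two
    sorted fractions at two replicates each, 500 expected reads per guide,
    log-normal abundance spread sigma 0.8, NB dispersion 0.1, 5% of genes
    planted at log2 effect -2 applied in the sorted fraction with additive
    per-guide jitter (sd 0.3, so the mean realized effect equals the planted
    effect). The seed is mandatory.
    """

    seed: int
    n_genes: int = 1000
    guides_per_gene: int = 4
    n_controls: int | None = None  # default: genome-wide rate scaled to n_genes
    conditions: dict[str, int] = field(
        default_factory=lambda: {"PhagoNeg": 2, "PhagoLate": 2}
    )
    effect_condition: str = "PhagoLate"
    mean_depth: float = 500.0
    abundance_sigma: float = 0.8
    depth_sigma: float = 0.15
    dispersion: float = 0.1
    planted_fraction: float = 0.05
    planted_log2_effect: float = -2.0
    effect_jitter_sigma: float = 0.3
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_controls is None:
            self.n_controls = max(2, round(_CONTROL_RATE * self.n_genes))
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("need at least one gene and one guide per gene")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.planted_fraction < 1.0:
            raise ValueError("planted_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_condition not in self.conditions and self.planted_fraction > 0:
            raise ValueError(
                f"effect condition {self.effect_condition!r} not among conditions"
            )


@dataclass
class SimTruth:
    """Planted effects behind a simulated screen, for recovery testing."""

    planted_genes: frozenset[str]
    guide_effects: dict[str, float]  # realized log2 effect per planted guide
    config: SimConfig


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Unique random DNA spacers (the library loader rejects duplicates)."""
    alphabet = np.array(list("ACGT"))
    spacers: set[str] = set()
    while len(spacers) < n:
        draw = alphabet[rng.integers(0, 4, size=(n - len(spacers), length))]
        spacers.update("".join(row) for row in draw)
    return sorted(spacers)[:n] if len(spacers) == n else list(spacers)[:n]


def simulate_screen(cfg: SimConfig) -> tuple[LibraryIndex, CountMatrix, SimTruth]:
    """Draw a library, an NB count matrix across fractions, and the truth.

    Guide baseline abundances are log-normal with mean ``mean_depth``; counts
    are NB with the configured dispersion around ``s_j * lambda_i *
    2**effect`` where the effect applies only to guides of planted genes in
    the effect condition. Control guides are never planted.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    entries: list[LibraryEntry] = []
    for gene in genes:
        for j in range(cfg.guides_per_gene):
            entries.append(LibraryEntry(f"{gene}_g{j + 1}", gene, "", False))
    for c in range(cfg.n_controls):
        entries.append(LibraryEntry(f"CTRL_g{c + 1:04d}", CONTROL_GENE, "", True))
    spacers = _random_spacers(rng, len(entries), cfg.spacer_length)
    entries = [
        LibraryEntry(e.guide_id, e.gene, sp, e.is_control)
        for e, sp in zip(entries, spacers)
    ]
    index = LibraryIndex(entries)

    n_guides = len(entries)
    # mean-preserving log-normal: E[lambda] = mean_depth
    lam = cfg.mean_depth * rng.lognormal(
        -0.5 * cfg.abundance_sigma**2, cfg.abundance_sigma, size=n_guides
    )

    n_planted = round(cfg.planted_fraction * cfg.n_genes)
    planted = frozenset(rng.choice(genes, size=n_planted, replace=False))
    effects = np.zeros(n_guides)
    guide_effects: dict[str, float] = {}
    for i, e in enumerate(entries):
        if e.gene in planted:
            realized = cfg.planted_log2_effect + rng.normal(0.0, cfg.effect_jitter_sigma)
            effects[i] = realized
            guide_effects[e.guide_id] = float(realized)

    sample_rows = []
    columns: dict[str, np.ndarray] = {}
    for cond, n_rep in cfg.conditions.items():
        for r in range(1, n_rep + 1):
            sid = f"{cond}_r{r}"
            s_j = float(rng.lognormal(-0.5 * cfg.depth_sigma**2, cfg.depth_sigma))
            mu = s_j * lam
            if cond == cfg.effect_condition:
                mu = mu * np.exp2(effects)
            if cfg.dispersion > 0:
                n_param = 1.0 / cfg.dispersion
                counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
            else:
                counts = rng.poisson(mu)
            columns[sid] = counts.astype(np.int64)
            sample_rows.append({"sample_id": sid, "condition": cond, "replicate": r})
    samples = pd.DataFrame(sample_rows)
    counts_df = pd.DataFrame(columns, index=[e.guide_id for e in entries])
    matrix = CountMatrix(counts_df, samples, index.guide_to_gene())
    return index, matrix, SimTruth(planted, guide_effects, cfg)


#: Constant flanks around the spacer when emitting synthetic amplicon reads.
FASTQ_FLANK5 = "TTGTGGAAAGGACGAAACACCG"
FASTQ_FLANK3 = "GTTTTAGAGCTAGAAATAGCAAG"


def write_fastq(
    matrix: CountMatrix,
    index: LibraryIndex,
    out_dir: str | Path,
    seed: int = 0,
) -> dict[str, Path]:
    """Emit one FASTQ per sample with each guide's spacer embedded in flanks.

    Reads are shuffled (seeded) so counting order-independence is exercised.
    Returns sample_id -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spacer = {e.guide_id: e.spacer for e in index.entries}
    paths: dict[str, Path] = {}
    for sid in matrix.counts.columns:
        col = matrix.counts[sid]
        reads = [
            FASTQ_FLANK5 + spacer[gid] + FASTQ_FLANK3
            for gid, c in col.items()
            for _ in range(int(c))
        ]
        order = rng.permutation(len(reads))
        path = out_dir / f"{sid}.fastq"
        with open(path, "w") as fh:
            for i, idx in enumerate(order):
                seq = reads[idx]
                fh.write(f"@{sid}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sid] = path
    return paths


@dataclass
class NetworkTruth:
    """Planted complex rosters and the hit-sampling record."""

    rosters: dict[str, frozenset[str]]
    hits: frozenset[str]


def simulate_network(
    n_proteins: int = 200,
    n_complexes: int = 10,
    size_range: tuple[int, int] = (3, 8),
    within_prob: float = 0.9,
    background_prob: float = 0.002,
    hit_fraction: float = 0.3,
    seed: int = 0,
    complex_weight: float = 4.0,
) -> tuple[pd.DataFrame, "ComplexCatalog", list[str], NetworkTruth]:
    """Random bait-prey table, complex catalog and a complex-enriched hit list.

    Complex rosters are sampled (possibly overlapping) from the protein pool;
    within-complex pairs become bait-prey rows with probability
    ``within_prob`` plus uniform background pairs at ``background_prob``.
    Hits are ``round(hit_fraction * n_proteins)`` proteins drawn without
    replacement with weight ``complex_weight`` for complex members, so
    complex completeness varies across draws.
    """
    from phagoscreen.network import ComplexCatalog

    if size_range[0] < 2 or size_range[1] > n_proteins:
        raise ValueError("infeasible complex size range")
    rng = np.random.default_rng(seed)
    proteins = np.array([f"P{i + 1:05d}" for i in range(n_proteins)])
    rosters: dict[str, frozenset[str]] = {}
    records = []
    for c in range(n_complexes):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(proteins, size=size, replace=False)
        cid = f"CPX{c + 1:03d}"
        rosters[cid] = frozenset(members)
        records.append((cid, f"complex {c + 1}", list(members)))
    catalog = ComplexCatalog.from_records(records)

    rows = []
    for cid, members in rosters.items():
        mem = sorted(members)
        for i, a in enumerate(mem):
            for b in mem[i + 1 :]:
                if rng.random() < within_prob:
                    rows.append({"bait": a, "prey": b, "source": cid})
    n_pairs = n_proteins * (n_proteins - 1) // 2
    n_bg = rng.binomial(n_pairs, background_prob)
    for _ in range(n_bg):
        a, b = rng.choice(proteins, size=2, replace=False)
        rows.append({"bait": a, "prey": b, "source": "background"})
    interactions = pd.DataFrame(rows, columns=["bait", "prey", "source"])

    in_complex = np.isin(proteins, sorted(set().union(*rosters.values()) if rosters else set()))
    weights = np.where(in_complex, complex_weight, 1.0)
    weights = weights / weights.sum()
    n_hits = max(1, round(hit_fraction * n_proteins))
    hits = sorted(rng.choice(proteins, size=n_hits, replace=False, p=weights))
    return interactions, catalog, hits, NetworkTruth(rosters, frozenset(hits))
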