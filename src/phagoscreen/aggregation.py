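"""Step 2 of the screen analysis: aggregate ranked sgRNAs into gene scores.

Guides are ranked by a signed significance score r = sign(log2FC) *
(-log10 padj), so the most enriched guides sit at the top of the list and the
most depleted at the bottom. For each gene, its member guides are scored with
the weighted Kolmogorov-Smirnov running-sum statistic of gene-set enrichment
analysis (enrichment score, ES); significance comes from a permutation null
of uniform random same-size guide sets, giving separate depletion and
enrichment p-values that are BH-adjusted across genes per direction. A gene's
summary also carries the arithmetic mean log2 fold change of its guides
(aLFC, the volcano x-axis) and the count of its guides individually
significant at guide-level padj < 0.05 (the volcano dot size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phagoscreen.differential import adjust_bh
from phagoscreen.library import CONTROL_GENE

logger = logging.getLogger(__name__)

#: Floor applied to padj before the log so padj = 0 stays finite.
PADJ_EPSILON = 1e-300


def ranking_score(padj: np.ndarray, log2fc: np.ndarray) -> np.ndarray:
    """Signed significance: sign(log2FC) * (-log10 max(padj, eps))."""
    return np.sign(log2fc) * (-np.log10(np.maximum(padj, PADJ_EPSILON)))


def rank_sgrnas(stats: pd.DataFrame) -> pd.DataFrame:
    """Order guides by the signed significance score, descending.

    ``stats`` needs columns gene, log2fc, padj and a guide-id index. Guides
    with NA padj (untested or unconverged) are dropped. Ties are broken by
    guide id ascending so the ranking is fully deterministic.
    """
    kept = stats.dropna(subset=["padj"])
    if kept.empty:
        raise ValueError("no guides with adjusted p-values to rank")
    r = ranking_score(kept["padj"].to_numpy(), kept["log2fc"].to_numpy())
    ranked = pd.DataFrame(
        {"guide_id": kept.index, "gene": kept["gene"].to_numpy(), "r": r}
    )
    ranked = ranked.sort_values(
        ["r", "guide_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ranked


def _es_from_positions(
    abs_r: np.ndarray, positions: np.ndarray, weight: int
) -> float:
    """ES from sorted member positions in O(n) given the ranked |r| array.

    The running sum decreases linearly between hits, so its extrema occur
    just before or just after a hit; both candidates are checked for every
    member. When the positive and negative extremes tie in magnitude (within
    1e-12) the positive one is returned, so the statistic is deterministic
    under floating-point reordering.
    """
    n = len(positions)
    N = len(abs_r)
    if not 0 < n < N:
        raise ValueError("member set must be non-empty and a strict subset")
    w = abs_r[positions]
    total = w.sum()
    if weight == 0 or total == 0:
        incr = np.full(n, 1.0 / n)
    else:
        incr = w / total
    miss = 1.0 / (N - n)
    cum = np.cumsum(incr)
    misses_before = positions - np.arange(n)
    before = np.concatenate([[0.0], cum[:-1]]) - misses_before * miss
    after = cum - misses_before * miss
    best_pos = float(max(np.max(after), np.max(before), 0.0))
    best_neg = float(min(np.min(after), np.min(before), 0.0))
    if best_pos >= -best_neg - 1e-12:
        return best_pos
    return best_neg


def enrichment_score(
    ranked: pd.DataFrame, members: set[str], weight: int = 0
) -> float:
    """Signed maximum deviation of the GSEA running sum for ``members``.

    Hits add |r|**weight normalized over the member sum (uniform increments
    when weight is 0 or all member scores are 0); misses subtract
    1/(N - n). ES lies in [-1, 1]: negative when members concentrate at the
    depleted end of the list.
    """
    if weight not in (0, 1):
        raise ValueError("weight must be 0 or 1")
    ids = ranked["guide_id"].to_numpy()
    mask = np.isin(ids, list(members))
    if mask.sum() != len(members):
        missing = members - set(ids)
        raise ValueError(f"members not in ranked list: {sorted(missing)[:5]}")
    positions = np.flatnonzero(mask)
    return _es_from_positions(np.abs(ranked["r"].to_numpy()), positions, weight)


def _null_es(
    abs_r: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator, weight: int
) -> np.ndarray:
    """Null ES for uniform random guide sets of a given size."""
    N = len(abs_r)
    draws = rng.random((n_perm, N)).argpartition(set_size, axis=1)[:, :set_size]
    draws.sort(axis=1)
    return np.array(
        [_es_from_positions(abs_r, draws[i], weight) for i in range(n_perm)]
    )


def permutation_p(
    ranked: pd.DataFrame,
    members: set[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight: int = 0,
) -> tuple[float, float]:
    """Permutation p-values for depletion and enrichment of a guide set.

    The null redraws ``n_perm`` uniform random guide sets of the same size
    from the ranked list. With the add-one estimator the smallest attainable
    p is 1/(n_perm + 1), so p is never exactly zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es_obs = enrichment_score(ranked, members, weight)
    rng = np.random.default_rng(seed)
    null = _null_es(np.abs(ranked["r"].to_numpy()), len(members), n_perm, rng, weight)
    p_enr = (1.0 + np.sum(null >= es_obs)) / (n_perm + 1.0)
    p_dep = (1.0 + np.sum(null <= es_obs)) / (n_perm + 1.0)
    return p_dep, p_enr


def aggregate_genes(
    stats: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: int = 0,
    guide_sig_cutoff: float = 0.05,
    control_gene: str = CONTROL_GENE,
) -> pd.DataFrame:
    """Per-gene table: aLFC, ES, permutation p per direction, BH padj, n_sig.

    The permutation null depends only on the member-set size, so one seeded
    null distribution per distinct guide count is shared across genes --
    statistically identical to redrawing per gene, and what makes 1,000
    permutations per gene tractable on a genome-scale ranking. BH adjustment
    is applied across genes separately within each direction; the reported
    ``padj`` and ``direction`` follow the gene's dominant (smaller-raw-p)
    direction. The control pseudo-gene stays in the ranked background but
    gets no gene row.
    """
    ranked = rank_sgrnas(stats)
    kept = stats.dropna(subset=["padj"])
    abs_r = np.abs(ranked["r"].to_numpy())
    pos_of = {g: i for i, g in enumerate(ranked["guide_id"])}

    dropped = set(stats["gene"].unique()) - set(kept["gene"].unique()) - {control_gene}
    for gene in sorted(dropped):
        logger.info("gene %s dropped: no guides with valid statistics", gene)

    groups = {
        gene: sub
        for gene, sub in kept.groupby("gene", sort=True)
        if gene != control_gene
    }
    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({len(sub) for sub in groups.values() if 0 < len(sub) < len(ranked)}):
        null_by_size[size] = _null_es(abs_r, size, n_perm, rng, weight)

    rows = []
    for gene, sub in groups.items():
        positions = np.sort([pos_of[g] for g in sub.index])
        if not 0 < len(positions) < len(ranked):
            logger.info("gene %s dropped: member set not a strict subset", gene)
            continue
        es = _es_from_positions(abs_r, positions, weight)
        null = null_by_size[len(positions)]
        p_enr = (1.0 + np.sum(null >= es)) / (n_perm + 1.0)
        p_dep = (1.0 + np.sum(null <= es)) / (n_perm + 1.0)
        rows.append(
            {
                "gene": gene,
                "n_guides": len(sub),
                "alfc": float(sub["log2fc"].mean()),
                "es": es,
                "p_dep": p_dep,
                "p_enr": p_enr,
                "n_sig": int((sub["padj"] < guide_sig_cutoff).sum()),
            }
        )
    if not rows:
        raise ValueError("no genes with testable guides")
    out = pd.DataFrame(rows).set_index("gene")
    out["padj_dep"] = adjust_bh(out["p_dep"].to_numpy())
    out["padj_enr"] = adjust_bh(out["p_enr"].to_numpy())
    dep_dominant = out["p_dep"].to_numpy() <= out["p_enr"].to_numpy()
    out["direction"] = np.where(dep_dominant, "depleted", "enriched")
    out["padj"] = np.where(dep_dominant, out["padj_dep"], out["padj_enr"])
    return out


@dataclass
class HitList:
    """Genes passing the hit thresholds for one contrast and direction."""

    contrast: str
    direction: str
    padj_cutoff: float
    genes: list[str] = field(default_factory=list)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def call_hits(
    genes: pd.DataFrame,
    direction: str = "depleted",
    padj_cutoff: float = 0.05,
    use_raw_p: bool = False,
    contrast: str = "",
) -> HitList:
    """Select genes with direction-consistent aLFC and padj below the cutoff.

    ``use_raw_p`` switches the threshold to the unadjusted permutation p (a
    laxer convention some screens report); the default is the BH-adjusted
    p-value of the requested direction.
    """
    if direction not in {"depleted", "enriched"}:
        raise ValueError(f"unknown direction {direction!r}")
    col = ("p_dep" if use_raw_p else "padj_dep") if direction == "depleted" else (
        "p_enr" if use_raw_p else "padj_enr"
    )
    sign_ok = genes["alfc"] < 0 if direction == "depleted" else genes["alfc"] > 0
    sel = (genes[col] <= padj_cutoff) & sign_ok
    return HitList(
        contrast=contrast,
        direction=direction,
        padj_cutoff=padj_cutoff,
        genes=sorted(genes.index[sel]),
    )


def write_gene_stats(genes: pd.DataFrame, path: str) -> None:
    genes.to_csv(path, sep="\t")


def write_volcano_table(genes: pd.DataFrame, path: str) -> None:
    """Volcano-ready TSV: aLFC, -log10 padj and per-gene significant-guide count."""
    vol = pd.DataFrame(
        {
            "alfc": genes["alfc"],
            "neg_log10_padj": -np.log10(np.maximum(genes["padj"], PADJ_EPSILON)),
            "n_sig": genes["n_sig"],
        },
        index=genes.index,
    )
    vol.to_csv(path, sep="\t")


def write_hits(hits: HitList, path: str) -> None:
    with open(path, "w") as fh:
        for gene in hits.genes:
            fh.write(gene + "\n")
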