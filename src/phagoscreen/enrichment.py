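"""Over-representation analysis of hit lists against gene-set collections.

Each gene set is tested with a two-sided Fisher exact test on the 2x2 table
of hit/non-hit x in-set/out-of-set within a gene universe (by default the
screened genes, the proper background for a screen hit list). Two-sided means
the sum of probabilities of all tables at least as unlikely as the observed
one under the hypergeometric null. p-values are BH-adjusted across tested
terms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from phagoscreen.differential import adjust_bh


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Parse a GMT file into {term_id: {"name": ..., "members": set}}."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: need term, name, >=1 member")
            term_id, name, *members = fields
            if term_id in sets:
                raise ValueError(f"{path}: duplicate term {term_id!r}")
            member_set = {m.strip().upper() for m in members if m.strip()}
            if not member_set:
                raise ValueError(f"{path} line {lineno}: term {term_id!r} has no members")
            sets[term_id] = {"name": name, "members": member_set}
    return sets


def fisher_ora(
    hits: list[str] | set[str],
    universe: list[str] | set[str],
    collection: dict[str, dict],
) -> pd.DataFrame:
    """Fisher over-representation of ``hits`` within ``universe`` per gene set.

    Sets are intersected with the universe before testing; empty intersections
    are dropped. Returns a table sorted by padj (ties by raw p, then term id)
    with the 2x2 margins, sample odds ratio, p and BH padj.
    """
    hit_set = {str(h).strip().upper() for h in hits}
    uni = {str(u).strip().upper() for u in universe}
    stray = hit_set - uni
    if stray:
        raise ValueError(f"hits not in universe: {sorted(stray)[:10]}")
    n, N = len(hit_set), len(uni)
    rows = []
    for term_id, info in collection.items():
        members = info["members"] & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & hit_set)
        table = np.array([[k, n - k], [K - k, N - n - K + k]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (
                (k * (N - n - K + k)) / ((n - k) * (K - k))
                if (n - k) > 0 and (K - k) > 0
                else np.inf
            )
        rows.append(
            {
                "term_id": term_id,
                "name": info.get("name", term_id),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows)
    out["padj"] = adjust_bh(out["p"].to_numpy())
    out = out.sort_values(["padj", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out


def write_ora(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
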