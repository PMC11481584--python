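"""Gene-set over-representation testing by two-sided Fisher's exact test.

DEG lists are tested against flat gene sets (GMT format) over a stated
universe — by default the genes actually tested for differential expression
in the relevant cell type.  Each term yields a 2x2 table

    =============  ========  ============
                   in term   not in term
    DEG            k         n - k
    non-DEG        K - k     N - K - (n - k)
    =============  ========  ============

whose two-sided p-value is the sum of hypergeometric probabilities of all
tables at most as probable as the observed one (the method of small
p-values).  BH adjustment runs across all tested terms; q < 0.05 flags
significance.  Up- and down-regulated lists are tested separately when a
direction label is supplied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = ["read_gmt", "write_gmt", "fisher_term_test", "run_enrichment"]


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into {term_id: (term_name, member gene set)}."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs id, name, >=1 gene): {line[:80]!r}")
        sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return sets


def write_gmt(sets: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([tid, name, *sorted(genes)])
        for tid, (name, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def fisher_term_test(k: int, K: int, n: int, N: int) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test of one term's 2x2 table.

    Parameters: ``k`` DEGs in the term, ``K`` universe genes in the term,
    ``n`` DEGs, ``N`` universe genes.

    Returns ``(p_value, odds_ratio, continuity_used)``; the odds ratio is
    the sample odds ratio ad/bc, computed with a 0.5 continuity addition to
    every cell (flagged) only when a zero margin makes it undefined.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= max(0, n - (N - K))):
        raise ValueError(f"inconsistent contingency counts k={k}, K={K}, n={n}, N={N}")
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    if b * c > 0:
        odds, continuity = (a * d) / (b * c), False
    else:
        odds, continuity = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return p, float(odds), continuity


def run_enrichment(
    deg_set,
    universe,
    gene_sets: dict[str, tuple[str, frozenset[str]]],
    directions: pd.Series | dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a DEG list in flat gene sets.

    Terms are intersected with the universe before testing; terms with no
    universe member are dropped.  BH adjustment runs across all tested
    terms; rows are ordered by (q, p).  When ``directions`` maps DEGs to
    ``up``/``down``, each direction is tested separately (the direction
    appears in a ``direction`` column and the BH family is per direction).

    Returns a DataFrame with term_id, term_name, k, K, n, N, count,
    odds_ratio, or_continuity, p_value, q_value, significant.
    """
    universe = frozenset(universe)
    deg_set = frozenset(deg_set)
    if not universe:
        raise ValueError("empty universe")
    if not deg_set:
        raise ValueError("empty DEG set")
    extra = deg_set - universe
    if extra:
        raise ValueError(f"DEGs outside the universe: {sorted(extra)[:5]}...")

    if directions is not None:
        directions = dict(directions)
        frames = []
        for direction in ("up", "down"):
            subset = frozenset(g for g in deg_set if directions.get(g) == direction)
            if not subset:
                continue
            sub = run_enrichment(subset, universe, gene_sets, alpha=alpha)
            sub.insert(0, "direction", direction)
            frames.append(sub)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    N, n = len(universe), len(deg_set)
    rows = []
    for term_id in sorted(gene_sets):
        term_name, genes = gene_sets[term_id]
        members = genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & deg_set)
        p, odds, cont = fisher_term_test(k, K, n, N)
        rows.append(
            {
                "term_id": term_id, "term_name": term_name,
                "k": k, "K": K, "n": n, "N": N, "count": k,
                "odds_ratio": odds, "or_continuity": cont, "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "count",
                     "odds_ratio", "or_continuity", "p_value", "q_value", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    out = out.sort_values(["q_value", "p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return out
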