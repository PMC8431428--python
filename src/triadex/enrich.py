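"""Over-representation analysis against a gene→term annotation map.

One-sided hypergeometric test per term: with background size N, term size
K, query-set size n and overlap k, the p-value is P(X ≥ k) for
X ~ Hypergeom(N, K, n).  P-values are BH-adjusted across tested terms and
each term reports its rich factor k/K (fraction of the term captured by
the query set).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .de import adjust_bh


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    gene_set: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    min_term: int = 2,
) -> pd.DataFrame:
    """Term over-representation of ``gene_set`` within ``background``.

    Terms are intersected with the background; terms smaller than
    ``min_term`` after intersection are skipped.  Returns a DataFrame
    sorted by p-value with columns term, k, K, n, N, rich_factor,
    p_value, p_adj and significant (p_adj < alpha).
    """
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    gene_set = set(gene_set)
    offenders = gene_set - background
    if offenders:
        raise ValueError(
            f"gene set contains {len(offenders)} ids outside the background, "
            f"e.g. {sorted(offenders)[:5]}"
        )
    N, n = len(background), len(gene_set)
    rows = []
    for term, members in annotation.items():
        term_genes = set(members) & background
        K = len(term_genes)
        if K < min_term:
            continue
        k = len(term_genes & gene_set)
        rows.append(
            dict(
                term=term, k=k, K=K, n=n, N=N,
                rich_factor=k / K,
                p_value=hypergeom_pvalue(k, K, n, N),
            )
        )
    out = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "rich_factor", "p_value"]
    )
    if len(out):
        out["p_adj"] = adjust_bh(out["p_value"].to_numpy())
        out = out.sort_values(
            ["p_value", "term"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        out["p_adj"] = []
    out["significant"] = out["p_adj"] < alpha if len(out) else []
    return out
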