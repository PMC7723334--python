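"""Over-representation analysis against GO-style / pathway gene sets.

The statistic is the hypergeometric upper tail P(X >= k) for k DE genes
falling into a term of size K, drawn n from a background of N; q-values
are BH-adjusted within each namespace (BP/CC/MF/pathway separately).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .de import adjust_bh
from .io import NAMESPACES, GeneSetCollection

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["term_id", "name", "namespace", "k", "n", "K", "N", "p", "q",
                  "fold_enrichment"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k successes observed among n draws from a population of N containing
    K successes; computed via the stable survival function.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    de_genes,
    collection: GeneSetCollection,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """One enrichment result per term of size >= min_term_size.

    DE genes outside the background are dropped (logged); q is BH within
    namespace; rows sort by (q, p, term id).
    """
    background = collection.background
    if not background:
        raise ValueError("empty background universe")
    de = set(de_genes)
    dropped = de - background
    if dropped:
        logger.info("dropping %d DE genes absent from background", len(dropped))
    de &= background
    n, N = len(de), len(background)
    rows = []
    for tid in sorted(collection.terms):
        name, ns, members = collection.terms[tid]
        members = members & background
        K = len(members)
        if K < min_term_size:
            continue
        k = len(de & members)
        p = hypergeom_upper_tail(k, K, n, N)
        fold = (k / n) / (K / N) if n else 0.0
        rows.append((tid, name, ns, k, n, K, N, p, fold))
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "namespace", "k", "n", "K", "N", "p",
                       "fold_enrichment"]
    )
    df["q"] = 1.0
    for ns in NAMESPACES:
        mask = df["namespace"] == ns
        if mask.any():
            df.loc[mask, "q"] = adjust_bh(df.loc[mask, "p"].to_numpy())
    return df[RESULT_COLUMNS].sort_values(
        ["q", "p", "term_id"], ignore_index=True
    )


def top_terms(results: pd.DataFrame, n: int = 30, namespace: str | None = None) -> pd.DataFrame:
    """Top-n most enriched terms (optionally within one namespace)."""
    df = results if namespace is None else results[results["namespace"] == namespace]
    return df.head(n).reset_index(drop=True)
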