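"""Over-representation analysis of protein sets against flat term annotations.

For a query set (e.g. the significantly decreased proteins) drawn from a
background (all proteins that passed the valid-value filter), each term is
scored by the one-sided Fisher exact test on the 2x2 table
(in-term/out-of-term x in-query/out-of-query), equivalently the
hypergeometric upper tail P(X >= k).  Fold enrichment is (k/n)/(K/N).
Benjamini-Hochberg q-values are computed over all tested terms.  Terms with
fewer than ``min_term_size`` proteins in the background are excluded from
testing, mirroring the >= 5-protein rule; term sizes are counted after
restriction to the background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnnotationSet, ValidationError

DEFAULT_MIN_TERM_SIZE = 5


def fisher_one_sided(k: int, K: int, n: int, N: int) -> float:
    """One-sided (over-representation) Fisher exact p for a 2x2 table.

    Equals the hypergeometric upper tail P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: set[str],
    background: set[str],
    annotations: AnnotationSet,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
) -> pd.DataFrame:
    """Term over-representation of ``query`` within ``background``.

    Returns one row per tested term, sorted by p then term id (stable):
    ``K`` term size in background, ``N`` background size, ``n`` query size,
    ``k`` overlap, ``fold_enrichment``, ``p_one_sided``, ``q_bh``.
    """
    query = set(query)
    background = set(background)
    offenders = query - background
    if offenders:
        raise ValidationError(
            f"query proteins absent from background: {sorted(offenders)[:10]}"
        )
    if len(background) < 2:
        raise ValidationError("background must contain >= 2 proteins")

    N = len(background)
    n = len(query)
    rows = []
    for term_id in sorted(annotations.term_membership):
        members = annotations.term_membership[term_id] & background
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & query)
        expected = K / N * n
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            {
                "term_id": term_id,
                "name": annotations.term_names.get(term_id, term_id),
                "K": K,
                "N": N,
                "n": n,
                "k": k,
                "expected": expected,
                "fold_enrichment": fold,
                "p_one_sided": fisher_one_sided(k, K, n, N),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "K", "N", "n", "k",
            "expected", "fold_enrichment", "p_one_sided",
        ],
    )
    if not table.empty:
        table["q_bh"] = bh_fdr(table["p_one_sided"].to_numpy())
        table = table.sort_values(
            ["p_one_sided", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q_bh"] = pd.Series(dtype=float)
    return table
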