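"""One-sided Fisher's exact (hypergeometric) term over-representation.

For a gene set of size n drawn from a background universe of size N, a
term annotating K universe genes and k set genes, the enrichment p-value
is the upper hypergeometric tail P(X >= k).  FDR is Benjamini-Hochberg
across all terms tested in one run.  Terms with k = 0 get p = 1 exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import adjust_bh
from .errors import ValidationError
from .io import AnnotationSet

log = logging.getLogger(__name__)

ENRICH_COLUMNS = ["term_id", "term_name", "k", "n", "K", "N",
                  "pvalue", "fdr", "neg_log10_fdr"]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    gene_set: set[str],
    annotations: AnnotationSet,
    background: set[str],
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Per-term one-sided over-representation of ``gene_set`` in ``background``.

    Genes outside the background are dropped (logged); annotations are
    restricted to the background; terms annotating fewer than
    ``min_term_size`` universe genes are untestable and skipped (logged).
    Rows are ordered by FDR, then raw p, then term id.
    """
    if not background:
        raise ValidationError("background universe must be nonempty")
    gene_set = set(gene_set)
    outside = gene_set - set(background)
    if outside:
        log.info("dropped %d query gene(s) outside the background", len(outside))
        gene_set = gene_set - outside
    restricted = annotations.restricted(set(background))
    N, n = len(background), len(gene_set)
    rows = []
    skipped = 0
    for tid in sorted(restricted.terms):
        name, members = restricted.terms[tid]
        K = len(members)
        if K < min_term_size:
            skipped += 1
            continue
        k = len(members & gene_set)
        p = 1.0 if k == 0 else hypergeom_tail(k, N, K, n)
        rows.append({"term_id": tid, "term_name": name, "k": k, "n": n,
                     "K": K, "N": N, "pvalue": p})
    if skipped:
        log.info("skipped %d untestable term(s) with K < %d", skipped, min_term_size)
    table = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:7])
    if len(table):
        table["fdr"] = adjust_bh(table["pvalue"].to_numpy())
        with np.errstate(divide="ignore"):
            table["neg_log10_fdr"] = -np.log10(table["fdr"])
        table = table.sort_values(
            ["fdr", "pvalue", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
        table["neg_log10_fdr"] = pd.Series(dtype=float)
    return table


def top_terms(results: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Top-n terms by ascending FDR; ties broken by raw p, then term id."""
    if results.empty:
        raise ValidationError("enrichment result table is empty")
    ordered = results.sort_values(["fdr", "pvalue", "term_id"], kind="stable")
    return ordered.head(n).reset_index(drop=True)
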