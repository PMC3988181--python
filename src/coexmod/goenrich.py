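"""Per-module GO term enrichment by the hypergeometric test.

Each module is tested against the genome-wide background of annotated genes:
for a term annotating ``K`` of ``N`` background genes, observing ``k``
annotated members in a module with ``n`` annotated members has upper-tail
probability ``P(X >= k)`` under ``X ~ Hypergeometric(N, K, n)``.  Only
annotated genes enter the counts, so unannotated module members neither help
nor hurt (the custom-reference convention of GO enrichment tools).  Both a
per-module Bonferroni correction and Benjamini-Hochberg FDR over the same
term set are reported; FDR < alpha is the module-selection criterion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .moddetect import ModulePartition

__all__ = ["hypergeom_tail", "enrich_modules", "select_modules_by_terms"]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` carry the term; ``n`` genes drawn
    (the module); ``k`` observed carriers.  Summed in log space.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    if k > K:
        raise ValueError(f"k={k} exceeds K={K}")
    if k <= max(0, n - (N - K)):  # at or below the support minimum
        return 1.0
    upper = min(n, K)
    j = np.arange(k, upper + 1)
    if j.size == 0:
        return 0.0
    logp = stats.hypergeom.logpmf(j, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich_modules(
    partition: ModulePartition,
    ann: pd.DataFrame,
    min_module_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric GO enrichment of every sufficiently large module.

    The background ``N`` is the number of distinct annotated genes; the term
    universe is every term with at least one annotated gene genome-wide, and
    the same universe feeds the per-module Bonferroni factor and BH-FDR.
    Modules with fewer than ``min_module_size`` annotated members are not
    tested.  Returns one row per (module, term) with counts, raw p,
    Bonferroni and BH-FDR adjusted p, and a ``significant`` flag
    (``fdr_bh < alpha``).
    """
    if ann.empty:
        raise ValueError("annotation table is empty")
    ann = ann.drop_duplicates(["gene_id", "term_accession"])
    background = set(ann["gene_id"])
    n_background = len(background)
    term_genes = ann.groupby("term_accession")["gene_id"].agg(set)
    term_names = ann.drop_duplicates("term_accession").set_index("term_accession")["term_name"]

    rows = []
    for module_id in partition.module_ids():
        members = set(partition.members(module_id)) & background
        n = len(members)
        if n < min_module_size:
            continue
        module_rows = []
        for term, genes in term_genes.items():
            big_k = len(genes)
            k = len(members & genes)
            p_raw = hypergeom_tail(k, n, big_k, n_background)
            module_rows.append((module_id, term, term_names[term], k, n, big_k,
                                n_background, p_raw))
        sub = pd.DataFrame(
            module_rows,
            columns=["module_id", "term_accession", "term_name", "k", "n", "K", "N", "p_raw"],
        )
        n_tests = len(sub)
        sub["p_bonferroni"] = np.minimum(1.0, sub["p_raw"] * n_tests)
        sub["fdr_bh"] = multipletests(sub["p_raw"], method="fdr_bh")[1]
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["module_id", "term_accession", "term_name", "k", "n", "K", "N",
                     "p_raw", "p_bonferroni", "fdr_bh", "significant"]
        )
    table = pd.concat(rows, ignore_index=True)
    table["significant"] = table["fdr_bh"] < alpha
    return table.sort_values(["module_id", "p_raw", "term_accession"], ignore_index=True)


def select_modules_by_terms(
    enrichment: pd.DataFrame, keywords: list[str], alpha: float = 0.05
) -> list[int]:
    """Modules with a significant term whose name contains any keyword.

    Matching is case-insensitive substring on ``term_name``; significance is
    ``fdr_bh < alpha``.
    """
    if not keywords:
        raise ValueError("keyword list is empty")
    if enrichment.empty:
        return []
    sig = enrichment[enrichment["fdr_bh"] < alpha]
    lowered = [kw.lower() for kw in keywords]
    hit = sig["term_name"].str.lower().apply(lambda name: any(kw in name for kw in lowered))
    return sorted(sig.loc[hit, "module_id"].unique().tolist())
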