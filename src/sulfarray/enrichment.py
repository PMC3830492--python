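"""Singular Enrichment Analysis: per-term chi-squared tests of a gene list
against an array-wide background, with Benjamini–Yekutieli FDR control.

For every GO term mapping at least ``min_entries`` background genes, the
2×2 table (in input list vs not) × (annotated to term vs not) is tested by
Pearson's chi-squared (df = 1, no continuity correction by default, matching
AgriGO's chi-square option).  Raw p-values are adjusted by the
Benjamini–Yekutieli step-up, which is valid under arbitrary dependence
between terms — appropriate because GO terms overlap.  Both over- and
under-represented terms are reported, with the direction flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentError", "chi_squared_enrichment", "by_fdr", "run_sea"]


class EnrichmentError(ValueError):
    """Invalid enrichment input (empty list, inconsistent counts, bad p)."""


def _term_counts(
    input_set: set[str], annotation: pd.DataFrame, background_set: set[str]
) -> pd.DataFrame:
    ann = annotation[annotation["gene_id"].isin(background_set)]
    ann = ann.drop_duplicates(["gene_id", "term_id"])
    by_term = ann.groupby("term_id", sort=True)["gene_id"]
    rows = []
    for term, genes in by_term:
        gset = set(genes)
        rows.append((term, len(gset & input_set), len(gset)))
    return pd.DataFrame(rows, columns=["term_id", "k", "K"])


def chi_squared_enrichment(
    input_set: set[str],
    annotation: pd.DataFrame,
    background_set: set[str],
    min_entries: int = 5,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-term 2×2 Pearson chi-squared tests.

    Returns one row per term with K >= min_entries background mappings:
    counts (k, n, K, N), the chi-squared statistic, its df=1 p-value and the
    direction of deviation (sign of k/n − K/N).
    """
    if not input_set:
        raise EnrichmentError("empty input gene list")
    extra = set(input_set) - set(background_set)
    if extra:
        raise EnrichmentError(
            f"input genes not in background: {sorted(extra)[:3]}..."
            if len(extra) > 3
            else f"input genes not in background: {sorted(extra)}"
        )
    n = len(input_set)
    N = len(background_set)
    counts = _term_counts(set(input_set), annotation, set(background_set))
    if (counts["K"] > N).any():
        raise EnrichmentError("term counts inconsistent with background size")
    counts = counts[counts["K"] >= min_entries].reset_index(drop=True)
    chi2 = np.zeros(len(counts))
    p = np.ones(len(counts))
    for i, (k, K) in enumerate(zip(counts["k"], counts["K"])):
        table = np.array([[k, n - k], [K - k, N - n - (K - k)]], dtype=float)
        if (table < 0).any():
            raise EnrichmentError("term counts inconsistent with input list")
        # degenerate margins (term covers everything / nothing) carry no signal
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            continue
        res = stats.chi2_contingency(table, correction=continuity_correction)
        chi2[i], p[i] = res.statistic, res.pvalue
    out = counts.copy()
    out["n"] = n
    out["N"] = N
    out["chi2"] = chi2
    out["p_raw"] = p
    out["input_pct"] = 100.0 * out["k"] / n
    out["background_pct"] = 100.0 * out["K"] / N
    out["direction"] = np.where(
        out["input_pct"] >= out["background_pct"], "over", "under"
    )
    return out[
        [
            "term_id",
            "k",
            "n",
            "K",
            "N",
            "chi2",
            "p_raw",
            "input_pct",
            "background_pct",
            "direction",
        ]
    ]


def by_fdr(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjustment (FDR under dependency).

    adj_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) the m-th harmonic number; returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def run_sea(
    input_set: set[str],
    annotation: pd.DataFrame,
    background_set: set[str],
    min_entries: int = 5,
    alpha: float = 0.01,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Full singular enrichment analysis of one gene list.

    Chi-squared tests per term, BY adjustment across all tested terms, a
    significance flag at ``p_adj < alpha``, sorted by adjusted p (ties by
    term id).
    """
    res = chi_squared_enrichment(
        input_set, annotation, background_set, min_entries, continuity_correction
    )
    res = res.copy()
    res["p_adj"] = by_fdr(res["p_raw"].to_numpy())
    res["significant"] = res["p_adj"] < alpha
    return res.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
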