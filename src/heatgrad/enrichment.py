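"""Hypergeometric category enrichment with Benjamini-Hochberg FDR.

Given a called gene set (e.g. the upregulated heat-responsive genes), a
gene universe (all genes surviving the CPM filter) and a gene -> category
annotation map (e.g. GO terms), each category is tested with the
upper-tail hypergeometric probability of drawing at least ``k`` annotated
genes when sampling ``K`` genes from a universe of ``N`` containing ``n``
annotated ones.  The enrichment fold is ``(k/K) / (n/N)``.
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

ANNOTATION_COLUMNS = ("gene", "term")


def read_annotation(path) -> pd.DataFrame:
    """Read a two-column gene -> term TSV (one pair per line)."""
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def hypergeom_enrich(
    gene_set,
    annotation: pd.DataFrame,
    universe,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``gene_set`` within ``universe``.

    Every term annotated in the universe is reported (terms absent from the
    set keep p = 1), sorted by FDR then descending fold.  Genes in the set
    but not the universe are an error.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    stray = sorted(g for g in gene_set if g not in universe)
    if stray:
        raise ValueError(f"genes in set but not in universe: {stray}")

    ann = annotation[annotation["gene"].isin(universe)].drop_duplicates(
        subset=["gene", "term"]
    )
    N = len(universe)
    K = len(gene_set)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        genes_with_term = set(sub["gene"])
        n = len(genes_with_term)
        k = len(genes_with_term & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, n, K)) if k > 0 else 1.0
        fold = (k / K) / (n / N) if K > 0 else 0.0
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": p, "fold": fold}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_value", "fold", "fdr", "enriched"]
        )
        return out
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["enriched"] = out["fdr"] < fdr_max
    return out.sort_values(
        ["fdr", "fold"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
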