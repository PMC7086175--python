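"""Functional-term enrichment of orthogroup sets.

Orthogroups inherit the union of their member genes' terms.  Enrichment
of a foreground set (e.g. orthogroups that underwent a targeting change)
against a background (orthogroups with at least one organelle-targeted
protein, restricted by the caller) is tested per term with an upper-tail
hypergeometric test and Benjamini-Hochberg correction; terms are called
significant at q <= 0.01.  Optional parent-term propagation supports
hierarchical vocabularies (MapMan bins, subcompartment trees).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .trees import OrgfluxError


class EnrichmentError(OrgfluxError):
    pass


def inherit_terms(
    gene_terms: dict[str, set],
    orthogroups: dict[str, list],
    parent_map: dict[str, str] | None = None,
) -> dict[str, set]:
    """Orthogroup -> union of member genes' terms.

    With ``parent_map`` (term -> parent term), every term also implies its
    ancestors (cycle-safe).
    """
    table: dict[str, set] = {}
    for og, genes in orthogroups.items():
        terms: set = set()
        for gene in genes:
            terms |= gene_terms.get(gene, set())
        if parent_map:
            closed = set(terms)
            for term in terms:
                seen = {term}
                parent = parent_map.get(term)
                while parent is not None and parent not in seen:
                    closed.add(parent)
                    seen.add(parent)
                    parent = parent_map.get(parent)
            terms = closed
        table[og] = terms
    return table


def enrich(
    foreground: set,
    background: set,
    table: dict[str, set],
    alpha: float = 0.01,
    min_background_carriers: int = 2,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment with BH correction.

    Columns: term, k (foreground carriers), K (background carriers),
    n (foreground size), N (background size), p, q, significant.
    Terms carried by fewer than ``min_background_carriers`` background
    orthogroups are not tested.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise EnrichmentError("foreground must be a subset of the background")
    N = len(background)
    n = len(foreground)
    carriers: dict[str, int] = {}
    hits: dict[str, int] = {}
    for og in background:
        for term in table.get(og, ()):
            carriers[term] = carriers.get(term, 0) + 1
            if og in foreground:
                hits[term] = hits.get(term, 0) + 1
    rows = []
    for term in sorted(carriers):
        K = carriers[term]
        if K < min_background_carriers:
            continue
        k = hits.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] <= alpha
    return df.sort_values(["q", "p", "term"]).reset_index(drop=True)
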