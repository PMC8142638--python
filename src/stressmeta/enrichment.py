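"""Over-representation analysis with an explicit fold-enrichment score.

Per term: a = term genes in the query, b = query size, c = term genes in
the universe, d = universe size; score = (a/b)/((c-a)/(d-b)); p is the
hypergeometric upper tail.  Two corrections are carried side by side:
Bonferroni (the CALL threshold for "enriched") and BH-FDR (the DISPLAYED
heatmap value) — both are part of the analysis contract, not redundancy.

Terms are flat sets (no ontology-hierarchy traversal); genes outside the
supplied universe are ignored when counting c, keeping a <= c <= d.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import adjust_pvalues
from .exceptions import StressmetaError
from .overlap import fold_enrichment, hypergeom_upper_tail

__all__ = ["enrich", "consensus_heatmap"]


def enrich(query, collection: Mapping[str, set], universe) -> pd.DataFrame:
    """ORA of a query gene set against a term collection within a universe.

    Returns one row per term: a, b, c, d, score, p, p_bonf, p_fdr.
    """
    query, universe = set(query), set(universe)
    stray = query - universe
    if stray:
        raise StressmetaError(
            f"query gene {sorted(stray)[0]!r} is outside the universe")
    if not collection:
        raise StressmetaError("empty term collection")
    b, d = len(query), len(universe)
    rows = []
    for term, genes in collection.items():
        term_in_universe = set(genes) & universe
        a = len(term_in_universe & query)
        c = len(term_in_universe)
        p = hypergeom_upper_tail(a, d, c, b) if a > 0 else 1.0
        rows.append((term, a, b, c, d, fold_enrichment(a, b, c, d), p))
    out = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "score", "p"])
    n_terms = len(out)
    out["p_bonf"] = np.minimum(1.0, out["p"] * n_terms)
    out["p_fdr"] = adjust_pvalues(out["p"].to_numpy())
    return out.set_index("term")


def consensus_heatmap(
    results: Mapping[str, Mapping[str, pd.DataFrame]],
    min_datasets: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term x (group, dataset) matrix of -log10(p_fdr) for consensus terms.

    A term is retained when it is called enriched (p_bonf < alpha) in at
    least ``min_datasets`` datasets within EITHER direction group.  Cells
    where the term was not called are NaN (the "not significant" marker);
    retained-but-absent combinations are NaN as well.
    """
    for group, tables in results.items():
        if min_datasets > len(tables):
            raise StressmetaError(
                f"min_datasets={min_datasets} exceeds the {len(tables)} datasets "
                f"in group {group!r}")

    keep: set[str] = set()
    for tables in results.values():
        called = pd.Series(0, dtype=int)
        for table in tables.values():
            hits = table.index[table["p_bonf"] < alpha]
            called = called.add(pd.Series(1, index=hits), fill_value=0)
        keep |= set(called.index[called >= min_datasets])

    columns = [(g, ds) for g, tables in results.items() for ds in tables]
    matrix = pd.DataFrame(
        np.nan,
        index=pd.Index(sorted(keep), name="term"),
        columns=pd.MultiIndex.from_tuples(columns, names=["group", "dataset"]),
    )
    for group, tables in results.items():
        for ds, table in tables.items():
            hit = table[table["p_bonf"] < alpha]
            common = matrix.index.intersection(hit.index)
            with np.errstate(divide="ignore"):
                matrix.loc[common, (group, ds)] = -np.log10(
                    hit.loc[common, "p_fdr"].to_numpy())
    return matrix
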