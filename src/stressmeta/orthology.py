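"""Collapse source-species gene lists onto the reference namespace.

Mapping rule: per source gene keep the top-scoring reference ortholog
(ties at the maximum all kept) plus any additional paralogs with score >=
``min_paralog_score``.  The score floor gates the extra paralogs, not the
best hit, so a gene whose only ortholog scores below the floor still maps;
a strict mode drops sub-floor top hits instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import StressmetaError

__all__ = ["OrthologyMapping", "map_to_reference"]


@dataclass
class OrthologyMapping:
    """Mapped reference set plus the mapping report."""

    mapped: set[str]
    unmapped: list[str]
    expansions: dict[str, list[str]] = field(default_factory=dict)

    def report_frame(self) -> pd.DataFrame:
        rows = [("unmapped", g, "") for g in self.unmapped]
        rows += [("one_to_many", g, ";".join(refs)) for g, refs in self.expansions.items()]
        return pd.DataFrame(rows, columns=["kind", "source_gene", "reference_genes"])


def map_to_reference(
    genes,
    table: pd.DataFrame,
    species: str | None = None,
    min_paralog_score: int = 3,
    strict: bool = False,
) -> OrthologyMapping:
    """Map a source gene set to the reference namespace via a scored table.

    ``table`` has columns source_gene, source_species, reference_gene,
    score.  Restricting to ``species`` (when given) must leave a non-empty
    table.  The result deduplicates many-to-one mappings (set semantics).
    """
    sub = table
    if species is not None:
        sub = table[table["source_species"] == species]
        if sub.empty:
            raise StressmetaError(f"ortholog table has no records for species {species!r}")
    if sub.empty:
        raise StressmetaError("ortholog table is empty")

    by_gene = {g: grp for g, grp in sub.groupby("source_gene")}
    mapped: set[str] = set()
    unmapped: list[str] = []
    expansions: dict[str, list[str]] = {}
    for gene in sorted(set(genes)):
        grp = by_gene.get(gene)
        if grp is None or grp.empty:
            unmapped.append(gene)
            continue
        top = int(grp["score"].max())
        keep = grp["score"] >= min(top, min_paralog_score)
        if strict and top < min_paralog_score:
            keep = grp["score"] >= min_paralog_score
        refs = sorted(set(grp.loc[keep, "reference_gene"]))
        if not refs:
            unmapped.append(gene)
            continue
        if len(refs) > 1:
            expansions[gene] = refs
        mapped.update(refs)
    return OrthologyMapping(mapped=mapped, unmapped=unmapped, expansions=expansions)
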