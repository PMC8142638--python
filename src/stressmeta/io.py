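"""Readers and writers for the package's plain-text dialects.

All formats are TSV or GMT.  Readers validate structure (unique gene ids,
rectangular matrices, numeric cells) and raise :class:`ParseError` with the
offending location; ``read(write(x)) == x`` on valid data.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ParseError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_de_table",
    "write_de_table",
]

SAMPLE_COLUMNS = ["sample_id", "genotype", "condition", "timepoint", "replicate"]
EDGE_COLUMNS = ["node_a", "node_b", "confidence"]
ORTHOLOG_COLUMNS = ["source_gene", "source_species", "reference_gene", "score"]
DE_COLUMNS = ["gene_id", "log2fc", "p", "p_adj", "contrast", "mode"]


def _check_rectangular(path: Path) -> None:
    """Reject ragged TSV files, reporting the first bad line."""
    with open(path) as fh:
        header = fh.readline()
        width = header.rstrip("\n").count("\t") + 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            n = line.rstrip("\n").count("\t") + 1
            if n != width:
                raise ParseError(
                    f"{path}: line {lineno} has {n} fields, expected {width}"
                )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column ``gene_id``)."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated gene_id {dup.iloc[0]!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ParseError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
        if vals.isna().any():
            gene = df.index[vals.isna().to_numpy()][0]
            raise ParseError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        df[col] = vals
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str, "condition": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing sample-metadata columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated sample_id {dup.iloc[0]!r}")
    return df.set_index("sample_id")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT needs term, description, >=1 gene")
            term = fields[0]
            if term in sets:
                raise ParseError(f"{path}: line {lineno}: duplicated term {term!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ParseError(f"{path}: line {lineno}: term {term!r} has no genes")
            sets[term] = genes
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing edge-list columns {missing}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any():
        raise ParseError(f"{path}: non-numeric confidence at row {int(conf.isna().idxmax()) + 2}")
    if ((conf < 0) | (conf > 1)).any():
        raise ParseError(f"{path}: confidence outside [0, 1]")
    df["confidence"] = conf
    if (df["node_a"] == df["node_b"]).any():
        node = df.loc[df["node_a"] == df["node_b"], "node_a"].iloc[0]
        raise ParseError(f"{path}: self-loop at node {node!r}")
    key = df[["node_a", "node_b"]].apply(lambda r: tuple(sorted(r)), axis=1)
    if key.duplicated().any():
        a, b = key[key.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate undirected edge {a!r}-{b!r}")
    return df.reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, columns=EDGE_COLUMNS)


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"source_gene": str, "source_species": str, "reference_gene": str})
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing ortholog columns {missing}")
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any() or (score < 1).any() or (score != score.astype(int)).any():
        raise ParseError(f"{path}: scores must be integers >= 1")
    df["score"] = score.astype(int)
    if df.duplicated(["source_gene", "reference_gene"]).any():
        row = df[df.duplicated(["source_gene", "reference_gene"])].iloc[0]
        raise ParseError(
            f"{path}: duplicated (source_gene, reference_gene) pair "
            f"({row['source_gene']!r}, {row['reference_gene']!r})"
        )
    return df.reset_index(drop=True)


def write_ortholog_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=ORTHOLOG_COLUMNS)


def read_de_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contrast": str, "mode": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing DE columns {missing}")
    if df["gene_id"].duplicated().any():
        gene = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicated gene_id {gene!r}")
    return df.set_index("gene_id")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def roundtrip_bytes(df: pd.DataFrame) -> bytes:
    """Canonical TSV bytes of a frame (used for manifest hashing)."""
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t")
    return buf.getvalue().encode()
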