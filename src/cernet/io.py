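"""Readers and writers for the pipeline's on-disk formats.

All tables are TSV.  Graphs are written as GraphML (lossless: node classes
and edge statistics survive a round trip) and as SIF triples
(``lnc<TAB>ceRNA<TAB>mrna``) for Cytoscape.  Malformed input is reported
with the file name and the offending line.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InteractionTable


class ParseError(ValueError):
    """A file violated its documented schema."""


def read_expression(
    path, design_path, classes_path=None
) -> ExpressionMatrix:
    """Read an expression TSV (first column transcript id, header = samples)
    plus a sample-annotation TSV (sample, condition, pair)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate transcript id {dup!r}")
    df.index.name = None
    design = read_design(design_path)
    classes = read_classes(classes_path) if classes_path else None
    return ExpressionMatrix(df, design, classes)


def read_design(path) -> pd.DataFrame:
    path = Path(path)
    design = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = {"condition", "pair"} - set(design.columns)
    if missing:
        raise ParseError(f"{path}: missing design columns {sorted(missing)}")
    return design


def read_classes(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns (transcript id, class)")
    df.columns = ["id", "class", *df.columns[2:]]
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ParseError(f"{path}: duplicate transcript id {dup!r}")
    classes = df.set_index("id")["class"]
    classes.index.name = None
    return classes


def write_expression(matrix: ExpressionMatrix, path, design_path, classes_path=None):
    matrix.values.rename_axis("transcript_id").to_csv(path, sep="\t")
    matrix.design.rename_axis("sample").to_csv(design_path, sep="\t")
    if classes_path and matrix.classes is not None:
        matrix.classes.rename_axis("id").rename("class").to_csv(
            classes_path, sep="\t"
        )


def read_interactions(path, gene_class: str) -> InteractionTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "mirna_id"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    empty = df["gene_id"].isna() | df["mirna_id"].isna()
    if empty.any():
        raise ParseError(f"{path}: empty id at line {int(empty.argmax()) + 2}")
    return InteractionTable(df, gene_class)


def write_interactions(table: InteractionTable, path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def read_id_list(path) -> set[str]:
    """One id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


SIF_RELATION = "ceRNA"


def write_graph(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a graph as GraphML (lossless) or SIF (tab-separated triples)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(g.edges):
                if g.nodes[u].get("node_class") == "mRNA":
                    u, v = v, u
                fh.write(f"{u}\t{SIF_RELATION}\t{v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r} (use 'graphml' or 'sif')")


def read_graph(path) -> nx.Graph:
    """Read a GraphML graph written by :func:`write_graph`."""
    g = nx.read_graphml(path)
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
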