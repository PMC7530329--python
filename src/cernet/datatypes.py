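"""Core in-memory containers shared across pipeline stages.

The pipeline works on log2-scale expression values in a paired tumor/normal
design: every sample belongs to exactly one patient pair, and every pair
contributes one tumor and one normal sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
LNCRNA = "lncRNA"
MRNA = "mRNA"
CODING = "coding"

GENE_CLASSES = (LNCRNA, MRNA)
TRANSCRIPT_CLASSES = (CODING, LNCRNA)


@dataclass
class ExpressionMatrix:
    """Transcripts-by-samples abundance table with a paired two-class design.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id, one column per sample, log2 scale.
    design
        DataFrame indexed by sample id with columns ``condition``
        (``tumor``/``normal``) and ``pair`` (patient-pair id).
    classes
        Optional Series mapping transcript id to its class
        (``lncRNA``/``mRNA``); required by stages that split by class.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = {"condition", "pair"} - set(self.design.columns)
        if missing:
            raise ValueError(f"design is missing columns: {sorted(missing)}")
        unknown = set(self.design["condition"]) - {TUMOR, NORMAL}
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        extra = set(self.values.columns) ^ set(self.design.index)
        if extra:
            raise ValueError(
                f"samples in matrix and design disagree: {sorted(extra)}"
            )
        for pair_id, grp in self.design.groupby("pair"):
            conds = sorted(grp["condition"])
            if conds != [NORMAL, TUMOR]:
                raise ValueError(
                    f"pair {pair_id!r} must contain exactly one tumor and one "
                    f"normal sample, got {conds}"
                )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate transcript ids: {list(dups)[:5]}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression values must be numeric")

    @property
    def n_pairs(self) -> int:
        return self.design["pair"].nunique()

    def paired_samples(self) -> list[tuple[str, str, str]]:
        """Return (pair_id, tumor_sample, normal_sample), sorted by pair id."""
        out = []
        for pair_id, grp in self.design.groupby("pair", sort=True):
            tum = grp.index[grp["condition"] == TUMOR][0]
            norm = grp.index[grp["condition"] == NORMAL][0]
            out.append((pair_id, tum, norm))
        return out

    def paired_differences(self) -> pd.DataFrame:
        """Tumor-minus-normal differences, one column per patient pair."""
        pairs = self.paired_samples()
        cols = {}
        for pair_id, tum, norm in pairs:
            cols[pair_id] = self.values[tum] - self.values[norm]
        return pd.DataFrame(cols, index=self.values.index)

    def swap_labels(self) -> "ExpressionMatrix":
        """Return a copy with tumor/normal labels exchanged (for symmetry checks)."""
        design = self.design.copy()
        design["condition"] = design["condition"].map({TUMOR: NORMAL, NORMAL: TUMOR})
        return ExpressionMatrix(self.values.copy(), design, self.classes)


@dataclass
class InteractionTable:
    """Bipartite miRNA-target edge list for one RNA class.

    ``edges`` holds columns ``gene_id`` and ``mirna_id``; duplicate rows are
    collapsed, empty ids and gene==miRNA self-pairs rejected.
    """

    edges: pd.DataFrame
    gene_class: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene_class must be one of {GENE_CLASSES}, got {self.gene_class!r}"
            )
        missing = {"gene_id", "mirna_id"} - set(self.edges.columns)
        if missing:
            raise ValueError(f"interaction table missing columns: {sorted(missing)}")
        edges = self.edges.loc[:, ["gene_id", "mirna_id"]].astype(str)
        if (edges["gene_id"] == "").any() or (edges["mirna_id"] == "").any():
            raise ValueError("interaction table contains empty ids")
        if (edges["gene_id"] == edges["mirna_id"]).any():
            raise ValueError("interaction table contains self-pairs")
        self.edges = edges.drop_duplicates(ignore_index=True)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene_id"])

    @property
    def mirnas(self) -> set[str]:
        return set(self.edges["mirna_id"])

    def partners(self) -> dict[str, frozenset[str]]:
        """Map each gene to its set of miRNA partners."""
        return {
            g: frozenset(sub["mirna_id"])
            for g, sub in self.edges.groupby("gene_id", sort=True)
        }


@dataclass
class TripleNetwork:
    """Tripartite lncRNA-miRNA-mRNA graph stored as two bipartite edge layers."""

    lnc_mi: dict[str, frozenset[str]] = field(default_factory=dict)
    mrna_mi: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # drop genes left without partners so node sets stay edge-derived
        self.lnc_mi = {g: fs for g, fs in self.lnc_mi.items() if fs}
        self.mrna_mi = {g: fs for g, fs in self.mrna_mi.items() if fs}
        collisions = set(self.lnc_mi) & set(self.mrna_mi)
        if collisions:
            raise ValueError(
                f"ids appear as both lncRNA and mRNA: {sorted(collisions)[:5]}"
            )
        mirnas = self.mirna_nodes
        gene_overlap = (set(self.lnc_mi) | set(self.mrna_mi)) & mirnas
        if gene_overlap:
            raise ValueError(
                f"ids appear as both gene and miRNA: {sorted(gene_overlap)[:5]}"
            )

    @property
    def lnc_nodes(self) -> set[str]:
        return set(self.lnc_mi)

    @property
    def mrna_nodes(self) -> set[str]:
        return set(self.mrna_mi)

    @property
    def mirna_nodes(self) -> set[str]:
        out: set[str] = set()
        for fs in self.lnc_mi.values():
            out |= fs
        for fs in self.mrna_mi.values():
            out |= fs
        return out

    @property
    def n_lnc_mi_edges(self) -> int:
        return sum(len(fs) for fs in self.lnc_mi.values())

    @property
    def n_mrna_mi_edges(self) -> int:
        return sum(len(fs) for fs in self.mrna_mi.values())

    def summary(self) -> dict[str, int]:
        return {
            "n_lnc": len(self.lnc_mi),
            "n_mrna": len(self.mrna_mi),
            "n_mirna": len(self.mirna_nodes),
            "n_lnc_mi_edges": self.n_lnc_mi_edges,
            "n_mrna_mi_edges": self.n_mrna_mi_edges,
        }
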