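"""Probe-to-transcript filtering and probe-level expression collapse.

Microarray probes are re-annotated against transcript sequences and kept only
when the alignment is unambiguous.  Three criteria are applied in order to
the perfect-match hits (match length equal to the probe length, 100%
identity):

1. probes matching both a protein-coding and a lncRNA transcript are removed;
2. within each class, probes matching more than one transcript are removed;
3. only transcripts supported by more than three surviving probes are kept.

Expression of a kept transcript is the per-sample median of its probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .datatypes import CODING, LNCRNA, TRANSCRIPT_CLASSES, ExpressionMatrix

MIN_SUPPORT = 4  # "more than three probes"


@dataclass(frozen=True)
class ProbeHit:
    """One BLAST-style alignment between a probe and a transcript."""

    probe_id: str
    transcript_id: str
    transcript_class: str
    match_length: int
    identity_pct: float


@dataclass
class ProbeAnnotation:
    """Final one-to-one probe → transcript mapping after filtering.

    Only probes whose transcript passed the support criterion appear in
    ``mapping``; ``transcripts_kept`` holds the transcripts with >= 4
    supporting probes.
    """

    mapping: dict[str, tuple[str, str]]
    transcripts_kept: frozenset[str]

    def transcript_probes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.transcripts_kept}
        for probe, (transcript, _cls) in self.mapping.items():
            out[transcript].add(probe)
        return out

    def transcript_classes(self) -> pd.Series:
        pairs = sorted({(t, c) for (t, c) in self.mapping.values()})
        return pd.Series(
            {t: c for t, c in pairs}, name="class", dtype=object
        )


def _as_frame(hits: Iterable[ProbeHit] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
    else:
        df = pd.DataFrame([h.__dict__ for h in hits])
    if df.empty:
        raise ValueError("hit table is empty")
    required = {
        "probe_id",
        "transcript_id",
        "transcript_class",
        "match_length",
        "identity_pct",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df


def filter_hits(
    hits: Iterable[ProbeHit] | pd.DataFrame, perfect_match_length: int = 60
) -> ProbeAnnotation:
    """Apply the three filtering criteria and return the final annotation.

    Raises ``ValueError`` on an empty hit list, on an unknown transcript
    class, or when one transcript id is annotated with both classes.
    """
    df = _as_frame(hits)
    if df.empty:
        raise ValueError("hit table is empty")
    unknown = set(df["transcript_class"]) - set(TRANSCRIPT_CLASSES)
    if unknown:
        raise ValueError(
            f"unknown transcript_class values: {sorted(unknown)}; "
            f"expected one of {TRANSCRIPT_CLASSES}"
        )
    both = (
        df.groupby("transcript_id")["transcript_class"].nunique().pipe(lambda s: s[s > 1])
    )
    if len(both):
        raise ValueError(
            f"transcripts annotated with both classes: {sorted(both.index)[:5]}"
        )

    # perfect-match hits only
    perfect = df[
        (df["match_length"] == perfect_match_length) & (df["identity_pct"] == 100.0)
    ].drop_duplicates(["probe_id", "transcript_id"])

    # (1) drop probes hitting both classes
    n_classes = perfect.groupby("probe_id")["transcript_class"].nunique()
    cross = set(n_classes[n_classes > 1].index)
    perfect = perfect[~perfect["probe_id"].isin(cross)]

    # (2) within each class, drop probes hitting more than one transcript
    n_targets = perfect.groupby("probe_id")["transcript_id"].nunique()
    multi = set(n_targets[n_targets > 1].index)
    unique_hits = perfect[~perfect["probe_id"].isin(multi)]

    # (3) keep transcripts with more than three supporting probes
    support = unique_hits.groupby("transcript_id")["probe_id"].nunique()
    kept_transcripts = frozenset(support[support >= MIN_SUPPORT].index)
    final = unique_hits[unique_hits["transcript_id"].isin(kept_transcripts)]

    mapping = {
        row.probe_id: (row.transcript_id, row.transcript_class)
        for row in final.itertuples(index=False)
    }
    return ProbeAnnotation(mapping, kept_transcripts)


def collapse_to_transcripts(
    probe_matrix: ExpressionMatrix, annotation: ProbeAnnotation
) -> ExpressionMatrix:
    """Collapse probe-level expression to transcript level (per-sample median)."""
    if not annotation.mapping:
        empty = probe_matrix.values.iloc[0:0]
        return ExpressionMatrix(empty, probe_matrix.design, pd.Series(dtype=object))
    probes = pd.Index(annotation.mapping.keys())
    missing = probes.difference(probe_matrix.values.index)
    if len(missing):
        raise ValueError(
            f"annotated probes absent from probe matrix: {sorted(missing)[:5]}"
        )
    sub = probe_matrix.values.loc[probes]
    transcript_of = pd.Series(
        {p: t for p, (t, _c) in annotation.mapping.items()}, name="transcript"
    )
    collapsed = sub.groupby(transcript_of).median()
    collapsed = collapsed.sort_index()
    classes = annotation.transcript_classes().reindex(collapsed.index)
    return ExpressionMatrix(collapsed, probe_matrix.design, classes)


BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_blast_hits(path, class_table: pd.Series | dict) -> pd.DataFrame:
    """Read BLAST outfmt-6 rows and attach transcript classes.

    ``class_table`` maps transcript id (sseqid) to ``coding`` or ``lncRNA``;
    transcripts missing a class raise a ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    classes = pd.Series(class_table)
    unknown = set(df["sseqid"]) - set(classes.index)
    if unknown:
        raise ValueError(f"transcripts without a class label: {sorted(unknown)[:5]}")
    return pd.DataFrame(
        {
            "probe_id": df["qseqid"].astype(str),
            "transcript_id": df["sseqid"].astype(str),
            "transcript_class": df["sseqid"].map(classes),
            "match_length": df["length"].astype(int),
            "identity_pct": df["pident"].astype(float),
        }
    )
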