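"""Readers and writers for every on-disk format the pipeline touches.

Validating parsers for FASTA genomes, BED3+/narrowPeak peak and read
intervals, BED12 gene models, BED4 repeat annotation, two/three-column
mapping tables and OBO ontology subsets, plus a uniform TSV writer.
Parsers reject malformed records with line-numbered errors rather than
silently coercing them.  GTF-style 1-based closed inputs are not
accepted; gene models arrive as BED12, already 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "FormatError",
    "SequenceRecord",
    "AnnotationTable",
    "OboTerm",
    "Ontology",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gene_models_bed12",
    "read_repeats_bed4",
    "read_mapping_table",
    "read_obo_subset",
    "write_table",
]

_DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file (message names the offending line)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("empty sequence name")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.name}")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in {self.name}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects.

    Order is preserved, lowercase is normalized to uppercase, duplicate
    header names and characters outside {A, C, G, T, N} are format
    errors naming the line.
    """
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()
    header_line = 0

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {name!r} has no sequence")
        records.append(SequenceRecord(name, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate header {name!r}")
                seen.add(name)
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                seq = line.strip().upper()
                bad = set(seq) - _DNA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal characters {sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_bed(path: str | Path, min_cols: int = 3) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak intervals (0-based half-open, as stored).

    Column 6 is taken as strand when present and valid; all columns
    beyond the first three are preserved verbatim in ``attrs``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < max(3, min_cols):
                raise FormatError(
                    f"{path}:{lineno}: expected >= {max(3, min_cols)} columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            out.append(
                GenomicInterval(cols[0], start, end, strand, attrs=tuple(cols[3:]))
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, re-emitting any preserved extra columns."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), *iv.attrs]
            fh.write("\t".join(cols) + "\n")


@dataclass
class AnnotationTable:
    """Gene models plus repeat annotation, as plain DataFrames.

    ``transcripts``: transcript_id, gene_id, chrom, start, end, strand,
    cds_start, cds_end.  ``exons``/``utr5``/``utr3``: transcript_id,
    chrom, start, end.  ``repeats``: chrom, start, end, repeat_class.
    """

    transcripts: pd.DataFrame
    exons: pd.DataFrame
    utr5: pd.DataFrame = field(default_factory=lambda: _empty_feature_frame())
    utr3: pd.DataFrame = field(default_factory=lambda: _empty_feature_frame())
    repeats: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "repeat_class"]
        )
    )

    def __post_init__(self) -> None:
        self._strand = dict(
            zip(self.transcripts["transcript_id"], self.transcripts["strand"])
        )
        self.validate()

    def transcript_strand(self, transcript_id: str) -> str:
        return self._strand[transcript_id]

    def validate(self) -> None:
        tx = self.transcripts
        if tx["transcript_id"].duplicated().any():
            dup = tx.loc[tx["transcript_id"].duplicated(), "transcript_id"].iloc[0]
            raise FormatError(f"duplicate transcript_id {dup!r}")
        spans = tx.set_index("transcript_id")[["chrom", "start", "end"]]
        for row in self.exons.itertuples(index=False):
            if row.transcript_id not in spans.index:
                raise FormatError(f"exon references unknown transcript {row.transcript_id!r}")
            span = spans.loc[row.transcript_id]
            if row.chrom != span["chrom"] or row.start < span["start"] or row.end > span["end"]:
                raise FormatError(
                    f"exon {row.chrom}:{row.start}-{row.end} outside transcript "
                    f"{row.transcript_id}"
                )

    def gene_ids(self) -> list[str]:
        return sorted(self.transcripts["gene_id"].unique())


def _empty_feature_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["transcript_id", "chrom", "start", "end"])


def read_gene_models_bed12(
    path: str | Path, tx2gene: Mapping[str, str] | None = None
) -> AnnotationTable:
    """Read BED12 gene models into an :class:`AnnotationTable`.

    Exons come from the block columns; 5'/3' UTRs are the exonic bases
    outside the thickStart/thickEnd CDS span, oriented by strand.  When
    ``tx2gene`` is absent each transcript becomes its own gene.
    """
    tx_rows, exon_rows, utr5_rows, utr3_rows = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, name, strand = cols[0], cols[3], cols[5]
            try:
                start, end = int(cols[1]), int(cols[2])
                thick_start, thick_end = int(cols[6]), int(cols[7])
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED12 field") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: transcript {name!r} lacks strand")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            gene = tx2gene[name] if tx2gene is not None else name
            tx_rows.append((name, gene, chrom, start, end, strand, thick_start, thick_end))
            for size, off in zip(sizes, offsets):
                es, ee = start + off, start + off + size
                if ee > end:
                    raise FormatError(f"{path}:{lineno}: exon outside transcript span")
                exon_rows.append((name, chrom, es, ee))
                left = (es, min(ee, thick_start))
                right = (max(es, thick_end), ee)
                for lo, hi in (left, right):
                    if lo >= hi:
                        continue
                    five_prime = (hi <= thick_start) == (strand == "+")
                    (utr5_rows if five_prime else utr3_rows).append((name, chrom, lo, hi))
    cols5 = ["transcript_id", "chrom", "start", "end"]
    return AnnotationTable(
        transcripts=pd.DataFrame(
            tx_rows,
            columns=[
                "transcript_id", "gene_id", "chrom", "start", "end",
                "strand", "cds_start", "cds_end",
            ],
        ),
        exons=pd.DataFrame(exon_rows, columns=cols5),
        utr5=pd.DataFrame(utr5_rows, columns=cols5) if utr5_rows else _empty_feature_frame(),
        utr3=pd.DataFrame(utr3_rows, columns=cols5) if utr3_rows else _empty_feature_frame(),
    )


def read_repeats_bed4(path: str | Path) -> pd.DataFrame:
    """Read BED4 repeat annotation; column 4 is the repeat class label."""
    ivs = read_bed(path, min_cols=4)
    rows = [(iv.chrom, iv.start, iv.end, iv.attrs[0]) for iv in ivs]
    for chrom, start, end, cls in rows:
        if not cls:
            raise FormatError(f"{path}: repeat at {chrom}:{start}-{end} has empty class")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])


def read_mapping_table(
    path: str | Path, columns: Sequence[str]
) -> pd.DataFrame:
    """Read a headered TSV association table (e.g. transcript -> KO).

    Duplicate rows are collapsed; many-to-many associations are allowed;
    empty keys are format errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[list(columns)]
    if df.isna().any().any() or (df == "").any().any():
        raise FormatError(f"{path}: empty key in mapping table")
    return df.drop_duplicates().reset_index(drop=True)


@dataclass(frozen=True)
class OboTerm:
    term_id: str
    name: str
    namespace: str
    parents: tuple  # direct is_a parents


@dataclass
class Ontology:
    """A DAG of ontology terms over is_a edges (obsolete terms excluded)."""

    terms: dict[str, OboTerm]
    _anc_cache: dict = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def ancestors(self, term_id: str) -> frozenset:
        """All is_a ancestors of a term (excluding the term itself)."""
        if term_id in self._anc_cache:
            return self._anc_cache[term_id]
        out: set[str] = set()
        stack = [p for p in self.terms[term_id].parents if p in self.terms]
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(q for q in self.terms[p].parents if q in self.terms)
        result = frozenset(out)
        self._anc_cache[term_id] = result
        return result


def read_obo_subset(path: str | Path) -> Ontology:
    """Read an OBO [Term] subset into an :class:`Ontology`.

    Obsolete terms are excluded; a cycle in the is_a graph (including a
    self-referential is_a) is a format error.
    """
    graph = obonet.read_obo(path)  # drops obsolete terms by default
    dag = nx.DiGraph()
    terms: dict[str, OboTerm] = {}
    for node, data in graph.nodes(data=True):
        parents = tuple(sorted(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        ))
        terms[node] = OboTerm(
            term_id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            parents=parents,
        )
        dag.add_node(node)
        for p in parents:
            dag.add_edge(node, p)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise FormatError(f"{path}: cycle in is_a graph involving {cycle[0][0]}")
    return Ontology(terms=terms)


def write_table(df: pd.DataFrame, path: str | Path, float_digits: int = 6) -> None:
    """Write a DataFrame as deterministic TSV.

    Header always present; floats rendered with ``float_digits``
    significant digits; NaN rendered as ``NA``; rows written in the
    order given, so identical input produces byte-identical output.
    """
    out = df.copy()
    fmt = f"%.{float_digits}g"
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=fmt)
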