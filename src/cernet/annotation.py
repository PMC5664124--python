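"""Transcript models, genomic interval arithmetic and GTF round-tripping.

Coordinates are 1-based inclusive throughout (GTF convention); two
intervals overlap iff they share at least one base.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "TranscriptModel",
    "AnnotationSet",
    "interval_overlap",
    "exonic_overlap_bp",
    "read_gtf",
    "write_gtf",
]

Interval = tuple[int, int]


def interval_overlap(a: Interval, b: Interval) -> int:
    """Number of shared bases between two 1-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on a genome.

    ``exons`` are 1-based inclusive (start, end) pairs, sorted by start and
    non-overlapping. ``biotype`` separates reference coding transcripts from
    assembled lncRNA candidates. ``orf`` optionally records the open reading
    frame on the *spliced* transcript (1-based inclusive, stop codon
    included); the synthetic generator uses it to build coding sequences and
    to reserve 3'UTR space for miRNA sites.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = "candidate"
    orf: Interval | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = e
        if self.biotype not in ("coding_reference", "candidate"):
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return replace(self, biotype=biotype)


def exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total exon-vs-exon shared bases between two transcripts (any strand)."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += interval_overlap(ea, eb)
    return total


@dataclass
class AnnotationSet:
    """Reference coding transcripts plus candidate transcripts.

    Derived views: per-gene genomic spans and per-transcript intron
    intervals of the reference, used by the overlap filter and by the
    intergenic/intronic/antisense classifier.
    """

    reference: list[TranscriptModel] = field(default_factory=list)
    candidates: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        ids = [t.transcript_id for t in self.reference] + [
            t.transcript_id for t in self.candidates
        ]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript ids: {dup}")

    @property
    def gene_spans(self) -> dict[str, tuple[str, Interval]]:
        """gene_id -> (chrom, [min start, max end] over the gene's transcripts)."""
        spans: dict[str, tuple[str, Interval]] = {}
        for t in self.reference:
            s, e = t.span
            if t.gene_id in spans:
                chrom, (s0, e0) = spans[t.gene_id]
                spans[t.gene_id] = (chrom, (min(s0, s), max(e0, e)))
            else:
                spans[t.gene_id] = (t.chrom, (s, e))
        return spans

    def all_transcripts(self) -> list[TranscriptModel]:
        return list(self.reference) + list(self.candidates)


# -- GTF I/O -----------------------------------------------------------------


def write_gtf(models: Iterable[TranscriptModel], path, source: str = "cernet") -> None:
    """Write transcript + exon rows with ensembl-dialect attributes."""
    with open(path, "w") as fh:
        for t in models:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            s, e = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for es, ee in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{es}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[TranscriptModel]:
    """Parse a GTF into transcript models (gffutils, in-memory db).

    Exon rows are grouped by ``transcript_id``; ``transcript_biotype``
    defaults to ``candidate`` when absent.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        rec = grouped.setdefault(
            tid,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": feat.attributes.get("transcript_biotype", ["candidate"])[0],
                "exons": [],
            },
        )
        rec["exons"].append((feat.start, feat.end))
    models = []
    for tid, rec in grouped.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                biotype=rec["biotype"],
            )
        )
    return models
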