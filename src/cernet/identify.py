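"""lncRNA identification cascade and genomic classification.

Assembled candidate transcripts are filtered in four stages:

1. same-strand exonic overlap with reference coding transcripts,
2. expression (maximum FPKM over libraries below 1),
3. structure (spliced length < 200 nt or fewer than 2 exons),
4. coding potential (consensus of one or more predictors; a candidate is
   kept only when *every* predictor calls it noncoding).

Each stage is a pure predicate, so the surviving set does not depend on
stage order; only the attribution of a rejection to a stage does.
Survivors are classified as antisense, intronic, sense or intergenic
relative to the reference annotation, with precedence
antisense > intronic > sense > intergenic (cuffcompare-style priority).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotation import AnnotationSet, TranscriptModel, interval_overlap
from .expression import ExpressionMatrix

__all__ = [
    "CodingPotentialVerdict",
    "FilterReport",
    "longest_orf",
    "heuristic_coding_potential",
    "coding_potential_consensus",
    "filter_structural",
    "filter_expression",
    "remove_coding_overlap",
    "classify_lncrna",
    "run_identification_pipeline",
    "load_external_verdicts",
]

STAGES = ("coding_overlap", "expression", "structural", "coding_potential")

_STOPS = ("TAA", "TAG", "TGA")
_TO_DNA = str.maketrans("Uu", "Tt")


@dataclass(frozen=True)
class CodingPotentialVerdict:
    predictor: str
    call: str  # "coding" | "noncoding"
    score: float

    def __post_init__(self):
        if self.call not in ("coding", "noncoding"):
            raise ValueError(f"call must be coding/noncoding, got {self.call!r}")


def longest_orf(sequence: str) -> int:
    """Length (nt, stop codon included) of the longest forward-strand ORF.

    An ORF runs ATG -> first in-frame stop; a trailing ATG with no stop
    does not count. All three forward frames are scanned.
    """
    seq = sequence.upper().translate(_TO_DNA)
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def heuristic_coding_potential(
    sequence: str,
    orf_fraction_threshold: float = 0.3,
    min_orf_nt: int = 300,
    name: str = "orf_fraction",
) -> CodingPotentialVerdict:
    """Built-in ORF-fraction coding-potential predictor.

    Score = longest ORF length / sequence length. The sequence is called
    coding when the score reaches ``orf_fraction_threshold`` or the
    longest ORF reaches ``min_orf_nt`` (the classical 100-codon rule).
    """
    seq = sequence.upper().translate(_TO_DNA)
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    orf = longest_orf(seq)
    score = orf / len(seq) if seq else 0.0
    call = "coding" if (score >= orf_fraction_threshold or orf >= min_orf_nt) else "noncoding"
    return CodingPotentialVerdict(name, call, score)


def coding_potential_consensus(verdicts: Sequence[CodingPotentialVerdict]) -> bool:
    """Keep (True) iff every predictor calls the transcript noncoding."""
    if not verdicts:
        raise ValueError("consensus needs at least one verdict")
    return all(v.call == "noncoding" for v in verdicts)


# -- stage predicates --------------------------------------------------------
# Each returns {transcript_id: None (pass) | rejection reason}.


def filter_structural(
    candidates: Iterable[TranscriptModel],
    min_length: int = 200,
    min_exons: int = 2,
) -> dict[str, str | None]:
    """Reject transcripts shorter than ``min_length`` nt (spliced) or with
    fewer than ``min_exons`` exons; both bounds are inclusive keeps."""
    out: dict[str, str | None] = {}
    for t in candidates:
        if t.spliced_length < min_length:
            out[t.transcript_id] = "length"
        elif t.n_exons < min_exons:
            out[t.transcript_id] = "exon_count"
        else:
            out[t.transcript_id] = None
    return out


def filter_expression(
    candidates: Iterable[TranscriptModel],
    expr: ExpressionMatrix,
    min_fpkm: float = 1.0,
    strict: bool = False,
) -> dict[str, str | None]:
    """Keep transcripts whose maximum FPKM over all libraries reaches
    ``min_fpkm`` (``strict=True`` demands a strict inequality)."""
    out: dict[str, str | None] = {}
    for t in candidates:
        if t.transcript_id not in expr.data.index:
            raise KeyError(f"candidate {t.transcript_id} missing from expression matrix")
        mx = float(expr.data.loc[t.transcript_id].max())
        ok = mx > min_fpkm if strict else mx >= min_fpkm
        out[t.transcript_id] = None if ok else "low_expression"
    return out


def remove_coding_overlap(
    candidates: Iterable[TranscriptModel],
    reference: AnnotationSet,
) -> dict[str, str | None]:
    """Reject candidates with >= 1 bp exonic overlap with a reference coding
    exon on the same strand; opposite-strand overlap is retained."""
    out: dict[str, str | None] = {}
    for t in candidates:
        hit = False
        for ref in reference.reference:
            if ref.chrom != t.chrom or ref.strand != t.strand:
                continue
            if _exon_overlap(t, ref):
                hit = True
                break
        out[t.transcript_id] = "coding_overlap" if hit else None
    return out


def _exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for ea in a.exons:
        for eb in b.exons:
            if interval_overlap(ea, eb) > 0:
                return True
    return False


def classify_lncrna(survivor: TranscriptModel, reference: AnnotationSet) -> str:
    """Positional class of a surviving lncRNA relative to coding genes.

    Precedence: antisense (opposite-strand exonic overlap) > intronic
    (span inside one intron of a reference transcript, either strand) >
    sense (same-strand exonic overlap) > intergenic.
    """
    same_chrom = [r for r in reference.reference if r.chrom == survivor.chrom]
    for r in same_chrom:
        if r.strand != survivor.strand and _exon_overlap(survivor, r):
            return "antisense"
    s, e = survivor.span
    for r in same_chrom:
        for istart, iend in r.introns:
            if istart <= s and e <= iend:
                return "intronic"
    for r in same_chrom:
        if r.strand == survivor.strand and _exon_overlap(survivor, r):
            return "sense"
    return "intergenic"


@dataclass
class FilterReport:
    """Outcome of the identification cascade.

    ``failures`` maps each rejected transcript to (stage, reason) of its
    *first* failing stage; ``survivors`` passed every stage and carry a
    class label in ``classes``. ``stage_counts`` records how many
    candidates remained after each stage.
    """

    order: tuple[str, ...]
    failures: dict[str, tuple[str, str]] = field(default_factory=dict)
    survivors: tuple[str, ...] = ()
    classes: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def stage_failed(self, transcript_id: str) -> str | None:
        rec = self.failures.get(transcript_id)
        return rec[0] if rec else None

    def reason(self, transcript_id: str) -> str | None:
        rec = self.failures.get(transcript_id)
        return rec[1] if rec else None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tid, (stage, reason) in self.failures.items():
            rows.append({"transcript_id": tid, "status": stage, "reason": reason, "class": ""})
        for tid in self.survivors:
            rows.append(
                {
                    "transcript_id": tid,
                    "status": "passed",
                    "reason": "",
                    "class": self.classes[tid],
                }
            )
        return pd.DataFrame(rows, columns=["transcript_id", "status", "reason", "class"])


def load_external_verdicts(path, predictor: str = "external") -> dict[str, CodingPotentialVerdict]:
    """Read a TSV of (transcript_id, call[, score]) from an external
    coding-potential tool run (e.g. CPC/CNCI/PLEK exports)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    out = {}
    for _, row in df.iterrows():
        score = float(row[cols["score"]]) if "score" in cols else 0.0
        out[str(row[cols["transcript_id"]])] = CodingPotentialVerdict(
            predictor, str(row[cols["call"]]), score
        )
    return out


def run_identification_pipeline(
    candidates: Sequence[TranscriptModel],
    reference: AnnotationSet,
    sequences: Mapping[str, str],
    expr: ExpressionMatrix,
    min_length: int = 200,
    min_exons: int = 2,
    min_fpkm: float = 1.0,
    strict_fpkm: bool = False,
    predictors: Sequence[Callable[[str], CodingPotentialVerdict]] | None = None,
    external_verdicts: Sequence[Mapping[str, CodingPotentialVerdict]] = (),
) -> FilterReport:
    """Run the full cascade: overlap -> expression -> structure -> coding
    potential -> classification.

    ``predictors`` are callables sequence -> verdict (default: the built-in
    ORF-fraction heuristic); ``external_verdicts`` are per-transcript
    verdict tables from external tools, combined into the same consensus.
    """
    if predictors is None:
        predictors = (heuristic_coding_potential,)
    report = FilterReport(order=STAGES)
    remaining = list(candidates)

    def apply(stage: str, outcome: dict[str, str | None]):
        nonlocal remaining
        kept = []
        for t in remaining:
            reason = outcome[t.transcript_id]
            if reason is None:
                kept.append(t)
            else:
                report.failures[t.transcript_id] = (stage, reason)
        remaining = kept
        report.stage_counts[stage] = len(remaining)

    apply("coding_overlap", remove_coding_overlap(remaining, reference))
    apply("expression", filter_expression(remaining, expr, min_fpkm, strict_fpkm))
    apply("structural", filter_structural(remaining, min_length, min_exons))

    cp_outcome: dict[str, str | None] = {}
    for t in remaining:
        tid = t.transcript_id
        if tid not in sequences:
            raise KeyError(f"no sequence for candidate {tid}")
        verdicts = [p(sequences[tid]) for p in predictors]
        for table in external_verdicts:
            if tid in table:
                verdicts.append(table[tid])
        cp_outcome[tid] = None if coding_potential_consensus(verdicts) else "coding_potential"
    apply("coding_potential", cp_outcome)

    report.survivors = tuple(t.transcript_id for t in remaining)
    for t in remaining:
        report.classes[t.transcript_id] = classify_lncrna(t, reference)
    return report
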