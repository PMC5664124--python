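"""Seeded synthetic fixtures for the whole pipeline.

The generator emulates the downstream products of a 2-tissue (embryo,
endosperm) x 3-stage (9/15/20 DAP) maize seed RNA-seq study: reference
coding-gene models and candidate transcripts on one synthetic
chromosome, spliced-transcript sequences with planted miRNA recognition
elements (MREs), a set of mature miRNA sequences (158 by default, the
size of the known Zea mays miRNA complement used for screening), and
coupled FPKM expression profiles in which planted ceRNA triplets show
positive lncRNA-mRNA and negative miRNA-partner correlation.

Every quantity is drawn from a seeded generator; the same configuration
and seed reproduce the fixture byte for byte. Ground truth (which
candidates are real lncRNAs, which are engineered decoys, where MREs
were planted, which triplets are coupled) travels alongside in a
:class:`TruthBundle` so recovery can be scored exactly.

Candidate decoys each violate exactly one identification filter:
``too_short`` (< 200 nt), ``mono_exonic`` (1 exon), ``same_strand_overlap``
(exonic overlap with a coding gene on the same strand), ``low_fpkm``
(maximum FPKM < 1) and ``coding_like`` (a long ORF that trips the
coding-potential consensus).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationSet, TranscriptModel, write_gtf
from .expression import ExpressionMatrix, sample_name
from .identify import longest_orf
from .targeting import score_duplex

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "PlantedMRE",
    "PlantedTriplet",
    "FixtureBundle",
    "SizingError",
    "generate_annotation",
    "generate_sequences",
    "generate_mirnas",
    "plant_mres",
    "simulate_expression",
    "simulate_bundle",
    "write_fixture",
    "simulate_de_dataset",
]

TISSUES = ("embryo", "endosperm")
STAGES = (9, 15, 20)
DEFAULT_DESIGN = tuple((t, s, 3) for t in TISSUES for s in STAGES)
DECOY_KINDS = ("too_short", "mono_exonic", "same_strand_overlap", "low_fpkm", "coding_like")
# decoy kind -> (pipeline stage, rejection reason) it is engineered to fail
DECOY_REASON = {
    "too_short": "length",
    "mono_exonic": "exon_count",
    "same_strand_overlap": "coding_overlap",
    "low_fpkm": "low_expression",
    "coding_like": "coding_potential",
}

CHROM = "chrS1"
_STOP_CODONS = ("TAA", "TAG", "TGA")
_MRE_SLOT = 64  # genomic spacing reserved per planted site (>= 24 nt window + gap)


class SizingError(ValueError):
    """Requested feature counts do not fit the available genome space."""


class DesignError(ValueError):
    """The sample design cannot support the requested simulation."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    ``noise_sd`` is the replicate standard deviation on the log2-FPKM
    scale; ``coupling_strength`` is the slope of the miRNA-driven
    repression applied to both members of a planted triplet (log2 units
    per unit of the miRNA's monotone developmental profile).
    """

    seed: int = 1
    n_coding_genes: int = 30
    n_intergenic: int = 6
    n_intronic: int = 2
    n_antisense: int = 2
    n_decoys: Mapping[str, int] = field(
        default_factory=lambda: {k: 1 for k in DECOY_KINDS}
    )
    n_mirnas: int = 158
    mirna_length_range: tuple[int, int] = (18, 24)
    n_planted_triplets: int = 10
    mirnas_per_triplet: int = 2
    design: tuple[tuple[str, int, int], ...] = DEFAULT_DESIGN
    noise_sd: float = 0.25
    coupling_strength: float = 1.5
    gc_fraction: float = 0.5
    genome_length: int | None = None

    @property
    def n_true_lncrnas(self) -> int:
        return self.n_intergenic + self.n_intronic + self.n_antisense

    def validate(self) -> None:
        counts = dict(
            n_coding_genes=self.n_coding_genes,
            n_intergenic=self.n_intergenic,
            n_intronic=self.n_intronic,
            n_antisense=self.n_antisense,
            n_mirnas=self.n_mirnas,
            n_planted_triplets=self.n_planted_triplets,
            mirnas_per_triplet=self.mirnas_per_triplet,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for kind, v in self.n_decoys.items():
            if kind not in DECOY_KINDS:
                raise ValueError(f"unknown decoy kind {kind!r}")
            if v < 0:
                raise ValueError(f"n_decoys[{kind!r}] must be >= 0")
        lo, hi = self.mirna_length_range
        if not (18 <= lo <= hi <= 24):
            raise ValueError("mirna_length_range must lie within [18, 24]")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.n_planted_triplets > min(self.n_true_lncrnas, self.n_coding_genes):
            raise ValueError(
                "n_planted_triplets exceeds available lncRNAs or coding genes"
            )
        if self.n_planted_triplets * self.mirnas_per_triplet > self.n_mirnas:
            raise ValueError("not enough miRNAs for the requested triplets")
        if self.n_intronic > self.n_coding_genes:
            raise SizingError("each intronic lncRNA needs its own host gene")
        if self.n_antisense + self.n_decoys.get("same_strand_overlap", 0) > max(
            0, self.n_coding_genes - self.n_intronic
        ):
            raise SizingError("not enough non-host genes for overlap candidates")
        if not self.design:
            raise DesignError("empty sample design")
        for tissue, stage, reps in self.design:
            if reps < 2:
                raise DesignError(
                    f"degenerate design: {tissue} {stage}DAP has {reps} replicate(s); >= 2 required"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = tuple((t, int(s), int(r)) for t, s, r in d["design"])
        if "mirna_length_range" in d:
            d["mirna_length_range"] = tuple(d["mirna_length_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PlantedMRE:
    mirna_id: str
    transcript_id: str
    position: int  # 1-based on the spliced transcript
    planned_penalty: float = 0.0
    realized_penalty: float | None = None


@dataclass(frozen=True)
class PlantedTriplet:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]


@dataclass
class TruthBundle:
    """Ground truth of one fixture: labels, planted sites, planted triplets."""

    true_lncrna_ids: dict[str, str] = field(default_factory=dict)  # id -> class
    decoy_ids: dict[str, str] = field(default_factory=dict)  # id -> rejection reason
    planted_mres: list[PlantedMRE] = field(default_factory=list)
    planted_triplets: list[PlantedTriplet] = field(default_factory=list)
    mrna_ids: tuple[str, ...] = ()
    candidate_ids: tuple[str, ...] = ()
    mirna_ids: tuple[str, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        d = json.loads(text)
        return cls(
            true_lncrna_ids=dict(d["true_lncrna_ids"]),
            decoy_ids=dict(d["decoy_ids"]),
            planted_mres=[PlantedMRE(**m) for m in d["planted_mres"]],
            planted_triplets=[
                PlantedTriplet(t["lncrna_id"], t["mrna_id"], tuple(t["shared_mirnas"]))
                for t in d["planted_triplets"]
            ],
            mrna_ids=tuple(d["mrna_ids"]),
            candidate_ids=tuple(d["candidate_ids"]),
            mirna_ids=tuple(d["mirna_ids"]),
        )


def _split_length(rng, total: int, parts: int, min_len: int) -> list[int]:
    """Deterministically split ``total`` into ``parts`` pieces, each >= min_len."""
    if parts * min_len > total:
        raise SizingError(f"cannot split {total} nt into {parts} exons of >= {min_len} nt")
    extra = total - parts * min_len
    add = rng.multinomial(extra, np.full(parts, 1.0 / parts))
    return [min_len + int(a) for a in add]


def _exons_from_lengths(start: int, exon_lens: Sequence[int], intron_lens: Sequence[int]):
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def mirna_name(index: int) -> str:
    return f"zma-miR{index + 1:04d}"


def generate_annotation(config: SimulationConfig) -> tuple[AnnotationSet, TruthBundle]:
    """Build the reference genes, candidate transcripts and the truth plan.

    Reference genes are laid left-to-right on one synthetic chromosome;
    the first ``n_intronic`` genes carry one enlarged intron that hosts an
    intronic candidate. Intergenic candidates and non-overlap decoys are
    placed beyond the last gene. MRE positions for the planted triplets
    are reserved here (lncRNA: interior slots; mRNA: inside the 3'UTR the
    ORF layout leaves free) and realized later by :func:`plant_mres`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    utr3_needed = 20 + config.mirnas_per_triplet * _MRE_SLOT
    reference: list[TranscriptModel] = []
    host_intron: list[tuple[int, int]] = []  # largest intron per gene (genomic)
    cursor = 5001
    for i in range(config.n_coding_genes):
        L = 3 * int(rng.integers(300, 601))  # spliced 900..1800 nt
        n_ex = int(rng.integers(3, 6))
        exon_lens = _split_length(rng, L, n_ex, 120)
        intron_lens = [int(rng.integers(300, 801)) for _ in range(n_ex - 1)]
        if i < config.n_intronic:
            intron_lens[(n_ex - 1) // 2] = int(rng.integers(2400, 3001))
        strand = str(rng.choice(["+", "-"]))
        exons = _exons_from_lengths(cursor, exon_lens, intron_lens)
        orf_len = 3 * ((L - 30 - utr3_needed) // 3)
        if orf_len < 300:
            raise SizingError("coding gene too short for ORF + 3'UTR layout")
        model = TranscriptModel(
            transcript_id=f"MRNA{i + 1:04d}",
            gene_id=f"GENE{i + 1:04d}",
            chrom=CHROM,
            strand=strand,
            exons=exons,
            biotype="coding_reference",
            orf=(31, 30 + orf_len),
        )
        reference.append(model)
        introns = model.introns
        host_intron.append(max(introns, key=lambda iv: iv[1] - iv[0]) if introns else (0, -1))
        cursor = exons[-1][1] + int(rng.integers(1500, 3001))

    # --- candidates --------------------------------------------------------
    raw: list[tuple[dict, str, str]] = []  # (model kwargs, kind, label)

    for j in range(config.n_intronic):
        a, b = host_intron[j]
        if b - a + 1 < 1200:
            raise SizingError("host intron too small for an intronic candidate")
        L = int(rng.integers(400, 701))
        e1, e2 = _split_length(rng, L, 2, 120)
        intr = int(rng.integers(200, 401))
        exons = _exons_from_lengths(a + 20, [e1, e2], [intr])
        if exons[-1][1] >= b:
            raise SizingError("intronic candidate does not fit its host intron")
        raw.append(
            (dict(strand=str(rng.choice(["+", "-"])), exons=exons), "lncrna", "intronic")
        )

    def _overlap_candidate(host: TranscriptModel, strand: str):
        h1s, h1e = host.exons[0]
        e1_len = int(rng.integers(200, 261))
        e2_len = int(rng.integers(200, 261))
        gap = int(rng.integers(150, 251))
        exons = ((h1s + 5, h1s + 4 + e1_len),)
        e2s = exons[0][1] + gap + 1
        exons = exons + ((e2s, e2s + e2_len - 1),)
        return dict(strand=strand, exons=exons)

    used_host = config.n_intronic
    for j in range(config.n_antisense):
        host = reference[used_host + j]
        opp = "-" if host.strand == "+" else "+"
        raw.append((_overlap_candidate(host, opp), "lncrna", "antisense"))
    used_host += config.n_antisense
    for j in range(config.n_decoys.get("same_strand_overlap", 0)):
        host = reference[used_host + j]
        raw.append((_overlap_candidate(host, host.strand), "decoy", "same_strand_overlap"))

    tail = (reference[-1].span[1] if reference else 5000) + 3000
    def _intergenic(L: int, n_ex: int, orf: tuple[int, int] | None = None):
        nonlocal tail
        if n_ex == 1:
            exons = ((tail, tail + L - 1),)
        else:
            exon_lens = _split_length(rng, L, n_ex, 75)
            intron_lens = [int(rng.integers(100, 401)) for _ in range(n_ex - 1)]
            exons = _exons_from_lengths(tail, exon_lens, intron_lens)
        tail = exons[-1][1] + int(rng.integers(1000, 2001))
        return dict(strand=str(rng.choice(["+", "-"])), exons=exons, orf=orf)

    for _ in range(config.n_intergenic):
        raw.append((_intergenic(int(rng.integers(400, 1501)), int(rng.integers(2, 5))), "lncrna", "intergenic"))
    for _ in range(config.n_decoys.get("too_short", 0)):
        raw.append((_intergenic(150, 2), "decoy", "too_short"))
    for _ in range(config.n_decoys.get("mono_exonic", 0)):
        raw.append((_intergenic(600, 1), "decoy", "mono_exonic"))
    for _ in range(config.n_decoys.get("low_fpkm", 0)):
        raw.append((_intergenic(500, 2), "decoy", "low_fpkm"))
    for _ in range(config.n_decoys.get("coding_like", 0)):
        L = 900
        orf_len = 3 * ((L - 90) // 3)
        raw.append((_intergenic(L, 2, orf=(31, 30 + orf_len)), "decoy", "coding_like"))

    if config.genome_length is not None and tail + 5000 > config.genome_length:
        raise SizingError(
            f"genome_length={config.genome_length} too small: layout needs "
            f">= {tail + 5000} bp for the requested feature counts"
        )

    # shuffle candidate order, then assign sequential ids
    order = rng.permutation(len(raw))
    truth = TruthBundle()
    candidates: list[TranscriptModel] = []
    for new_idx, old_idx in enumerate(order):
        kwargs, kind, label = raw[old_idx]
        tid = f"CAND{new_idx + 1:04d}"
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=f"CG{new_idx + 1:04d}",
            chrom=CHROM,
            strand=kwargs["strand"],
            exons=kwargs["exons"],
            biotype="candidate",
            orf=kwargs.get("orf"),
        )
        candidates.append(model)
        if kind == "lncrna":
            truth.true_lncrna_ids[tid] = label
        else:
            truth.decoy_ids[tid] = DECOY_REASON[label]

    truth.mrna_ids = tuple(t.transcript_id for t in reference)
    truth.candidate_ids = tuple(t.transcript_id for t in candidates)
    truth.mirna_ids = tuple(mirna_name(i) for i in range(config.n_mirnas))

    # --- plan triplets and MRE positions -----------------------------------
    lnc_pool = sorted(truth.true_lncrna_ids)
    triplet_lncs = lnc_pool[: config.n_planted_triplets]
    mrna_pick = rng.choice(config.n_coding_genes, size=config.n_planted_triplets, replace=False)
    mirna_perm = rng.permutation(config.n_mirnas)
    by_id = {t.transcript_id: t for t in candidates + reference}
    for t_idx, lnc_id in enumerate(triplet_lncs):
        mrna_id = reference[int(mrna_pick[t_idx])].transcript_id
        block = mirna_perm[
            t_idx * config.mirnas_per_triplet : (t_idx + 1) * config.mirnas_per_triplet
        ]
        shared = tuple(mirna_name(int(i)) for i in block)
        truth.planted_triplets.append(PlantedTriplet(lnc_id, mrna_id, shared))
        lnc_len = by_id[lnc_id].spliced_length
        mrna_model = by_id[mrna_id]
        utr3_start = mrna_model.orf[1] + 1
        for k, mid in enumerate(shared):
            lnc_pos = 40 + k * _MRE_SLOT
            if lnc_pos + 30 > lnc_len:
                raise SizingError(f"lncRNA {lnc_id} too short for {k + 1} planted sites")
            truth.planted_mres.append(PlantedMRE(mid, lnc_id, lnc_pos))
            mrna_pos = utr3_start + 6 + k * _MRE_SLOT
            truth.planted_mres.append(PlantedMRE(mid, mrna_id, mrna_pos))

    return AnnotationSet(reference=reference, candidates=candidates), truth


# -- sequences ---------------------------------------------------------------


def _random_bases(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _orf_sequence(rng, length: int, orf: tuple[int, int], gc: float) -> str:
    """Random sequence carrying one designed ORF (ATG ... stop) at ``orf``."""
    start, end = orf
    if (end - start + 1) % 3 != 0 or end > length:
        raise ValueError("ORF must be codon-aligned and inside the sequence")
    parts = [_random_bases(rng, start - 1, gc).tobytes().decode()]
    n_inner = (end - start + 1) // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_inner + 1:
        c = _random_bases(rng, 3, gc).tobytes().decode()
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append(str(rng.choice(_STOP_CODONS)))
    parts.append("".join(codons))
    parts.append(_random_bases(rng, length - end, gc).tobytes().decode())
    return "".join(parts)


def _find_orfs(seq: str) -> list[tuple[int, int]]:
    """All (start0, length) ORFs, ATG -> in-frame stop inclusive."""
    out = []
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOP_CODONS:
                out.append((start, i + 3 - start))
                start = None
    return out


def _orf_limit(length: int) -> int:
    """Largest ORF a sequence may carry and still be called noncoding by the
    built-in predictor (fraction < 0.3 and ORF < 300 nt)."""
    return min(299, math.ceil(0.3 * length) - 1)


def _break_long_orfs(
    seq: str, limit: int, rng, forbidden: Sequence[tuple[int, int]] = ()
) -> str:
    """Insert stop codons until no ORF exceeds ``limit`` nt, never touching
    the 0-based inclusive ``forbidden`` intervals (planted MRE windows)."""

    def clashes(i: int) -> bool:
        return any(i <= f_end and i + 2 >= f_start for f_start, f_end in forbidden)

    s = list(seq)
    for _ in range(500):
        orfs = [o for o in _find_orfs("".join(s)) if o[1] > limit]
        if not orfs:
            return "".join(s)
        start, length = max(orfs, key=lambda o: o[1])
        slots = [i for i in range(start + 3, start + length - 3, 3) if not clashes(i)]
        if not slots:
            raise RuntimeError("cannot break ORF without touching a planted site")
        mid = start + length // 2
        slot = min(slots, key=lambda i: abs(i - mid))
        s[slot : slot + 3] = rng.choice(_STOP_CODONS)
    raise RuntimeError("ORF breaking did not converge")


def generate_sequences(
    annotation: AnnotationSet, gc_fraction: float = 0.5, seed: int = 1
) -> dict[str, str]:
    """One spliced DNA sequence per transcript model.

    Models carrying an ``orf`` layout get a designed ATG...stop reading
    frame there; all other (noncoding) models get random sequence whose
    incidental ORFs are disrupted below the coding-potential heuristic's
    calling limits.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng([seed, 202])
    out: dict[str, str] = {}
    for model in annotation.all_transcripts():
        L = model.spliced_length
        if model.orf is not None:
            out[model.transcript_id] = _orf_sequence(rng, L, model.orf, gc_fraction)
        else:
            seq = _random_bases(rng, L, gc_fraction).tobytes().decode()
            out[model.transcript_id] = _break_long_orfs(seq, _orf_limit(L), rng)
    return out


def generate_mirnas(
    n: int, length_range: tuple[int, int] = (18, 24), seed: int = 1
) -> dict[str, str]:
    """n distinct mature miRNA sequences over {A,C,G,U} with stable ids."""
    lo, hi = length_range
    if not (18 <= lo <= hi <= 24):
        raise ValueError("miRNA lengths must lie within [18, 24]")
    if n > 4 ** lo:
        raise ValueError(f"cannot draw {n} distinct sequences of length >= {lo}")
    rng = np.random.default_rng([seed, 303])
    bases = np.frombuffer(b"ACGU", dtype="S1")
    seen: set[str] = set()
    out: dict[str, str] = {}
    i = 0
    while len(out) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(bases, size=length).tobytes().decode()
        if seq in seen:
            continue
        seen.add(seq)
        out[mirna_name(i)] = seq
        i += 1
    return out


_RC = str.maketrans("ACGTU", "TGCAA")


def _mre_window(mirna_rna: str) -> str:
    """DNA transcript window perfectly complementary to the miRNA (the
    reverse complement, read 5'->3' on the transcript)."""
    return mirna_rna.upper().translate(_RC)[::-1]


def _apply_wobbles(window: str, mirna_rna: str, n_wobbles: int) -> str:
    """Introduce ``n_wobbles`` G:U wobbles at miRNA positions outside the
    doubled-penalty core (2-13), 0.5 penalty each."""
    if n_wobbles == 0:
        return window
    L = len(mirna_rna)
    w = list(window)
    candidates = [p for p in list(range(14, L + 1)) + [1] if mirna_rna[p - 1] in "GU"]
    if len(candidates) < n_wobbles:
        raise ValueError("not enough wobble-capable positions outside the core")
    for p in candidates[:n_wobbles]:
        idx = L - p  # 0-based window index pairing with miRNA position p
        w[idx] = "T" if mirna_rna[p - 1] == "G" else "G"
    return "".join(w)


def plant_mres(
    sequences: Mapping[str, str],
    mirnas: Mapping[str, str],
    truth: TruthBundle,
    max_planned_penalty: float = 0.0,
    seed: int = 1,
) -> dict[str, str]:
    """Write each planned MRE into its transcript sequence.

    Each planted window is the reverse complement of its miRNA with G:U
    wobble edits realizing the planned penalty (0.5 per wobble, outside
    miRNA positions 2-13). Incidental ORFs created or uncovered by
    planting on noncoding transcripts are re-broken around the planted
    windows. Realized penalties are verified with the scanner's scoring
    function and recorded back into the truth bundle.
    """
    rng = np.random.default_rng([seed, 505])
    seqs = {k: list(v) for k, v in sequences.items()}
    windows: dict[str, list[tuple[int, int]]] = {}

    by_transcript: dict[str, list[PlantedMRE]] = {}
    for pm in truth.planted_mres:
        by_transcript.setdefault(pm.transcript_id, []).append(pm)

    for tid, sites in by_transcript.items():
        if tid not in seqs:
            raise KeyError(f"planted transcript {tid} has no sequence")
        occupied: list[tuple[int, int]] = []
        for pm in sites:
            m = mirnas[pm.mirna_id].upper().replace("T", "U")
            L = len(m)
            start0 = pm.position - 1
            end0 = start0 + L - 1
            if start0 < 0 or end0 >= len(seqs[tid]):
                raise ValueError(
                    f"{tid}: transcript too short for a site at position {pm.position}"
                )
            for a, b in occupied:
                if start0 <= b and end0 >= a:
                    raise ValueError(f"{tid}: planned MRE positions overlap")
            occupied.append((start0, end0))
            n_wobbles = int(round(pm.planned_penalty / 0.5))
            if abs(n_wobbles * 0.5 - pm.planned_penalty) > 1e-9:
                raise ValueError("planned penalties must be multiples of 0.5 (wobbles)")
            window = _apply_wobbles(_mre_window(m), m, n_wobbles)
            seqs[tid][start0 : end0 + 1] = window
        windows[tid] = occupied

    out = {k: "".join(v) for k, v in seqs.items()}

    # re-disrupt ORFs on noncoding transcripts, avoiding the planted windows
    for tid in by_transcript:
        if tid in truth.true_lncrna_ids or tid in truth.decoy_ids:
            L = len(out[tid])
            out[tid] = _break_long_orfs(out[tid], _orf_limit(L), rng, windows[tid])

    for pm in truth.planted_mres:
        m = mirnas[pm.mirna_id]
        L = len(m)
        window = out[pm.transcript_id][pm.position - 1 : pm.position - 1 + L]
        realized = score_duplex(m, window)
        pm.realized_penalty = realized
        if realized > max_planned_penalty + 1e-9:
            raise ValueError(
                f"planted site {pm.mirna_id}@{pm.transcript_id}:{pm.position} "
                f"realized penalty {realized} > allowed {max_planned_penalty}"
            )
    return out


# -- expression --------------------------------------------------------------


def _design_samples(design) -> pd.DataFrame:
    rows = []
    for tissue, stage, reps in design:
        for k in range(1, reps + 1):
            rows.append(
                {
                    "sample": sample_name(tissue, stage, k),
                    "tissue": tissue,
                    "stage": int(stage),
                    "replicate": k,
                }
            )
    df = pd.DataFrame(rows).set_index("sample")
    if df.index.has_duplicates:
        raise DesignError("duplicate tissue/stage/replicate combinations in design")
    return df


def simulate_expression(
    config: SimulationConfig, truth: TruthBundle
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    """Coupled (lncRNA-candidate, mRNA, miRNA) FPKM matrices.

    Baselines are log-normal: per-feature mean log2-FPKM plus
    Normal(0, noise_sd) replicate noise. Each planted triplet's shared
    miRNAs follow a monotone developmental profile z (ordered by stage
    within tissue, direction alternating between triplets); the lncRNA
    and mRNA partners receive ``- coupling_strength * z``, producing
    positive lncRNA-mRNA and negative miRNA-partner correlation. The
    ``low_fpkm`` decoys get baselines far below 1 FPKM. Values are
    returned on the FPKM scale (2 ** log2-value).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 404])
    samples = _design_samples(config.design)
    S = len(samples)

    groups = sorted(
        {(int(s), t) for t, s, _ in config.design}
    )  # monotone axis: stage-major, tissue minor
    group_rank = {g: i for i, g in enumerate(groups)}
    z_levels = np.linspace(-1.0, 1.0, len(groups)) if len(groups) > 1 else np.zeros(1)
    z_sample = np.array(
        [z_levels[group_rank[(int(row.stage), row.tissue)]] for row in samples.itertuples()]
    )

    def matrix(ids, base):
        noise = rng.normal(0.0, config.noise_sd, size=(len(ids), S))
        return base[:, None] + noise

    cand_ids = list(truth.candidate_ids)
    mrna_ids = list(truth.mrna_ids)
    mirna_ids = list(truth.mirna_ids)

    cand_base = np.clip(rng.normal(2.0, 1.0, len(cand_ids)), 1.0, 8.0)
    low_idx = [i for i, cid in enumerate(cand_ids) if truth.decoy_ids.get(cid) == "low_expression"]
    for i in low_idx:
        cand_base[i] = rng.uniform(-3.0, -2.2)
    mrna_base = np.clip(rng.normal(3.5, 1.2, len(mrna_ids)), 1.0, 10.0)
    mirna_base = np.clip(rng.normal(3.0, 1.0, len(mirna_ids)), 1.0, 8.0)

    V_cand = matrix(cand_ids, cand_base)
    V_mrna = matrix(mrna_ids, mrna_base)
    V_mirna = matrix(mirna_ids, mirna_base)

    cand_row = {cid: i for i, cid in enumerate(cand_ids)}
    mrna_row = {mid: i for i, mid in enumerate(mrna_ids)}
    mirna_row = {mid: i for i, mid in enumerate(mirna_ids)}
    for t_idx, trip in enumerate(truth.planted_triplets):
        z = z_sample if t_idx % 2 == 0 else -z_sample
        V_cand[cand_row[trip.lncrna_id]] += -config.coupling_strength * z
        V_mrna[mrna_row[trip.mrna_id]] += -config.coupling_strength * z
        for mid in trip.shared_mirnas:
            V_mirna[mirna_row[mid]] += z

    def to_matrix(ids, V):
        fpkm = np.power(2.0, V)
        return ExpressionMatrix(
            pd.DataFrame(fpkm, index=ids, columns=samples.index), samples
        )

    return to_matrix(cand_ids, V_cand), to_matrix(mrna_ids, V_mrna), to_matrix(mirna_ids, V_mirna)


# -- orchestration -----------------------------------------------------------


@dataclass
class FixtureBundle:
    config: SimulationConfig
    annotation: AnnotationSet
    truth: TruthBundle
    sequences: dict[str, str]
    mirnas: dict[str, str]
    lnc_expr: ExpressionMatrix  # all candidates, decoys included
    mrna_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix


def simulate_bundle(config: SimulationConfig) -> FixtureBundle:
    """Run the full generator: annotation, sequences, miRNAs, planted MREs
    and coupled expression, all from ``config.seed``."""
    annotation, truth = generate_annotation(config)
    sequences = generate_sequences(annotation, config.gc_fraction, config.seed)
    mirnas = generate_mirnas(config.n_mirnas, config.mirna_length_range, config.seed)
    sequences = plant_mres(sequences, mirnas, truth, 0.0, config.seed)
    lnc_expr, mrna_expr, mirna_expr = simulate_expression(config, truth)
    return FixtureBundle(
        config, annotation, truth, sequences, mirnas, lnc_expr, mrna_expr, mirna_expr
    )


def write_fixture(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write the fixture to disk (GTFs, FASTAs, TSVs, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "candidates_gtf": outdir / "candidates.gtf",
        "transcripts_fa": outdir / "transcripts.fa",
        "mirnas_fa": outdir / "mirnas.fa",
        "expr_candidates": outdir / "expr_candidates.tsv",
        "expr_mrna": outdir / "expr_mrna.tsv",
        "expr_mirna": outdir / "expr_mirna.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_gtf(bundle.annotation.reference, paths["reference_gtf"])
    write_gtf(bundle.annotation.candidates, paths["candidates_gtf"])
    SeqIO.write(
        [SeqRecord(Seq(s), id=tid, description="") for tid, s in bundle.sequences.items()],
        paths["transcripts_fa"],
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(s), id=mid, description="") for mid, s in bundle.mirnas.items()],
        paths["mirnas_fa"],
        "fasta",
    )
    bundle.lnc_expr.to_tsv(paths["expr_candidates"], paths["samples"])
    bundle.mrna_expr.to_tsv(paths["expr_mrna"])
    bundle.mirna_expr.to_tsv(paths["expr_mirna"])
    paths["truth"].write_text(bundle.truth.to_json() + "\n")
    return paths


# -- two-group DE benchmark ---------------------------------------------------


def simulate_de_dataset(
    n_features: int = 1000,
    n_up: int = 0,
    n_down: int = 0,
    log2_shift: float = 2.0,
    noise_sd: float = 0.25,
    n_reps: int = 3,
    stages: Sequence[int] = (9, 15, 20),
    seed: int = 1,
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Endosperm-vs-embryo benchmark matrix with planted shifts.

    The first ``n_up`` features are shifted up in endosperm by
    ``log2_shift`` at every stage, the next ``n_down`` down; the rest are
    null. Returns the FPKM matrix and the truth sets.
    """
    if n_up + n_down > n_features:
        raise ValueError("more planted features than features")
    rng = np.random.default_rng([seed, 606])
    design = tuple((t, s, n_reps) for t in TISSUES for s in stages)
    samples = _design_samples(design)
    base = rng.normal(3.0, 1.0, n_features)
    V = base[:, None] + rng.normal(0.0, noise_sd, size=(n_features, len(samples)))
    endo = np.array([t == "endosperm" for t in samples["tissue"]])
    ids = [f"FEAT{i + 1:05d}" for i in range(n_features)]
    V[:n_up, endo] += log2_shift
    V[n_up : n_up + n_down, endo] -= log2_shift
    truth = {"up": set(ids[:n_up]), "down": set(ids[n_up : n_up + n_down])}
    expr = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, V), index=ids, columns=samples.index), samples
    )
    return expr, truth
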