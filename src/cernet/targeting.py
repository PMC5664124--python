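"""Plant-style miRNA recognition element (MRE) scanning.

A miRNA is aligned 5'->3' against the reverse complement of each
transcript window of equal length (ungapped). Per-position penalties
follow the standard plant target rules: Watson-Crick match 0, G:U wobble
0.5, mismatch 1.0, with penalties doubled at miRNA positions 2-13 from
the 5' end (the region whose pairing plant AGO complexes require most
strictly). Windows with total penalty <= ``max_penalty`` (default 4.0)
are reported as MRE sites; overlapping hits are collapsed to the local
penalty minimum.

An optional single-bulge mode allows one unpaired transcript nucleotide
inside the duplex at a fixed penalty of 2.0.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "MiRNARecord",
    "MRESite",
    "TargetMap",
    "score_duplex",
    "scan_targets",
    "build_target_map",
]

_TO_RNA = str.maketrans("Tt", "Uu")
_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGU"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

# pair penalty matrix, rows = miRNA base, cols = target base (A C G U N)
_PAIR = np.ones((5, 5), dtype=float)
for m, t in ((0, 3), (3, 0), (1, 2), (2, 1)):  # A:U, U:A, C:G, G:C
    _PAIR[m, t] = 0.0
_PAIR[2, 3] = 0.5  # G:U wobble
_PAIR[3, 2] = 0.5  # U:G wobble

CORE_START = 2  # miRNA positions (1-based, 5'->3') with doubled penalty
CORE_END = 13


def _encode(seq: str, what: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.translate(_TO_RNA).encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({c for c in seq.upper() if c not in "ACGTUN"})
        raise ValueError(f"{what}: non-ACGU/T/N characters {bad}")
    return codes


def _weights(length: int, core_start: int = CORE_START, core_end: int = CORE_END) -> np.ndarray:
    w = np.ones(length)
    w[core_start - 1 : core_end] = 2.0
    return w


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA sequence, RNA alphabet, 18-24 nt."""

    mirna_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().translate(_TO_RNA)
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.mirna_id}: miRNA must be over A/C/G/U")
        if not 18 <= len(seq) <= 24:
            raise ValueError(
                f"{self.mirna_id}: length {len(seq)} outside the mature miRNA range 18-24 nt"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MRESite:
    """One miRNA binding site on a transcript (1-based start, window length)."""

    mirna_id: str
    transcript_id: str
    start: int
    penalty: float
    length: int


def score_duplex(mirna_seq: str, window: str) -> float:
    """Penalty for an ungapped miRNA/target duplex of equal lengths.

    The miRNA (5'->3') pairs antiparallel with the window, so miRNA
    position i pairs with window position ``len(window) - i + 1``.
    """
    m = _encode(mirna_seq, "miRNA")
    t = _encode(window, "window")
    if len(m) != len(t):
        raise ValueError(
            f"ungapped duplex needs equal lengths, got {len(m)} vs {len(t)}"
        )
    pen = _PAIR[m, t[::-1]]
    return float(np.dot(pen, _weights(len(m))))


def _collapse(sites: list[MRESite]) -> list[MRESite]:
    """Collapse chains of mutually overlapping hits to the penalty minimum.

    Hits are chained while consecutive accepted windows overlap; each chain
    keeps its single lowest-penalty site (leftmost on ties).
    """
    if not sites:
        return []
    sites = sorted(sites, key=lambda s: (s.start, s.length))
    out = []
    best = sites[0]
    chain_end = sites[0].start + sites[0].length - 1
    for s in sites[1:]:
        if s.start <= chain_end:  # overlaps the running chain
            if s.penalty < best.penalty:
                best = s
            chain_end = max(chain_end, s.start + s.length - 1)
        else:
            out.append(best)
            best = s
            chain_end = s.start + s.length - 1
    out.append(best)
    return out


def scan_targets(
    mirna: MiRNARecord,
    transcript_id: str,
    sequence: str,
    max_penalty: float = 4.0,
    bulge: bool = False,
    bulge_penalty: float = 2.0,
) -> list[MRESite]:
    """All MRE sites of one miRNA on one transcript.

    Slides a window of miRNA length (plus one in bulge mode) over the
    transcript, scores every window, keeps penalties <= ``max_penalty``
    and collapses overlapping hits to the local minimum.
    """
    m = _encode(mirna.sequence, mirna.mirna_id)
    t = _encode(sequence, transcript_id)
    L = len(m)
    if len(t) < L:
        raise ValueError(
            f"{transcript_id}: transcript ({len(t)} nt) shorter than miRNA ({L} nt)"
        )
    w = _weights(L)
    hits: list[MRESite] = []

    windows = sliding_window_view(t, L)[:, ::-1]  # column j = miRNA position j+1
    pen = (_PAIR[m[None, :], windows] * w[None, :]).sum(axis=1)
    for idx in np.flatnonzero(pen <= max_penalty):
        hits.append(MRESite(mirna.mirna_id, transcript_id, int(idx) + 1, float(pen[idx]), L))

    if bulge and len(t) >= L + 1:
        wide = sliding_window_view(t, L + 1)
        best = np.full(wide.shape[0], np.inf)
        # skip one internal target base (keeping both duplex ends paired)
        for skip in range(1, L):
            cols = [c for c in range(L + 1) if c != skip]
            sub = wide[:, cols][:, ::-1]
            pb = (_PAIR[m[None, :], sub] * w[None, :]).sum(axis=1) + bulge_penalty
            best = np.minimum(best, pb)
        for idx in np.flatnonzero(best <= max_penalty):
            hits.append(
                MRESite(mirna.mirna_id, transcript_id, int(idx) + 1, float(best[idx]), L + 1)
            )

    return _collapse(hits)


class TargetMap:
    """miRNA -> transcript MRE sites with per-pair counts.

    ``targets_of`` and ``mirnas_targeting`` are the two transposes of the
    same binary relation; ``mre_count`` counts sites per (miRNA, transcript).
    """

    def __init__(self, sites: Iterable[MRESite]):
        self.sites: list[MRESite] = list(sites)
        self._counts: Counter = Counter(
            (s.mirna_id, s.transcript_id) for s in self.sites
        )
        self._targets: dict[str, set[str]] = defaultdict(set)
        self._mirnas: dict[str, set[str]] = defaultdict(set)
        for s in self.sites:
            self._targets[s.mirna_id].add(s.transcript_id)
            self._mirnas[s.transcript_id].add(s.mirna_id)

    def mre_count(self, mirna_id: str, transcript_id: str) -> int:
        return self._counts.get((mirna_id, transcript_id), 0)

    def targets_of(self, mirna_id: str) -> frozenset:
        return frozenset(self._targets.get(mirna_id, ()))

    def mirnas_targeting(self, transcript_id: str) -> frozenset:
        return frozenset(self._mirnas.get(transcript_id, ()))

    def pairs(self) -> dict[tuple[str, str], int]:
        return dict(self._counts)

    def __len__(self) -> int:
        return len(self.sites)


def _as_records(mirnas) -> list[MiRNARecord]:
    if isinstance(mirnas, Mapping):
        return [MiRNARecord(k, v) for k, v in mirnas.items()]
    out = []
    for item in mirnas:
        if isinstance(item, MiRNARecord):
            out.append(item)
        else:
            out.append(MiRNARecord(*item))
    return out


def build_target_map(
    mirnas,
    sequences: Mapping[str, str],
    max_penalty: float = 4.0,
    bulge: bool = False,
) -> TargetMap:
    """Scan every miRNA against every transcript and assemble the map."""
    records = _as_records(mirnas)
    ids = [r.mirna_id for r in records]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate miRNA ids: {dup}")
    tids = list(sequences)
    if len(tids) != len(set(tids)):
        raise ValueError("duplicate transcript ids")
    sites: list[MRESite] = []
    for rec in records:
        for tid in tids:
            seq = sequences[tid]
            if len(seq) < len(rec.sequence):
                continue
            sites.extend(scan_targets(rec, tid, seq, max_penalty=max_penalty, bulge=bulge))
    return TargetMap(sites)
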