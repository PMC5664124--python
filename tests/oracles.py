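"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: duplex
scoring is a per-position python loop, window scanning enumerates every
window, and hypergeometric tails are exact rational arithmetic.
"""

from fractions import Fraction
from math import comb

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def oracle_duplex_penalty(mirna: str, window: str) -> float:
    """Position-by-position plant-rule penalty (miRNA 5'->3' vs antiparallel
    target window), doubled at miRNA positions 2-13."""
    mirna = mirna.upper().replace("T", "U")
    window = window.upper().replace("T", "U")
    L = len(mirna)
    assert len(window) == L
    total = 0.0
    for i in range(L):  # miRNA position i+1 pairs with window position L-i
        pair = (mirna[i], window[L - 1 - i])
        if pair in WC:
            p = 0.0
        elif pair in WOBBLE:
            p = 0.5
        else:
            p = 1.0
        if 2 <= i + 1 <= 13:
            p *= 2.0
        total += p
    return total


def oracle_scan(mirna: str, seq: str, max_penalty: float) -> list[tuple[int, float]]:
    """All-window enumeration with overlap collapse to the penalty minimum
    (ties -> leftmost). Returns (1-based start, penalty) pairs."""
    L = len(mirna)
    hits = []
    for i in range(len(seq) - L + 1):
        pen = oracle_duplex_penalty(mirna, seq[i : i + L])
        if pen <= max_penalty:
            hits.append((i + 1, pen))
    out = []
    i = 0
    while i < len(hits):
        j = i
        best = i
        chain_end = hits[i][0] + L - 1
        while j + 1 < len(hits) and hits[j + 1][0] <= chain_end:
            j += 1
            chain_end = max(chain_end, hits[j][0] + L - 1)
            if hits[j][1] < hits[best][1]:
                best = j
        out.append(hits[best])
        i = j + 1
    return out


def oracle_hypergeom_upper(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n) by enumeration."""
    denom = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, denom)


def oracle_longest_orf(seq: str) -> int:
    """Exhaustive 3-frame ATG->stop scan (stop codon included)."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        for s_idx, codon in enumerate(codons):
            if codon == "ATG":
                for e_idx in range(s_idx + 1, len(codons)):
                    if codons[e_idx] in stops:
                        best = max(best, (e_idx - s_idx + 1) * 3)
                        break
    return best
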