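"""Endosperm-vs-embryo differential expression and tissue specificity.

Fold change is endosperm mean FPKM over embryo mean FPKM (with a small
pseudocount against zeros); significance comes from a two-sided Welch
t-test on log2(FPKM + 1) across replicates. A feature is called up when
log2FC >= 1 with p < 0.05, down when log2FC <= -1 with p < 0.05
(thresholds configurable). Stage-wise calls are intersected to find
features consistently regulated across all supplied stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = [
    "DERecord",
    "StageIntersection",
    "fold_change",
    "de_test",
    "call_de",
    "call_de_all_stages",
    "intersect_stages",
    "tissue_specificity",
]


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    stage: int
    fc: float
    log2fc: float
    p_value: float
    call: str  # "up" | "down" | "ns"


def fold_change(
    mean_endosperm: float, mean_embryo: float, pseudocount: float = 0.01
) -> tuple[float, float]:
    """(FC, log2FC) with FC = (endosperm + pc) / (embryo + pc)."""
    if mean_endosperm < 0 or mean_embryo < 0:
        raise ValueError("mean FPKM values must be non-negative")
    fc = (mean_endosperm + pseudocount) / (mean_embryo + pseudocount)
    return fc, math.log2(fc)


def _fix_nan_p(p: np.ndarray, mean_diff: np.ndarray) -> np.ndarray:
    """Welch on two zero-variance groups yields NaN; resolve by the limit:
    equal means -> p = 1 (t = 0), different means -> p = 0 (|t| -> inf)."""
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        p = p.copy()
        p[bad & (np.abs(mean_diff) < 1e-12)] = 1.0
        p[bad & (np.abs(mean_diff) >= 1e-12)] = 0.0
    return p


def de_test(
    group_endosperm: Sequence[float],
    group_embryo: Sequence[float],
    log_transform: bool = True,
) -> float:
    """Two-sided Welch t-test p-value between replicate groups.

    Values are log2(FPKM + 1)-transformed by default before testing.
    """
    a = np.asarray(group_endosperm, dtype=float)
    b = np.asarray(group_embryo, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs >= 2 replicates per group")
    if log_transform:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    p = _fix_nan_p(np.atleast_1d(res.pvalue), np.atleast_1d(a.mean() - b.mean()))
    return float(p[0])


def call_de(
    expr: ExpressionMatrix,
    stage: int,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    pseudocount: float = 0.01,
    log_transform: bool = True,
    bh: bool = False,
    tissue_numerator: str = "endosperm",
    tissue_denominator: str = "embryo",
) -> list[DERecord]:
    """Per-feature DE calls for one stage (numerator vs denominator tissue)."""
    en_cols = expr.samples_in(tissue_numerator, stage)
    em_cols = expr.samples_in(tissue_denominator, stage)
    if not en_cols or not em_cols:
        raise ValueError(f"stage {stage}: both tissues must be present")
    if len(en_cols) < 2 or len(em_cols) < 2:
        raise ValueError(f"stage {stage}: Welch's t-test needs >= 2 replicates per group")

    A = expr.data[en_cols].to_numpy(dtype=float)
    B = expr.data[em_cols].to_numpy(dtype=float)
    fc = (A.mean(axis=1) + pseudocount) / (B.mean(axis=1) + pseudocount)
    log2fc = np.log2(fc)

    At = np.log2(A + 1.0) if log_transform else A
    Bt = np.log2(B + 1.0) if log_transform else B
    res = stats.ttest_ind(At, Bt, axis=1, equal_var=False)
    p = _fix_nan_p(res.pvalue, At.mean(axis=1) - Bt.mean(axis=1))
    if bh:
        p = multipletests(p, method="fdr_bh")[1]

    records = []
    for fid, f, l2, pv in zip(expr.feature_ids, fc, log2fc, p):
        if pv < alpha and l2 >= min_abs_log2fc:
            call = "up"
        elif pv < alpha and l2 <= -min_abs_log2fc:
            call = "down"
        else:
            call = "ns"
        records.append(DERecord(fid, int(stage), float(f), float(l2), float(pv), call))
    return records


def call_de_all_stages(expr: ExpressionMatrix, **kwargs) -> list[DERecord]:
    records: list[DERecord] = []
    for stage in expr.stages:
        records.extend(call_de(expr, stage, **kwargs))
    return records


@dataclass
class StageIntersection:
    """Per-stage up/down sets and their all-stage intersections."""

    up: dict[int, set[str]] = field(default_factory=dict)
    down: dict[int, set[str]] = field(default_factory=dict)
    consistent_up: set[str] = field(default_factory=set)
    consistent_down: set[str] = field(default_factory=set)


def intersect_stages(records: Iterable[DERecord]) -> StageIntersection:
    """Venn-style intersection of DE calls over all supplied stages."""
    out = StageIntersection()
    stages = set()
    for r in records:
        stages.add(r.stage)
        out.up.setdefault(r.stage, set())
        out.down.setdefault(r.stage, set())
        if r.call == "up":
            out.up[r.stage].add(r.feature_id)
        elif r.call == "down":
            out.down[r.stage].add(r.feature_id)
    if stages:
        out.consistent_up = set.intersection(*(out.up[s] for s in stages))
        out.consistent_down = set.intersection(*(out.down[s] for s in stages))
    return out


def tissue_specificity(
    expr: ExpressionMatrix,
    presence_fpkm: float = 1.0,
    absence_fpkm: float = 1.0,
) -> dict[str, set[str]]:
    """Tissue-exclusive features.

    A feature is specific to a tissue iff its FPKM exceeds
    ``presence_fpkm`` in at least one library of that tissue AND stays
    below ``absence_fpkm`` in every library of every other tissue.
    """
    tissues = expr.tissues
    if len(tissues) < 2:
        raise ValueError("tissue specificity needs >= 2 tissues")
    out: dict[str, set[str]] = {t: set() for t in tissues}
    for tissue in tissues:
        own = expr.data[expr.samples_in(tissue)].to_numpy(dtype=float)
        other_cols = [c for t in tissues if t != tissue for c in expr.samples_in(t)]
        other = expr.data[other_cols].to_numpy(dtype=float)
        detected = (own > presence_fpkm).any(axis=1)
        absent = (other < absence_fpkm).all(axis=1)
        for fid, d, a in zip(expr.feature_ids, detected, absent):
            if d and a:
                out[tissue].add(fid)
    return out
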