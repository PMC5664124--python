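"""ceRNA network inference: co-expression screens, MRE-ratio ceRNA score,
shared-miRNA hypergeometric test, network assembly, and term enrichment.

The competing-endogenous-RNA (ceRNA) hypothesis holds that transcripts
sharing miRNA recognition elements (MREs) titrate a common miRNA pool and
thereby regulate each other. An lncRNA-mRNA pair becomes a network edge
when (i) the two are positively co-expressed (PCC > 0.5, p < 0.01),
(ii) at least one miRNA targets both partners and is negatively
co-expressed with both, (iii) the ceRNA score passes its threshold, and
(iv) a hypergeometric test on the shared-miRNA count is significant
(p < 0.01).

The ceRNA score (ratio mode, default) is the number of MREs on the
lncRNA for the *shared* miRNAs divided by the number of MREs on the
lncRNA for *all* miRNAs targeting it, hence in [0, 1]; the default
threshold 1.0 retains pairs in which every lncRNA-targeting miRNA is
shared. Count mode instead uses the raw number of shared-miRNA MREs on
the lncRNA, for workflows that threshold on absolute MRE counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .targeting import TargetMap

__all__ = [
    "CoexpressionPair",
    "CeRNAPair",
    "CeRNANetwork",
    "EnrichmentResult",
    "pearson",
    "coexpressed_pairs",
    "mirna_anticorrelated",
    "cerna_score",
    "shared_mirna_hypergeom",
    "build_network",
    "term_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexpressionPair:
    id_a: str
    id_b: str
    pcc: float
    p_value: float


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-transform p-value.

    p derives from t = r * sqrt((m - 2) / (1 - r^2)) on m - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    if x.size < 3:
        raise ValueError("Pearson correlation needs >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _corr_matrix_with_p(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row PCC between two matrices sharing columns, plus p-values.

    Zero-variance rows propagate NaN correlations (screens then skip them).
    """
    m = A.shape[1]
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    sa = Az.std(axis=1)
    sb = Bz.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Az @ Bz.T) / m / np.outer(sa, sb)
        R = np.clip(R, -1.0, 1.0)
        t = R * np.sqrt((m - 2) / (1.0 - R * R))
    # |r| = 1 exactly -> t infinite -> p = 0
    t = np.where(np.abs(R) >= 1.0, np.inf * np.sign(R), t)
    P = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    return R, P


def _matched_log(a: ExpressionMatrix, b: ExpressionMatrix, log_transform: bool):
    if list(a.data.columns) != list(b.data.columns):
        raise ValueError("expression matrices must share identical sample columns")
    A = a.log2().to_numpy() if log_transform else a.data.to_numpy(dtype=float)
    B = b.log2().to_numpy() if log_transform else b.data.to_numpy(dtype=float)
    return A, B


def coexpressed_pairs(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    min_pcc: float = 0.5,
    alpha: float = 0.01,
    log_transform: bool = True,
    bh: bool = False,
) -> list[CoexpressionPair]:
    """All lncRNA x mRNA pairs with PCC > min_pcc and p < alpha (strict)."""
    A, B = _matched_log(lnc_expr, mrna_expr, log_transform)
    R, P = _corr_matrix_with_p(A, B)
    if bh:
        flat = multipletests(P.ravel(), method="fdr_bh")[1]
        P = flat.reshape(P.shape)
    out = []
    lnc_ids = lnc_expr.feature_ids
    mrna_ids = mrna_expr.feature_ids
    for i, j in zip(*np.where((R > min_pcc) & (P < alpha))):
        out.append(CoexpressionPair(lnc_ids[i], mrna_ids[j], float(R[i, j]), float(P[i, j])))
    return out


def mirna_anticorrelated(
    mirna_expr: ExpressionMatrix,
    feature_expr: ExpressionMatrix,
    max_pcc: float = -0.5,
    alpha: float = 0.01,
    log_transform: bool = True,
    bh: bool = False,
) -> list[CoexpressionPair]:
    """(miRNA, feature) pairs with PCC < max_pcc and p < alpha."""
    A, B = _matched_log(mirna_expr, feature_expr, log_transform)
    R, P = _corr_matrix_with_p(A, B)
    if bh:
        flat = multipletests(P.ravel(), method="fdr_bh")[1]
        P = flat.reshape(P.shape)
    out = []
    m_ids = mirna_expr.feature_ids
    f_ids = feature_expr.feature_ids
    for i, j in zip(*np.where((R < max_pcc) & (P < alpha))):
        out.append(CoexpressionPair(m_ids[i], f_ids[j], float(R[i, j]), float(P[i, j])))
    return out


def shared_mirna_hypergeom(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N population, K successes,
    n draws): the chance of k or more shared miRNAs when the n miRNAs
    targeting the mRNA were drawn at random from the N-miRNA universe of
    which K target the lncRNA."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric counts N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cerna_score(
    lncrna_id: str,
    mrna_id: str,
    target_map: TargetMap,
    anticorrelated: Iterable[tuple[str, str]] | None = None,
    mode: str = "ratio",
) -> tuple[float, frozenset]:
    """ceRNA score of an lncRNA-mRNA pair and its shared miRNA set.

    Shared miRNAs target both partners; when an anticorrelation screen is
    supplied (pairs of (mirna_id, feature_id) that passed), a miRNA counts
    as shared only if it passed the screen for BOTH partners. Ratio mode:
    shared-miRNA MREs on the lncRNA over all MREs on the lncRNA. Count
    mode: the raw number of shared-miRNA MREs on the lncRNA.
    """
    if mode not in ("ratio", "count"):
        raise ValueError(f"unknown score mode {mode!r}")
    targeting_lnc = target_map.mirnas_targeting(lncrna_id)
    targeting_mrna = target_map.mirnas_targeting(mrna_id)
    shared = targeting_lnc & targeting_mrna
    if anticorrelated is not None:
        passed = set(anticorrelated)
        shared = frozenset(
            m for m in shared if (m, lncrna_id) in passed and (m, mrna_id) in passed
        )
    numer = sum(target_map.mre_count(m, lncrna_id) for m in shared)
    if mode == "count":
        return float(numer), frozenset(shared)
    denom = sum(target_map.mre_count(m, lncrna_id) for m in targeting_lnc)
    if denom == 0:
        raise ZeroDivisionError(
            f"ceRNA score undefined: no miRNA targets lncRNA {lncrna_id}"
        )
    return numer / denom, frozenset(shared)


@dataclass(frozen=True)
class CeRNAPair:
    """One evaluated lncRNA-mRNA pair (retained pairs become network edges)."""

    lncrna_id: str
    mrna_id: str
    pcc: float
    pcc_p: float
    shared_mirnas: frozenset
    score: float
    hyper_p: float
    N: int  # miRNA universe size
    K: int  # miRNAs targeting the lncRNA
    n: int  # miRNAs targeting the mRNA
    k: int  # shared (screened) miRNAs
    retained: bool


class CeRNANetwork:
    """Typed lncRNA-miRNA-mRNA network plus the full evaluated pair table."""

    def __init__(self, graph: nx.Graph, pairs: list[CeRNAPair]):
        self.graph = graph
        self.pairs = pairs

    @property
    def retained_pairs(self) -> list[CeRNAPair]:
        return [p for p in self.pairs if p.retained]

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind]

    def pair_table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "lncrna_id": p.lncrna_id,
                    "mrna_id": p.mrna_id,
                    "pcc": p.pcc,
                    "pcc_p": p.pcc_p,
                    "shared_mirnas": ",".join(sorted(p.shared_mirnas)),
                    "N": p.N,
                    "K": p.K,
                    "n": p.n,
                    "k": p.k,
                    "score": p.score,
                    "hyper_p": p.hyper_p,
                    "retained": p.retained,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "lncrna_id", "mrna_id", "pcc", "pcc_p", "shared_mirnas",
                "N", "K", "n", "k", "score", "hyper_p", "retained",
            ],
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    coexpressed: Sequence[CoexpressionPair],
    anticorrelated_lnc: Sequence[CoexpressionPair],
    anticorrelated_mrna: Sequence[CoexpressionPair],
    target_map: TargetMap,
    n_mirna_universe: int,
    min_score: float = 1.0,
    alpha: float = 0.01,
    score_mode: str = "ratio",
) -> CeRNANetwork:
    """Assemble the ceRNA network from the screens and the target map.

    ``n_mirna_universe`` is the number of miRNAs supplied to the run (the
    hypergeometric population N).
    """
    screen = {(p.id_a, p.id_b) for p in anticorrelated_lnc}
    screen |= {(p.id_a, p.id_b) for p in anticorrelated_mrna}

    pairs: list[CeRNAPair] = []
    graph = nx.Graph()
    for co in coexpressed:
        lnc, mrna = co.id_a, co.id_b
        K = len(target_map.mirnas_targeting(lnc))
        n = len(target_map.mirnas_targeting(mrna))
        try:
            score, shared = cerna_score(lnc, mrna, target_map, screen, mode=score_mode)
        except ZeroDivisionError:
            logger.info("skipping pair (%s, %s): no miRNA targets the lncRNA", lnc, mrna)
            continue
        k = len(shared)
        hyper_p = shared_mirna_hypergeom(n_mirna_universe, K, n, k)
        retained = (k >= 1) and (score >= min_score) and (hyper_p < alpha)
        pairs.append(
            CeRNAPair(
                lnc, mrna, co.pcc, co.p_value, shared, score, hyper_p,
                n_mirna_universe, K, n, k, retained,
            )
        )
        if retained:
            graph.add_node(lnc, kind="lncRNA")
            graph.add_node(mrna, kind="mRNA")
            graph.add_edge(
                lnc, mrna,
                kind="cerna",
                score=score,
                hyper_p=hyper_p,
                pcc=co.pcc,
                provenance="coexpression+cerna_score+hypergeometric",
            )
            for m in sorted(shared):
                graph.add_node(m, kind="miRNA")
                for endpoint in (lnc, mrna):
                    if not graph.has_edge(m, endpoint):
                        graph.add_edge(
                            m, endpoint,
                            kind="mirna_target",
                            provenance="targeting+anticorrelation",
                        )
    return CeRNANetwork(graph, pairs)


# -- term enrichment ---------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # in-set features annotated with the term
    n: int  # feature-set size (restricted to the universe)
    K: int  # universe features annotated with the term
    N: int  # universe size
    fold_enrichment: float
    p_value: float


def term_enrichment(
    feature_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
    universe: Iterable[str],
    alpha: float = 0.05,
    min_fold_enrichment: float = 4.0,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in a set.

    Fold enrichment = (k/n) / (K/N). Retained terms satisfy p < alpha and
    fold enrichment > min_fold_enrichment (both strict).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    fset = set(feature_set) & universe
    if set(feature_set) - universe:
        raise ValueError("feature set must be a subset of the universe")

    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, set[str]] = {}
        for _, row in annotation.iterrows():
            ann.setdefault(str(row["feature_id"]), set()).add(str(row["term_id"]))
    else:
        ann = {f: set(terms) for f, terms in annotation.items()}

    term_universe: dict[str, set[str]] = {}
    for f in universe:
        for term in ann.get(f, ()):
            term_universe.setdefault(term, set()).add(f)

    N = len(universe)
    n = len(fset)
    results = []
    for term in sorted(term_universe):
        members = term_universe[term]
        K = len(members)
        k = len(members & fset)
        fe = (k / n) / (K / N) if n else 0.0
        p = shared_mirna_hypergeom(N, K, n, k)
        res = EnrichmentResult(term, k, n, K, N, fe, p)
        if return_all or (p < alpha and fe > min_fold_enrichment):
            results.append(res)
    return results
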