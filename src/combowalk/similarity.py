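"""Elementary similarity measures and their noisy-OR fusion.

Drug-drug similarity combines a chemical-structure measure (Jaccard over
binary fingerprints) with a pharmacological one (two-step resource-allocation
flow through the drug-protein bipartite graph).  Protein-protein similarity
combines normalized Smith-Waterman sequence similarity with Wang's
graph-based GO semantic similarity.  Each pair of elementary measures is
fused by probability disjunction  s = 1 - (1 - s1)(1 - s2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .datatypes import (
    AssociationMatrix,
    FingerprintSet,
    OntologyDAG,
    ProteinAnnotation,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "jaccard_similarity",
    "bipartite_projection_similarity",
    "sequence_similarity",
    "go_semantic_similarity",
    "disjunction_integrate",
    "wang_term_similarity",
]


def jaccard_similarity(fingerprints: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Jaccard similarity of binary fingerprints.

    ``S_ij = |b_i AND b_j| / |b_i OR b_j|``.  A pair of all-zero
    fingerprints (0/0) is defined as similarity 0 and logged.
    """
    bits = fingerprints.bits.astype(np.float64)
    inter = bits @ bits.T
    popcount = bits.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - inter
    empty = popcount == 0
    if empty.any():
        logger.warning(
            "%d drug(s) have empty fingerprints; their Jaccard similarity "
            "is defined as 0: %s",
            int(empty.sum()),
            [d for d, e in zip(fingerprints.drug_ids, empty) if e],
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(list(fingerprints.drug_ids), sim)


def bipartite_projection_similarity(assoc: AssociationMatrix) -> SimilarityMatrix:
    """Drug-drug similarity by two-step resource allocation through proteins.

    Each drug spreads one unit of resource to its associated proteins in
    proportion to the association weights, and each protein returns its
    share to its associated drugs the same way.  The fraction of drug *i*'s
    resource that ends at drug *j* is

        S_ij = (1 / k(d_j)) * sum_l a_il * a_jl / k(p_l)

    with ``k`` the weighted degree.  Drugs sharing no protein get 0, as do
    degenerate (degree-zero) drugs or proteins.  The raw flow matrix is
    asymmetric; the returned :class:`SimilarityMatrix` stores the
    symmetrized average while :func:`bipartite_projection_flow` exposes the
    directed values.
    """
    flow = bipartite_projection_flow(assoc)
    sym = (flow + flow.T) / 2.0
    return SimilarityMatrix(list(assoc.drug_ids), sym)


def bipartite_projection_flow(assoc: AssociationMatrix) -> np.ndarray:
    """Directed resource-allocation flow matrix (row i -> column j)."""
    a = assoc.scores
    kd = assoc.drug_degrees()
    kp = assoc.protein_degrees()
    inv_kp = np.where(kp > 0, 1.0 / np.where(kp > 0, kp, 1.0), 0.0)
    inv_kd = np.where(kd > 0, 1.0 / np.where(kd > 0, kd, 1.0), 0.0)
    # flow[i, j] = (1/k(d_j)) sum_l a_il a_jl / k(p_l)
    flow = (a * inv_kp[None, :]) @ a.T * inv_kd[None, :]
    return flow


@dataclass
class AlignmentParams:
    """Smith-Waterman scoring scheme.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Defaults:
    BLOSUM62, open 10, extend 4.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 4.0


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def sequence_similarity(
    annotation: ProteinAnnotation,
    scoring: AlignmentParams | None = None,
) -> SimilarityMatrix:
    """Normalized Smith-Waterman similarity of protein sequences.

    ``S_ij = SW(i, j) / sqrt(SW(i, i) * SW(j, j))`` under the configured
    substitution matrix and affine gap penalties, clipped to [0, 1].
    """
    params = scoring or AlignmentParams()
    aligner = _make_aligner(params)
    seqs = [s.upper() for s in annotation.sequences]
    n = len(seqs)
    self_scores = np.array([aligner.score(s, s) for s in seqs])
    for pid, sc in zip(annotation.protein_ids, self_scores):
        if sc <= 0:
            raise ValueError(
                f"protein {pid!r} has non-positive self-alignment score {sc}"
            )
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            raw = aligner.score(seqs[i], seqs[j])
            sim[i, j] = sim[j, i] = max(raw, 0.0) / np.sqrt(
                self_scores[i] * self_scores[j]
            )
    np.clip(sim, 0.0, 1.0, out=sim)
    return SimilarityMatrix(list(annotation.protein_ids), sim)


def _semantic_values(term: str, dag: OntologyDAG) -> dict[str, float]:
    """Wang S-values: contribution of each ancestor to *term*'s semantics.

    S(term) = 1; S(t) = max over weighted child edges of w_e * S(child),
    maximized over all paths from *term* up to t.
    """
    sval = {term: 1.0}
    # process terms in decreasing S-value order (Dijkstra-like on max-product)
    import heapq

    heap = [(-1.0, term)]
    done: set[str] = set()
    while heap:
        neg_s, t = heapq.heappop(heap)
        if t in done:
            continue
        done.add(t)
        s = -neg_s
        for parent, w in dag.parents(t):
            cand = s * w
            if cand > sval.get(parent, 0.0):
                sval[parent] = cand
                heapq.heappush(heap, (-cand, parent))
    return sval


def wang_term_similarity(a: str, b: str, dag: OntologyDAG) -> float:
    """Wang's graph-based semantic similarity between two ontology terms."""
    sa = _semantic_values(a, dag)
    sb = _semantic_values(b, dag)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    num = sum(sa[t] + sb[t] for t in common)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


def _best_match_average(
    terms_a: list[str], terms_b: list[str], sim: np.ndarray
) -> float:
    """Best-match-average aggregation of a term-pair similarity matrix."""
    if not terms_a or not terms_b:
        return 0.0
    row_best = sim.max(axis=1)
    col_best = sim.max(axis=0)
    return (row_best.sum() + col_best.sum()) / (len(terms_a) + len(terms_b))


def go_semantic_similarity(
    annotation: ProteinAnnotation,
    dag: OntologyDAG,
    method: str = "wang",
    combine: str = "bma",
) -> SimilarityMatrix:
    """Pairwise protein similarity from GO annotation sets.

    Term-term similarity is Wang's measure (semantic contributions over
    common ancestors, relation-weighted).  Term sets are aggregated by
    best-match average.  Similarities are computed per ontology namespace
    (biological process / molecular function / cellular component when the
    DAG declares them) and averaged over the namespaces in which both
    proteins carry annotations.  Proteins with no resolvable term have
    similarity 0 to everything (logged).
    """
    if method != "wang":
        raise ValueError(f"unknown term-similarity method {method!r}")
    if combine != "bma":
        raise ValueError(f"unknown aggregation {combine!r}")
    annotation = annotation.resolve_terms(dag)
    n = annotation.n_proteins

    for pid, terms in zip(annotation.protein_ids, annotation.go_terms):
        if not terms:
            logger.warning(
                "protein %s has no resolvable GO terms; similarity 0 to all", pid
            )

    # cache S-values once per distinct term
    all_terms = sorted(set().union(*annotation.go_terms) if n else set())
    svals = {t: _semantic_values(t, dag) for t in all_terms}
    term_ns = {t: dag.namespace(t) for t in all_terms}
    sv_sum = {t: sum(svals[t].values()) for t in all_terms}

    def term_sim(a: str, b: str) -> float:
        sa, sb = svals[a], svals[b]
        if len(sb) < len(sa):
            sa, sb = sb, sa
        num = 0.0
        for t, v in sa.items():
            w = sb.get(t)
            if w is not None:
                num += v + w
        if num == 0.0:
            return 0.0
        return num / (sv_sum[a] + sv_sum[b])

    namespaces = sorted({term_ns[t] for t in all_terms})
    by_ns = [
        [sorted(t for t in terms if term_ns[t] == ns) for terms in annotation.go_terms]
        for ns in namespaces
    ]

    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            vals = []
            for ns_terms in by_ns:
                ta, tb = ns_terms[i], ns_terms[j]
                if ta and tb:
                    mat = np.array([[term_sim(a, b) for b in tb] for a in ta])
                    vals.append(_best_match_average(ta, tb, mat))
            if vals:
                sim[i, j] = sim[j, i] = float(np.mean(vals))
    np.clip(sim, 0.0, 1.0, out=sim)
    return SimilarityMatrix(list(annotation.protein_ids), sim)


def disjunction_integrate(
    s1: SimilarityMatrix, s2: SimilarityMatrix
) -> SimilarityMatrix:
    """Fuse two similarity matrices by probability disjunction (noisy-OR).

    ``S_ij = 1 - (1 - s1_ij)(1 - s2_ij)``; always >= max(s1_ij, s2_ij).
    """
    if s1.ids != s2.ids:
        raise ValueError("similarity matrices have mismatched identifiers")
    for name, m in (("first", s1), ("second", s2)):
        if m.values.min(initial=0.0) < 0 or m.values.max(initial=0.0) > 1:
            bad = np.unravel_index(
                int(np.argmax((m.values < 0) | (m.values > 1))), m.values.shape
            )
            raise ValueError(
                f"{name} matrix entry out of [0,1] at pair "
                f"({m.ids[bad[0]]!r}, {m.ids[bad[1]]!r})"
            )
    fused = 1.0 - (1.0 - s1.values) * (1.0 - s2.values)
    return SimilarityMatrix(list(s1.ids), fused)
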