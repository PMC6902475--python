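"""Benchmark construction: target filtering, universe expansion, negative
sampling, and feature-matrix assembly.

Positive combinations come from a curated list; negatives are drawn
uniformly from the drug universe (excluding every positive, as a set) to
balance the classes.  Per drug, low-confidence targets are removed
(threshold on the [0,1]-rescaled confidence) and only the top-k remaining
targets are kept.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationMatrix,
    BenchmarkSet,
    CombinationSample,
    FingerprintSet,
    ProteinAnnotation,
)
from .network import TransitionMatrix
from .rwr import build_seed_distribution, build_seed_set, random_walk_restart

logger = logging.getLogger(__name__)

__all__ = [
    "filter_targets",
    "expand_drug_universe",
    "sample_negatives",
    "assemble_feature_matrix",
    "assemble_ontology_feature_matrix",
]


def filter_targets(
    raw_assoc: AssociationMatrix, threshold: float = 0.5, top_k: int = 3
) -> AssociationMatrix:
    """Keep, per drug, the *top_k* highest-confidence targets above *threshold*.

    Associations below *threshold* are dropped first; of the survivors only
    the *top_k* best are retained (all of them when fewer survive).  Ties at
    the k-th score are broken by protein input order.  Idempotent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1] (rescaled confidence)")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scores = raw_assoc.scores
    out = np.zeros_like(scores)
    for i in range(scores.shape[0]):
        survivors = np.flatnonzero(scores[i] >= threshold)
        if survivors.size > top_k:
            # stable sort on (-score, column) keeps input order among ties
            order = np.argsort(-scores[i, survivors], kind="stable")
            survivors = survivors[order[:top_k]]
        out[i, survivors] = scores[i, survivors]
    return AssociationMatrix(
        list(raw_assoc.drug_ids), list(raw_assoc.protein_ids), out
    )


def expand_drug_universe(
    seed_drugs: Sequence[str],
    drug_drug_scores: Mapping[tuple[str, str], float] | pd.DataFrame,
    k: int = 3,
) -> list[str]:
    """Union of *seed_drugs* and each seed's top-*k* scored neighbors.

    *drug_drug_scores* is either a mapping ``(drug_a, drug_b) -> score`` or
    a DataFrame with columns (drug_a, drug_b, score); pairs are treated as
    undirected.  Order is deterministic: seeds first (input order), then
    each seed's neighbors by descending score, ties by neighbor ID;
    duplicates dropped on first appearance.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    neighbors: dict[str, list[tuple[float, str]]] = {}
    if isinstance(drug_drug_scores, pd.DataFrame):
        items = (
            ((str(a), str(b)), float(s))
            for a, b, s in drug_drug_scores.itertuples(index=False)
        )
    else:
        items = iter(drug_drug_scores.items())
    for (a, b), score in items:
        neighbors.setdefault(a, []).append((-score, b))
        neighbors.setdefault(b, []).append((-score, a))

    out: dict[str, None] = dict.fromkeys(seed_drugs)
    if k > 0:
        for seed in seed_drugs:
            for _negscore, nb in sorted(neighbors.get(seed, []))[:k]:
                out.setdefault(nb, None)
    return list(out)


def sample_negatives(
    universe: Sequence[str],
    n: int,
    arity: int = 2,
    exclude: Iterable[frozenset[str]] = (),
    seed: int = 0,
) -> list[CombinationSample]:
    """Draw *n* distinct unordered drug sets of size *arity*, none excluded.

    Reproducible from *seed*; raises before emitting partial output if *n*
    distinct non-excluded sets cannot exist in the universe.
    """
    universe = list(dict.fromkeys(universe))
    if arity < 2:
        raise ValueError("arity must be >= 2")
    excluded = {frozenset(e) for e in exclude}
    import math

    n_possible = math.comb(len(universe), arity)
    n_excluded_in = sum(1 for e in excluded if len(e) == arity and e <= set(universe))
    if n > n_possible - n_excluded_in:
        raise ValueError(
            f"cannot draw {n} distinct {arity}-drug sets from a "
            f"{len(universe)}-drug universe with {n_excluded_in} exclusions"
        )
    rng = np.random.default_rng(seed)
    picked: set[frozenset[str]] = set()
    samples: list[CombinationSample] = []
    # rejection sampling; fall back to exhaustive enumeration if it stalls
    max_tries = 50 * max(n, 1) + 1000
    tries = 0
    while len(samples) < n and tries < max_tries:
        tries += 1
        combo = frozenset(rng.choice(len(universe), size=arity, replace=False))
        combo = frozenset(universe[i] for i in combo)
        if combo in excluded or combo in picked:
            continue
        picked.add(combo)
        samples.append(CombinationSample(drug_ids=combo, label=0))
    if len(samples) < n:
        for idxs in itertools.combinations(range(len(universe)), arity):
            combo = frozenset(universe[i] for i in idxs)
            if combo in excluded or combo in picked:
                continue
            picked.add(combo)
            samples.append(CombinationSample(drug_ids=combo, label=0))
            if len(samples) == n:
                break
    return samples


def assemble_feature_matrix(
    bench: BenchmarkSet,
    T: TransitionMatrix,
    assoc: AssociationMatrix,
    eta: float = 0.9,
    alpha: float = 0.2,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """One converged RWR feature vector per combination sample.

    Returns a DataFrame indexed by a deterministic combination ID
    (sorted drug IDs joined by ';'), with one column per network node plus
    a trailing ``label`` column.  Rows are computed independently, so
    permuting the sample order only permutes rows.
    """
    rows = []
    index = []
    labels = []
    cache: dict[frozenset[str], np.ndarray] = {}
    for sample in bench.samples:
        combo_id = ";".join(sorted(sample.drug_ids))
        vec = cache.get(sample.drug_ids)
        if vec is None:
            p0 = build_seed_distribution(sorted(sample.drug_ids), assoc, eta=eta)
            try:
                fv = random_walk_restart(T, p0, alpha=alpha, tol=tol, max_iter=max_iter)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"propagation failed for combination {combo_id!r}: {exc}"
                ) from exc
            vec = fv.vector
            cache[sample.drug_ids] = vec
        rows.append(vec)
        index.append(combo_id)
        labels.append(sample.label)
    feats = pd.DataFrame(np.asarray(rows), index=index, columns=T.node_ids)
    feats["label"] = labels
    return feats


def assemble_ontology_feature_matrix(
    bench: BenchmarkSet,
    fingerprints: FingerprintSet,
    assoc: AssociationMatrix,
    annotation: ProteinAnnotation,
) -> pd.DataFrame:
    """Primary ontology features: fingerprint union + GO-term union.

    The baseline representation that skips network propagation entirely:
    per combination, the bitwise OR of its drugs' fingerprints concatenated
    with a binary indicator over all GO terms annotating any of the
    combination's (filtered) target proteins.  Same row indexing and
    trailing ``label`` column as :func:`assemble_feature_matrix`.
    """
    if fingerprints.drug_ids != assoc.drug_ids:
        raise ValueError("fingerprint and association drug IDs differ")
    if annotation.protein_ids != assoc.protein_ids:
        raise ValueError("annotation and association protein IDs differ")
    all_terms = sorted(set().union(*annotation.go_terms))
    term_col = {t: k for k, t in enumerate(all_terms)}
    nbits = fingerprints.n_bits
    rows, index, labels = [], [], []
    for sample in bench.samples:
        combo_id = ";".join(sorted(sample.drug_ids))
        seeds = build_seed_set(sorted(sample.drug_ids), assoc)
        vec = np.zeros(nbits + len(all_terms))
        vec[:nbits] = fingerprints.bits[seeds.drug_indices].max(axis=0)
        for j in seeds.protein_indices:
            for t in annotation.go_terms[j]:
                vec[nbits + term_col[t]] = 1.0
        rows.append(vec)
        index.append(combo_id)
        labels.append(sample.label)
    cols = [f"bit{i}" for i in range(nbits)] + all_terms
    feats = pd.DataFrame(np.asarray(rows), index=index, columns=cols)
    feats["label"] = labels
    return feats
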