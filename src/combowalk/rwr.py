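"""Random walk with restart: seed distributions, propagation, ranking.

For a drug combination, the seed nodes are its drugs plus the union of
their (filtered) target proteins.  The initial distribution P0 puts mass
eta on the drug layer (split equally over the seed drugs) and 1 - eta on
the protein layer (split equally over the seed proteins).  Propagation

    P(t+1) = (1 - alpha) * T' P(t) + alpha * P0

iterates to an L1 fixed point; the converged distribution over all
n + m nodes is the combination's feature vector.  Mass sitting on fully
dangling nodes is re-seeded through P0 each step, so total probability is
conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .datatypes import AssociationMatrix
from .network import TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "InitialDistribution",
    "FeatureVector",
    "build_seed_set",
    "build_seed_distribution",
    "random_walk_restart",
    "closed_form_stationary",
    "rank_nodes",
]


@dataclass
class SeedSet:
    """Seed drugs of a combination and their associated proteins."""

    drug_indices: list[int]
    protein_indices: list[int]

    def __post_init__(self) -> None:
        if not self.drug_indices:
            raise ValueError("seed set needs at least one drug")
        if len(set(self.drug_indices)) != len(self.drug_indices):
            raise ValueError("duplicate seed drug index")
        if len(set(self.protein_indices)) != len(self.protein_indices):
            raise ValueError("duplicate seed protein index")


@dataclass
class InitialDistribution:
    """Restart distribution P0 over the n + m network nodes."""

    vector: np.ndarray
    eta: float
    n_drugs: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.min(initial=0.0) < 0:
            raise ValueError("P0 entries must be non-negative")
        if abs(self.vector.sum() - 1.0) > 1e-12:
            raise ValueError("P0 must sum to 1")


@dataclass
class FeatureVector:
    """Converged RWR distribution plus convergence diagnostics."""

    vector: np.ndarray
    iterations: int
    residual: float

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)


def build_seed_set(
    combo: Iterable[str], assoc: AssociationMatrix
) -> SeedSet:
    """Resolve a combination's drugs and the union of their target proteins."""
    drugs = list(dict.fromkeys(combo))
    if not drugs:
        raise ValueError("empty drug combination")
    index = {d: i for i, d in enumerate(assoc.drug_ids)}
    try:
        drug_idx = [index[d] for d in drugs]
    except KeyError as exc:
        raise KeyError(f"unknown drug ID {exc.args[0]!r} in combination") from None
    prot_mask = (assoc.scores[drug_idx] > 0).any(axis=0)
    return SeedSet(drug_idx, list(np.flatnonzero(prot_mask)))


def build_seed_distribution(
    combo: Iterable[str],
    assoc: AssociationMatrix,
    eta: float = 0.9,
) -> InitialDistribution:
    """Build P0 for a combination: eta/|drugs| per seed drug, (1-eta)/|proteins|
    per seed protein.  If no seed drug has any association, the full unit
    mass goes to the drug layer (eta is ignored, logged)."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0,1]; got {eta}")
    seeds = build_seed_set(combo, assoc)
    n, m = assoc.n_drugs, assoc.n_proteins
    p0 = np.zeros(n + m)
    if seeds.protein_indices:
        p0[seeds.drug_indices] = eta / len(seeds.drug_indices)
        p0[[n + j for j in seeds.protein_indices]] = (1.0 - eta) / len(
            seeds.protein_indices
        )
    else:
        logger.warning(
            "combination %s has no associated proteins; placing all seed "
            "mass on the drug layer (eta ignored)",
            sorted(dict.fromkeys(combo)),
        )
        p0[seeds.drug_indices] = 1.0 / len(seeds.drug_indices)
    return InitialDistribution(vector=p0, eta=eta, n_drugs=n)


def _step(
    tmat: np.ndarray,
    dangling: np.ndarray,
    p: np.ndarray,
    p0: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """One propagation step with dangling mass re-seeded through P0."""
    moved = tmat.T @ p
    lost = p[dangling].sum() if dangling.any() else 0.0
    return (1.0 - alpha) * (moved + lost * p0) + alpha * p0


def random_walk_restart(
    T: TransitionMatrix,
    P0: InitialDistribution,
    alpha: float = 0.2,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FeatureVector:
    """Iterate the restart walk to its L1 fixed point.

    Raises ``RuntimeError`` (reporting the final residual) if *max_iter*
    steps do not reach *tol*.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"restart probability alpha must be in (0,1]; got {alpha}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    p0 = P0.vector
    if p0.shape[0] != T.n_nodes:
        raise ValueError("P0 length does not match network size")
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = _step(T.matrix, T.dangling, p, p0, alpha)
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return FeatureVector(vector=p, iterations=it, residual=residual)
    raise RuntimeError(
        f"random walk did not converge in {max_iter} iterations "
        f"(final L1 residual {residual:.3e} > tol {tol:.3e})"
    )


def closed_form_stationary(
    T: TransitionMatrix,
    P0: InitialDistribution,
    alpha: float = 0.2,
    max_nodes: int = 2000,
) -> FeatureVector:
    """Direct linear solve of the fixed point P = (1-a)(T'P + dangling) + a P0.

    With dangling mass teleported to P0, the fixed point satisfies

        (I - (1-a) (T' + p0 w')) P = a P0

    where w is the dangling-row indicator.  Intended as an exact oracle for
    small networks (guarded at *max_nodes*).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"restart probability alpha must be in (0,1]; got {alpha}")
    nm = T.n_nodes
    if nm > max_nodes:
        raise ValueError(f"dense solve guarded at {max_nodes} nodes; got {nm}")
    p0 = P0.vector
    w = T.dangling.astype(float)
    A = np.eye(nm) - (1.0 - alpha) * (T.matrix.T + np.outer(p0, w))
    p = np.linalg.solve(A, alpha * p0)
    residual = float(np.abs(_step(T.matrix, T.dangling, p, p0, alpha) - p).sum())
    return FeatureVector(vector=p, iterations=0, residual=residual)


def rank_nodes(
    fv: FeatureVector,
    T: TransitionMatrix,
    layer: Literal["drug", "protein"],
) -> list[str]:
    """IDs of one layer sorted by descending probability.

    Ties are broken by input ID order, so the ranking is deterministic.
    """
    n = T.n_drugs
    if layer == "drug":
        ids, probs = T.drug_ids, fv.vector[:n]
    elif layer == "protein":
        ids, probs = T.protein_ids, fv.vector[n:]
    else:
        raise ValueError(f"layer must be 'drug' or 'protein'; got {layer!r}")
    order = np.argsort(-probs, kind="stable")
    return [ids[i] for i in order]
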