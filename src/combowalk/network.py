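"""Heterogeneous drug-protein network assembly and its block transition matrix.

The network has two node layers — drugs and proteins — joined by
within-layer similarity edges (S^(d), S^(p)) and cross-layer association
edges (A).  The random-walk transition matrix is the 2x2 block matrix

    T = [[T_dd, T_dp],
         [T_pd, T_pp]]

where a walker at a drug with known targets crosses to the protein layer
with probability lambda and stays among drugs with probability 1 - lambda
(and symmetrically for proteins).  Rows are from-node -> to-node; the walk
iteration uses the transpose.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HeteroNetwork",
    "TransitionMatrix",
    "build_transition_matrix",
    "stochasticity_report",
    "StochasticityReport",
]


@dataclass
class HeteroNetwork:
    """Drug layer + protein layer + bipartite associations."""

    drug_sim: SimilarityMatrix
    protein_sim: SimilarityMatrix
    assoc: AssociationMatrix

    def __post_init__(self) -> None:
        if self.drug_sim.ids != self.assoc.drug_ids:
            raise ValueError("drug similarity and association drug IDs differ")
        if self.protein_sim.ids != self.assoc.protein_ids:
            raise ValueError("protein similarity and association protein IDs differ")
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("network needs at least one drug and one protein")

    @property
    def n_drugs(self) -> int:
        return self.assoc.n_drugs

    @property
    def n_proteins(self) -> int:
        return self.assoc.n_proteins

    @property
    def drug_ids(self) -> list[str]:
        return self.assoc.drug_ids

    @property
    def protein_ids(self) -> list[str]:
        return self.assoc.protein_ids

    @property
    def node_ids(self) -> list[str]:
        return list(self.drug_ids) + list(self.protein_ids)


@dataclass
class TransitionMatrix:
    """Row-stochastic block transition matrix of the heterogeneous network.

    ``matrix`` is dense (n+m, n+m), rows from-node -> to-node.  Rows with no
    outgoing mass (fully dangling nodes) are all-zero and listed in
    ``dangling``; at propagation time their mass is redistributed to the
    restart distribution.
    """

    matrix: np.ndarray
    drug_ids: list[str]
    protein_ids: list[str]
    lam: float
    dangling: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    dangling_policy: str = "teleport-to-restart"

    def __post_init__(self) -> None:
        nm = self.n_drugs + self.n_proteins
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (nm, nm):
            raise ValueError(f"matrix must be ({nm},{nm}); got {self.matrix.shape}")
        if self.dangling.size == 0:
            self.dangling = self.matrix.sum(axis=1) == 0
        if self.matrix.min(initial=0.0) < 0:
            raise ValueError("transition probabilities must be non-negative")
        rowsums = self.matrix.sum(axis=1)
        bad = ~self.dangling & (np.abs(rowsums - 1.0) > 1e-12)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-dangling row {self.node_ids[i]!r} sums to {rowsums[i]!r}"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_proteins

    @property
    def node_ids(self) -> list[str]:
        return list(self.drug_ids) + list(self.protein_ids)

    def block(self, name: str) -> np.ndarray:
        """Return a view of one of the four blocks: 'dd', 'dp', 'pd', 'pp'."""
        n = self.n_drugs
        sl = {"d": slice(0, n), "p": slice(n, None)}
        return self.matrix[sl[name[0]], sl[name[1]]]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write nonzero entries as (from_id, to_id, probability) TSV, plus a
        JSON sidecar with lambda and the dangling policy."""
        path = Path(path)
        ids = self.node_ids
        rows, cols = np.nonzero(self.matrix)
        with open(path, "w") as fh:
            fh.write("from_id\tto_id\tprobability\n")
            for r, c in zip(rows, cols):
                fh.write(f"{ids[r]}\t{ids[c]}\t{self.matrix[r, c]:.17g}\n")
        side = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        side.write_text(
            json.dumps(
                {
                    "lambda": self.lam,
                    "dangling_policy": self.dangling_policy,
                    "n_drugs": self.n_drugs,
                    "n_proteins": self.n_proteins,
                },
                indent=2,
            )
        )


def _normalize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize; return (normalized, zero-row mask)."""
    sums = m.sum(axis=1)
    zero = sums == 0
    out = np.where(zero[:, None], 0.0, m / np.where(zero, 1.0, sums)[:, None])
    return out, zero


def build_transition_matrix(net: HeteroNetwork, lam: float = 0.7) -> TransitionMatrix:
    """Build the block transition matrix for jump probability *lam*.

    Within-layer blocks are row-normalized similarities (diagonal zeroed
    first: no self-loops) scaled by (1 - lam) for nodes that have
    associations; cross-layer blocks are row-normalized association weights
    scaled by lam.  A node with associations but zero off-diagonal
    similarity mass routes all its mass through associations (effective
    lam = 1 for that row, logged).  Fully dangling nodes keep an all-zero
    row, flagged for teleporting at propagation time.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"jump probability lambda must be in [0,1]; got {lam}")
    n, m = net.n_drugs, net.n_proteins
    a = net.assoc.scores

    sd = net.drug_sim.values.copy()
    np.fill_diagonal(sd, 0.0)
    sp = net.protein_sim.values.copy()
    np.fill_diagonal(sp, 0.0)

    sd_norm, sd_zero = _normalize_rows(sd)
    sp_norm, sp_zero = _normalize_rows(sp)
    adp_norm, d_noassoc = _normalize_rows(a)
    apd_norm, p_noassoc = _normalize_rows(a.T)

    d_has = ~d_noassoc
    p_has = ~p_noassoc

    # drug rows: similarity mass scaled by (1-lam) when associations exist
    d_sim_factor = np.where(d_has, 1.0 - lam, 1.0)
    p_sim_factor = np.where(p_has, 1.0 - lam, 1.0)
    t_dd = sd_norm * d_sim_factor[:, None]
    t_pp = sp_norm * p_sim_factor[:, None]
    t_dp = adp_norm * (lam * d_has)[:, None]
    t_pd = apd_norm * (lam * p_has)[:, None]

    # nodes with associations but no similarity mass: all mass via associations
    d_assoc_only = d_has & sd_zero
    p_assoc_only = p_has & sp_zero
    if d_assoc_only.any():
        logger.info(
            "%d drug(s) have associations but no similarity mass; routing all "
            "mass through associations: %s",
            int(d_assoc_only.sum()),
            [d for d, f in zip(net.drug_ids, d_assoc_only) if f],
        )
        t_dp[d_assoc_only] = adp_norm[d_assoc_only]
    if p_assoc_only.any():
        logger.info(
            "%d protein(s) have associations but no similarity mass; routing "
            "all mass through associations: %s",
            int(p_assoc_only.sum()),
            [p for p, f in zip(net.protein_ids, p_assoc_only) if f],
        )
        t_pd[p_assoc_only] = apd_norm[p_assoc_only]

    t = np.zeros((n + m, n + m))
    t[:n, :n] = t_dd
    t[:n, n:] = t_dp
    t[n:, :n] = t_pd
    t[n:, n:] = t_pp

    dangling = np.concatenate([d_noassoc & sd_zero, p_noassoc & sp_zero])
    if dangling.any():
        logger.info("%d fully dangling node(s) flagged", int(dangling.sum()))
    # wash out normalization round-off on non-dangling rows
    sums = t.sum(axis=1)
    live = ~dangling
    t[live] /= sums[live, None]

    return TransitionMatrix(
        matrix=t,
        drug_ids=list(net.drug_ids),
        protein_ids=list(net.protein_ids),
        lam=lam,
        dangling=dangling,
    )


@dataclass
class StochasticityReport:
    """Per-row diagnostics of a transition matrix."""

    row_sum_deviation: np.ndarray
    dangling: np.ndarray
    drug_block_mass: np.ndarray
    protein_block_mass: np.ndarray
    node_ids: list[str]

    @property
    def n_dangling(self) -> int:
        return int(self.dangling.sum())

    @property
    def max_deviation(self) -> float:
        live = ~self.dangling
        return float(self.row_sum_deviation[live].max(initial=0.0))


def stochasticity_report(T: TransitionMatrix) -> StochasticityReport:
    """Row-sum deviations, dangling flags, and per-row block mass split."""
    n = T.n_drugs
    rowsums = T.matrix.sum(axis=1)
    return StochasticityReport(
        row_sum_deviation=np.abs(rowsums - 1.0),
        dangling=T.dangling.copy(),
        drug_block_mass=T.matrix[:, :n].sum(axis=1),
        protein_block_mass=T.matrix[:, n:].sum(axis=1),
        node_ids=T.node_ids,
    )
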