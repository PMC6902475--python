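"""Core in-memory containers for the drug-protein heterogeneous network pipeline.

All containers are thin dataclasses around numpy arrays / pandas-friendly
structures with validation in ``__post_init__``.  Identifier order is
significant everywhere: it fixes matrix row/column order and the node order
of feature vectors, and is preserved from the input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: amino-acid alphabet accepted in protein sequences (X = unknown residue)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: fingerprint length of the default binary substructure scheme
DEFAULT_FINGERPRINT_LENGTH = 880


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class FingerprintSet:
    """Binary substructure fingerprints for an ordered set of drugs.

    Parameters
    ----------
    drug_ids : list of str
        Drug identifiers; order fixes row order of ``bits``.
    bits : ndarray of shape (n_drugs, n_bits)
        0/1 matrix; one row per drug.
    """

    drug_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValueError(
                f"bits must be (n_drugs, n_bits); got {self.bits.shape} "
                f"for {len(self.drug_ids)} drugs"
            )
        _check_unique(self.drug_ids, "drug")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        self.bits = self.bits.astype(np.uint8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]


@dataclass
class ProteinAnnotation:
    """Protein sequences and GO annotations for an ordered protein set."""

    protein_ids: list[str]
    sequences: list[str]
    go_terms: list[set[str]]

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if len(self.sequences) != n or len(self.go_terms) != n:
            raise ValueError("protein_ids, sequences and go_terms must align")
        _check_unique(self.protein_ids, "protein")
        for pid, seq in zip(self.protein_ids, self.sequences):
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq.upper()) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"invalid residues {sorted(bad)} in sequence of {pid!r}"
                )
        self.go_terms = [set(t) for t in self.go_terms]

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def resolve_terms(self, dag: "OntologyDAG") -> "ProteinAnnotation":
        """Return a copy with GO terms not present in *dag* dropped (logged)."""
        resolved = []
        for pid, terms in zip(self.protein_ids, self.go_terms):
            missing = {t for t in terms if t not in dag.terms}
            if missing:
                logger.warning(
                    "protein %s: dropping %d GO term(s) not in ontology: %s",
                    pid, len(missing), sorted(missing),
                )
            resolved.append(terms - missing)
        return ProteinAnnotation(
            list(self.protein_ids), list(self.sequences), resolved
        )


@dataclass
class OntologyDAG:
    """A gene-ontology-like DAG with relation-weighted child->parent edges.

    ``edges`` are (child, parent, relation) triples; ``relation_weights``
    maps relation names (``is_a``, ``part_of``, ...) to semantic
    contribution factors in (0, 1).  Relations without a weight are ignored
    when walking to ancestors.
    """

    terms: set[str]
    edges: list[tuple[str, str, str]]
    relation_weights: dict[str, float] = field(
        default_factory=lambda: {"is_a": 0.8, "part_of": 0.6}
    )
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent, _rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(
                    f"edge ({child!r}, {parent!r}) references unknown term"
                )
        for rel, w in self.relation_weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"relation weight for {rel!r} must be in (0,1)")
        self._parents: dict[str, list[tuple[str, float]]] = {}
        for child, parent, rel in self.edges:
            w = self.relation_weights.get(rel)
            if w is not None:
                self._parents.setdefault(child, []).append((parent, w))
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        # Kahn-style DFS over weighted parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.terms, WHITE)

        def visit(t: str) -> None:
            stack = [(t, iter(self._parents.get(t, ())))]
            color[t] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent, _w in it:
                    if color[parent] == GREY:
                        raise ValueError(f"ontology contains a cycle through {parent!r}")
                    if color[parent] == WHITE:
                        color[parent] = GREY
                        stack.append((parent, iter(self._parents.get(parent, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

        for t in self.terms:
            if color[t] == WHITE:
                visit(t)

    def parents(self, term: str) -> list[tuple[str, float]]:
        """Weighted (parent, contribution-factor) pairs of *term*."""
        return self._parents.get(term, [])

    def namespace(self, term: str) -> str:
        return self.namespaces.get(term, "default")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values must be ({n},{n}); got {self.values.shape}"
            )
        _check_unique(self.ids, "node")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError("similarity matrix is not symmetric within 1e-12")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            bad = np.unravel_index(np.argmax(np.abs(self.values - 0.5)), self.values.shape)
            raise ValueError(
                f"similarity out of [0,1] at pair ({self.ids[bad[0]]!r}, {self.ids[bad[1]]!r})"
            )
        np.clip(self.values, 0.0, 1.0, out=self.values)
        # exact symmetry after clipping
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class AssociationMatrix:
    """Drug-protein association confidences on a [0, 1] scale.

    ``scores`` is (n_drugs, m_proteins), non-negative.  ``from_raw`` rescales
    STITCH-style 0-1000 combined scores by dividing by 1000; scores are used
    as continuous weights, never binarized.
    """

    drug_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray
    raw_scale: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        shape = (len(self.drug_ids), len(self.protein_ids))
        if self.scores.shape != shape:
            raise ValueError(f"scores must be {shape}; got {self.scores.shape}")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.protein_ids, "protein")
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("association scores must be non-negative")
        if not self.raw_scale and self.scores.size and self.scores.max() > 1 + 1e-12:
            raise ValueError("rescaled association scores must be <= 1")

    @classmethod
    def from_raw(
        cls, drug_ids: list[str], protein_ids: list[str], raw_scores: np.ndarray
    ) -> "AssociationMatrix":
        """Build from raw 0-1000 confidence scores (rescaled to [0, 1])."""
        raw = np.asarray(raw_scores, dtype=float)
        if raw.size and raw.max() > 1000:
            raise ValueError("raw confidence scores must be <= 1000")
        return cls(drug_ids, protein_ids, raw / 1000.0)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def drug_degrees(self) -> np.ndarray:
        """Weighted degree of each drug (row sums of scores)."""
        return self.scores.sum(axis=1)

    def protein_degrees(self) -> np.ndarray:
        """Weighted degree of each protein (column sums of scores)."""
        return self.scores.sum(axis=0)


@dataclass(frozen=True)
class CombinationSample:
    """An unordered combination of >= 2 drugs with a binary effectiveness label."""

    drug_ids: frozenset[str]
    label: int

    def __post_init__(self) -> None:
        if len(self.drug_ids) < 2:
            raise ValueError("a combination needs at least 2 distinct drugs")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class BenchmarkSet:
    """A labeled set of combination samples with sampling provenance."""

    samples: list[CombinationSample]
    rng_seed: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        pos = {s.drug_ids for s in self.samples if s.label == 1}
        neg = {s.drug_ids for s in self.samples if s.label == 0}
        overlap = pos & neg
        if overlap:
            raise ValueError(
                f"{len(overlap)} combination(s) appear as both positive and negative"
            )

    @property
    def n_positive(self) -> int:
        return sum(s.label for s in self.samples)

    @property
    def n_negative(self) -> int:
        return len(self.samples) - self.n_positive
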