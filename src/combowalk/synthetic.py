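"""Synthetic drug-protein universe with a planted combination signal.

The generator emulates the five real inputs — fingerprints, protein
sequences, GO annotations, an ontology DAG, and scored drug-protein
associations — at desk scale, with a modular structure:

* proteins are partitioned into modules; proteins of one module share a
  mutated copy of a common core sequence and draw GO terms from
  module-specific branches of a generated DAG;
* drugs belong to modules and share module-specific fingerprint bit blocks;
* associations link drugs mostly to their own module's proteins with
  confidence ~ U(0.5, 0.9), plus uniform cross-module noise;
* a reserved pool of *bridge* proteins sits between complementary module
  pairs; every drug is strongly associated (confidence >= 0.85, surviving
  the top-k target filter) with a couple of bridges from its pair's pool.

Effective combinations are cross-module drug pairs that SHARE a bridge
protein, so the signal lives in the network topology (joint propagation
flow through the shared neighborhood), not in the raw fingerprints or GO
unions — which is exactly the mechanism the propagation features are meant
to capture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AssociationMatrix,
    BenchmarkSet,
    CombinationSample,
    FingerprintSet,
    OntologyDAG,
    ProteinAnnotation,
)

__all__ = ["SyntheticUniverseSpec", "SyntheticUniverse", "generate_universe", "plant_benchmark"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NAMESPACES = ("biological_process", "molecular_function")


@dataclass(frozen=True)
class SyntheticUniverseSpec:
    """Parameters of the synthetic universe.

    ``assoc_density`` is the per-(drug, own-module-protein) association
    probability; ``noise`` scales cross-module leakage (spurious
    associations, fingerprint bit flips, off-module GO terms).
    """

    n_drugs: int = 150
    m_proteins: int = 120
    fingerprint_length: int = 880
    n_modules: int = 6
    assoc_density: float = 0.3
    noise: float = 0.2
    rng_seed: int = 0
    bridge_fraction: float = 0.1
    bridges_per_drug: int = 2
    seq_core_length: int = 150
    seq_mutation_rate: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.m_proteins, self.fingerprint_length, self.n_modules) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < self.assoc_density <= 1.0:
            raise ValueError("assoc_density must be in (0,1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_modules % 2:
            raise ValueError("n_modules must be even (modules pair up)")
        n_bridges = int(self.m_proteins * self.bridge_fraction)
        if self.m_proteins - n_bridges < self.n_modules:
            raise ValueError("not enough proteins to populate every module")
        if n_bridges < (self.n_modules // 2) * (self.bridges_per_drug + 1):
            raise ValueError("bridge pool too small for the module pairing")


@dataclass
class SyntheticUniverse:
    """Generated inputs plus the planted structure (for benchmark planting)."""

    spec: SyntheticUniverseSpec
    fingerprints: FingerprintSet
    proteins: ProteinAnnotation
    dag: OntologyDAG
    assoc: AssociationMatrix
    drug_module: np.ndarray
    protein_module: np.ndarray  # -1 for bridge proteins
    bridge_pool: dict[int, list[int]]  # module-pair index -> bridge protein indices
    drug_bridges: list[list[int]] = field(default_factory=list)

    def __iter__(self):
        # allows: fps, prots, dag, assoc = universe
        return iter((self.fingerprints, self.proteins, self.dag, self.assoc))


def _go_id(counter: itertools.count) -> str:
    return f"GO:{next(counter):07d}"


def _build_dag(spec: SyntheticUniverseSpec, n_bridges: int):
    """Module-branched two-namespace DAG with mixed is_a / part_of edges.

    Bridge proteins get one unique leaf each under their pair's bridge
    branch, so bridges are related but not interchangeable — otherwise
    protein-layer diffusion would smear the planted shared-neighborhood
    signal uniformly over the whole bridge pool.
    """
    counter = itertools.count(1)
    terms: set[str] = set()
    edges: list[tuple[str, str, str]] = []
    namespaces: dict[str, str] = {}
    n_pairs = spec.n_modules // 2
    module_leaves: dict[str, dict[int, list[str]]] = {}
    bridge_terms: dict[str, dict[int, str]] = {}
    bridge_leaves: dict[str, list[str]] = {}
    for ns in _NAMESPACES:
        root = _go_id(counter)
        terms.add(root)
        namespaces[root] = ns
        module_leaves[ns] = {}
        bridge_terms[ns] = {}
        for mod in range(spec.n_modules):
            branch = _go_id(counter)
            terms.add(branch)
            namespaces[branch] = ns
            edges.append((branch, root, "is_a"))
            leaves = []
            for leaf_i in range(4):
                leaf = _go_id(counter)
                terms.add(leaf)
                namespaces[leaf] = ns
                rel = "is_a" if leaf_i % 2 == 0 else "part_of"
                edges.append((leaf, branch, rel))
                leaves.append(leaf)
            module_leaves[ns][mod] = leaves
        for pair in range(n_pairs):
            branch = _go_id(counter)
            terms.add(branch)
            namespaces[branch] = ns
            edges.append((branch, root, "is_a"))
            bridge_terms[ns][pair] = branch
        # one unique leaf per bridge protein, grouped under its pair's branch
        bridge_leaves[ns] = []
        for b in range(n_bridges):
            leaf = _go_id(counter)
            terms.add(leaf)
            namespaces[leaf] = ns
            edges.append((leaf, bridge_terms[ns][b % n_pairs], "is_a"))
            bridge_leaves[ns].append(leaf)
    dag = OntologyDAG(terms=terms, edges=edges, namespaces=namespaces)
    return dag, module_leaves, bridge_leaves


def generate_universe(spec: SyntheticUniverseSpec) -> SyntheticUniverse:
    """Generate the five pipeline inputs with planted modular structure.

    Fully reproducible from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, m = spec.n_drugs, spec.m_proteins
    n_pairs = spec.n_modules // 2

    # --- partition proteins: modules + reserved bridge pool -----------------
    n_bridges = int(m * spec.bridge_fraction)
    n_module_prots = m - n_bridges
    protein_module = np.full(m, -1, dtype=int)
    protein_module[:n_module_prots] = np.arange(n_module_prots) % spec.n_modules
    bridge_idx = list(range(n_module_prots, m))
    bridge_pool: dict[int, list[int]] = {
        q: bridge_idx[q::n_pairs] for q in range(n_pairs)
    }

    drug_module = np.arange(n) % spec.n_modules

    # --- ontology + annotations --------------------------------------------
    dag, module_leaves, bridge_leaves = _build_dag(spec, n_bridges)
    all_leaves = {
        ns: [t for mod in module_leaves[ns].values() for t in mod]
        for ns in _NAMESPACES
    }
    go_terms: list[set[str]] = []
    for j in range(m):
        terms: set[str] = set()
        mod = protein_module[j]
        if mod >= 0:
            for ns in _NAMESPACES:
                leaves = module_leaves[ns][mod]
                terms.update(rng.choice(leaves, size=2, replace=False))
                if rng.random() < spec.noise:
                    terms.add(str(rng.choice(all_leaves[ns])))
        else:
            for ns in _NAMESPACES:
                terms.add(bridge_leaves[ns][j - n_module_prots])
        go_terms.append(terms)

    # --- sequences: mutated module cores; bridges individually random -------
    aa = np.array(list(_AA))
    cores = {
        mod: rng.choice(aa, size=spec.seq_core_length)
        for mod in range(spec.n_modules)
    }
    sequences = []
    for j in range(m):
        mod = int(protein_module[j])
        if mod < 0:
            sequences.append("".join(rng.choice(aa, size=spec.seq_core_length)))
            continue
        core = cores[mod].copy()
        mut = rng.random(core.size) < spec.seq_mutation_rate
        core[mut] = rng.choice(aa, size=int(mut.sum()))
        sequences.append("".join(core))

    # --- fingerprints: module bit blocks + sparse background ----------------
    block = max(spec.fingerprint_length // (2 * spec.n_modules), 1)
    bits = (rng.random((n, spec.fingerprint_length)) < 0.05).astype(np.uint8)
    for i in range(n):
        lo = drug_module[i] * block
        hi = min(lo + block, spec.fingerprint_length)
        bits[i, lo:hi] = rng.random(hi - lo) < 0.8
    flip = rng.random(bits.shape) < spec.noise * 0.1
    bits[flip] ^= 1

    # --- associations --------------------------------------------------------
    scores = np.zeros((n, m))
    own = protein_module[None, :] == drug_module[:, None]
    hit = own & (rng.random((n, m)) < spec.assoc_density)
    scores[hit] = rng.uniform(0.5, 0.9, size=int(hit.sum()))
    # every drug keeps at least one own-module association
    for i in np.flatnonzero(~hit.any(axis=1)):
        j = rng.choice(np.flatnonzero(own[i]))
        scores[i, j] = rng.uniform(0.5, 0.9)
    # cross-module noise, mostly below the confidence filter
    spurious = (~own) & (protein_module[None, :] >= 0) & (
        rng.random((n, m)) < spec.noise * 5.0 / m
    )
    scores[spurious] = rng.uniform(0.05, 0.95, size=int(spurious.sum()))
    # strong bridge associations: each drug to a couple of its pair's bridges
    drug_bridges: list[list[int]] = []
    for i in range(n):
        pool = bridge_pool[int(drug_module[i]) // 2]
        chosen = sorted(
            rng.choice(pool, size=min(spec.bridges_per_drug, len(pool)), replace=False)
        )
        scores[i, chosen] = rng.uniform(0.85, 1.0, size=len(chosen))
        drug_bridges.append([int(c) for c in chosen])

    drug_ids = [f"D{i:04d}" for i in range(n)]
    protein_ids = [f"P{j:04d}" for j in range(m)]
    return SyntheticUniverse(
        spec=spec,
        fingerprints=FingerprintSet(drug_ids, bits),
        proteins=ProteinAnnotation(protein_ids, sequences, go_terms),
        dag=dag,
        assoc=AssociationMatrix(drug_ids, protein_ids, scores),
        drug_module=drug_module,
        protein_module=protein_module,
        bridge_pool=bridge_pool,
        drug_bridges=drug_bridges,
    )


def plant_benchmark(
    universe: SyntheticUniverse, n_pos: int, n_neg: int, seed: int = 0
) -> BenchmarkSet:
    """Draw a balanced benchmark from the planted topology.

    Positives: pairs of drugs from complementary modules (the two modules of
    one pair) that share at least one bridge protein.  Negatives: pairs with
    the same module-pair composition but no shared bridge — so fingerprints
    and GO unions are class-balanced and only the shared network
    neighborhood separates the classes.  Raises if the universe cannot
    supply the requested counts.
    """
    rng = np.random.default_rng(seed)
    dm = universe.drug_module
    ids = universe.assoc.drug_ids
    bridges = [set(b) for b in universe.drug_bridges]
    pos_cand: list[tuple[int, int]] = []
    neg_cand: list[tuple[int, int]] = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i] // 2 != dm[j] // 2 or dm[i] == dm[j]:
                continue  # not a complementary-module pair
            (pos_cand if bridges[i] & bridges[j] else neg_cand).append((i, j))
    if len(pos_cand) < n_pos or len(neg_cand) < n_neg:
        raise ValueError(
            f"universe supports only {len(pos_cand)} positive and "
            f"{len(neg_cand)} negative candidates; requested {n_pos}+{n_neg}"
        )
    pos_pick = rng.choice(len(pos_cand), size=n_pos, replace=False)
    neg_pick = rng.choice(len(neg_cand), size=n_neg, replace=False)
    samples = [
        CombinationSample(frozenset({ids[i], ids[j]}), 1)
        for i, j in (pos_cand[k] for k in sorted(pos_pick))
    ] + [
        CombinationSample(frozenset({ids[i], ids[j]}), 0)
        for i, j in (neg_cand[k] for k in sorted(neg_pick))
    ]
    return BenchmarkSet(
        samples=samples,
        rng_seed=seed,
        notes=f"planted benchmark: {n_pos} positives / {n_neg} negatives",
    )
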