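import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from combowalk import (
    AssociationMatrix,
    HeteroNetwork,
    SimilarityMatrix,
    SyntheticUniverseSpec,
    build_transition_matrix,
    generate_universe,
)


def random_similarity(rng: np.random.Generator, ids: list[str]) -> SimilarityMatrix:
    n = len(ids)
    vals = rng.random((n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    # sparsify so some nodes can end up isolated
    mask = rng.random((n, n)) < 0.5
    mask = mask & mask.T
    np.fill_diagonal(mask, False)
    vals = np.where(mask, 0.0, vals)
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(ids, vals)


def random_network(
    rng: np.random.Generator, n_drugs: int, n_proteins: int, assoc_density: float = 0.3
) -> HeteroNetwork:
    """Random heterogeneous network with some association-free nodes."""
    drug_ids = [f"d{i}" for i in range(n_drugs)]
    prot_ids = [f"p{j}" for j in range(n_proteins)]
    scores = np.where(
        rng.random((n_drugs, n_proteins)) < assoc_density,
        rng.random((n_drugs, n_proteins)),
        0.0,
    )
    return HeteroNetwork(
        drug_sim=random_similarity(rng, drug_ids),
        protein_sim=random_similarity(rng, prot_ids),
        assoc=AssociationMatrix(drug_ids, prot_ids, scores),
    )


@pytest.fixture(scope="session")
def small_universe():
    """30-drug / 40-protein planted universe shared across tests."""
    spec = SyntheticUniverseSpec(
        n_drugs=30, m_proteins=40, n_modules=4, bridge_fraction=0.3, rng_seed=7
    )
    return generate_universe(spec)


@pytest.fixture(scope="session")
def small_network(small_universe):
    from combowalk import (
        bipartite_projection_similarity,
        disjunction_integrate,
        filter_targets,
        go_semantic_similarity,
        jaccard_similarity,
        sequence_similarity,
    )

    u = small_universe
    assoc = filter_targets(u.assoc)
    s_d = disjunction_integrate(
        jaccard_similarity(u.fingerprints), bipartite_projection_similarity(assoc)
    )
    s_p = disjunction_integrate(
        sequence_similarity(u.proteins), go_semantic_similarity(u.proteins, u.dag)
    )
    net = HeteroNetwork(drug_sim=s_d, protein_sim=s_p, assoc=assoc)
    return net, build_transition_matrix(net, 0.7)
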