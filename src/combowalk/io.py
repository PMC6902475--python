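"""Readers and writers for the pipeline's on-disk formats.

Formats (all plain text, tab-separated unless noted):

* fingerprints:  ``drug_id`` + one 0/1 column per bit
* sequences:     FASTA (via Biopython)
* annotations:   GAF-like two-column TSV ``protein_id   go_term``
* ontology:      OBO (read via obonet; minimal writer included)
* associations:  ``drug  protein  score`` with raw scores on a 0-1000 scale
* positives:     one combination per line, tab-separated drug IDs
* similarity:    square TSV with an ID header row and column
* benchmark:     ``combination_id  drug_ids(semicolon-joined)  label``

ID order in matrices follows first appearance in the input file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    AssociationMatrix,
    BenchmarkSet,
    CombinationSample,
    FingerprintSet,
    OntologyDAG,
    ProteinAnnotation,
    SimilarityMatrix,
)

__all__ = [
    "read_fingerprints", "write_fingerprints",
    "read_fasta", "write_fasta",
    "read_annotations", "write_annotations",
    "read_obo", "write_obo",
    "read_associations", "write_associations",
    "read_positives", "write_positives",
    "read_similarity", "write_similarity",
    "read_benchmark", "write_benchmark",
    "write_feature_matrix", "read_feature_matrix",
    "read_protein_annotation", "write_universe",
]


# --- fingerprints -----------------------------------------------------------

def read_fingerprints(path: str | Path) -> FingerprintSet:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    ids = df.iloc[:, 0].tolist()
    bits = df.iloc[:, 1:].to_numpy()
    return FingerprintSet(ids, bits)


def write_fingerprints(fps: FingerprintSet, path: str | Path) -> None:
    cols = [f"bit{i}" for i in range(fps.n_bits)]
    df = pd.DataFrame(fps.bits, columns=cols)
    df.insert(0, "drug_id", fps.drug_ids)
    df.to_csv(path, sep="\t", index=False)


def read_smiles(path: str | Path) -> tuple[list[str], list[str]]:
    """TSV (drug_id, smiles) -> (ids, smiles strings) in file order."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug", "smiles"],
                     dtype=str)
    return df["drug"].tolist(), df["smiles"].tolist()


def fingerprints_from_smiles(
    drug_ids: Sequence[str], smiles: Sequence[str], n_bits: int = 880
) -> FingerprintSet:
    """Convenience: Morgan (radius 2) fingerprints folded to *n_bits*.

    Requires rdkit.  This is a generic circular-fingerprint stand-in, not
    the curated 880-bit substructure-key scheme precomputed inputs use; the
    canonical pipeline path reads precomputed fingerprints.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    bits = np.zeros((len(drug_ids), n_bits), dtype=np.uint8)
    for row, (did, smi) in enumerate(zip(drug_ids, smiles)):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {did!r}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        bits[row, list(fp.GetOnBits())] = 1
    return FingerprintSet(list(drug_ids), bits)


# --- sequences / annotations ------------------------------------------------

def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """(protein_ids, sequences) in file order."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return ids, seqs


def write_fasta(ids: Sequence[str], seqs: Sequence[str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """GAF-like TSV (protein_id, go_term) -> protein -> term set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "term"],
                     dtype=str, comment="!")
    out: dict[str, set[str]] = {}
    for prot, term in df.itertuples(index=False):
        out.setdefault(prot, set()).add(term)
    return out


def write_annotations(
    protein_ids: Sequence[str], go_terms: Sequence[set[str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pid, terms in zip(protein_ids, go_terms):
            for t in sorted(terms):
                fh.write(f"{pid}\t{t}\n")


def read_protein_annotation(
    fasta_path: str | Path, annotations_path: str | Path
) -> ProteinAnnotation:
    """Combine a FASTA file and a (protein, go_term) TSV; proteins without
    annotation rows get empty term sets."""
    ids, seqs = read_fasta(fasta_path)
    ann = read_annotations(annotations_path)
    return ProteinAnnotation(ids, seqs, [ann.get(i, set()) for i in ids])


# --- ontology ---------------------------------------------------------------

def read_obo(
    path: str | Path, relation_weights: dict[str, float] | None = None
) -> OntologyDAG:
    graph = obonet.read_obo(str(path))
    terms = set(graph.nodes)
    edges = [(child, parent, rel) for child, parent, rel in graph.edges(keys=True)]
    namespaces = {
        t: data["namespace"]
        for t, data in graph.nodes(data=True)
        if "namespace" in data
    }
    kwargs = {}
    if relation_weights is not None:
        kwargs["relation_weights"] = relation_weights
    return OntologyDAG(terms=terms, edges=edges, namespaces=namespaces, **kwargs)


def write_obo(dag: OntologyDAG, path: str | Path, ontology_name: str = "go") -> None:
    """Minimal OBO 1.2 writer (enough for obonet round-tripping)."""
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in dag.edges:
        by_child.setdefault(child, []).append((parent, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            ns = dag.namespaces.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent, rel in sorted(by_child.get(term, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {parent}\n")
            fh.write("\n")


# --- associations -----------------------------------------------------------

def read_associations(
    path: str | Path,
    drug_ids: Sequence[str] | None = None,
    protein_ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """TSV (drug, protein, score) with raw 0-1000 confidences.

    When *drug_ids* / *protein_ids* are given they fix the matrix axes
    (entities absent from the file get zero rows/columns); otherwise axes
    follow first appearance in the file.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["drug", "protein", "score"],
        dtype={"drug": str, "protein": str},
    )
    if drug_ids is None:
        drug_ids = list(dict.fromkeys(df["drug"]))
    if protein_ids is None:
        protein_ids = list(dict.fromkeys(df["protein"]))
    di = {d: i for i, d in enumerate(drug_ids)}
    pi = {p: i for i, p in enumerate(protein_ids)}
    raw = np.zeros((len(drug_ids), len(protein_ids)))
    for drug, protein, score in df.itertuples(index=False):
        if drug in di and protein in pi:
            raw[di[drug], pi[protein]] = float(score)
    return AssociationMatrix.from_raw(list(drug_ids), list(protein_ids), raw)


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write nonzero associations with raw 0-1000 scores."""
    rows, cols = np.nonzero(assoc.scores)
    with open(path, "w") as fh:
        for r, c in zip(rows, cols):
            fh.write(
                f"{assoc.drug_ids[r]}\t{assoc.protein_ids[c]}\t"
                f"{assoc.scores[r, c] * 1000:.6g}\n"
            )


# --- combinations -----------------------------------------------------------

def read_positives(path: str | Path) -> list[frozenset[str]]:
    """One combination per line: tab-separated drug IDs (>= 2 per row)."""
    combos = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = [p for p in line.strip().split("\t") if p]
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: a combination needs >= 2 drugs"
                )
            combos.append(frozenset(parts))
    return combos


def write_positives(combos: Sequence[frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for combo in combos:
            fh.write("\t".join(sorted(combo)) + "\n")


def read_benchmark(path: str | Path) -> BenchmarkSet:
    df = pd.read_csv(path, sep="\t", dtype={"drug_ids": str})
    samples = [
        CombinationSample(frozenset(row.drug_ids.split(";")), int(row.label))
        for row in df.itertuples(index=False)
    ]
    return BenchmarkSet(samples=samples)


def write_benchmark(bench: BenchmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("combination_id\tdrug_ids\tlabel\n")
        for k, s in enumerate(bench.samples):
            joined = ";".join(sorted(s.drug_ids))
            fh.write(f"C{k:05d}\t{joined}\t{s.label}\n")


# --- matrices ---------------------------------------------------------------

def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.index.astype(str)), df.to_numpy())


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


# --- synthetic-universe dump -------------------------------------------------

def write_universe(universe, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic universe in the exact formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fingerprints": outdir / "fingerprints.tsv",
        "fasta": outdir / "proteins.fasta",
        "annotations": outdir / "annotations.tsv",
        "obo": outdir / "ontology.obo",
        "associations": outdir / "associations.tsv",
    }
    write_fingerprints(universe.fingerprints, paths["fingerprints"])
    write_fasta(
        universe.proteins.protein_ids, universe.proteins.sequences, paths["fasta"]
    )
    write_annotations(
        universe.proteins.protein_ids, universe.proteins.go_terms,
        paths["annotations"],
    )
    write_obo(universe.dag, paths["obo"])
    write_associations(universe.assoc, paths["associations"])
    return paths
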