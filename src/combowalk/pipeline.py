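"""End-to-end orchestration: inputs -> similarities -> network -> features
-> classifier -> metrics, with a manifest for reproducibility.

All randomness flows from one root seed, split deterministically per stage
(negative sampling, classifier, fold assignment), so two runs with the same
config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cwio
from .benchmark import (
    assemble_feature_matrix,
    filter_targets,
    sample_negatives,
)
from .datatypes import BenchmarkSet, CombinationSample
from .model import GTBConfig, MetricsReport, cross_validate, train_gtb
from .network import HeteroNetwork, build_transition_matrix
from .similarity import (
    AlignmentParams,
    bipartite_projection_similarity,
    disjunction_integrate,
    go_semantic_similarity,
    jaccard_similarity,
    sequence_similarity,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sweep_parameter"]

_SEED_SPLIT = {"negatives": 11, "model": 23, "folds": 37}


def _stage_seed(root: int, stage: str) -> int:
    return (root * 1_000_003 + _SEED_SPLIT[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    fingerprints: str
    fasta: str
    annotations: str
    obo: str
    associations: str
    positives: str
    outdir: str = "combowalk_run"
    lam: float = 0.7
    alpha: float = 0.2
    eta: float = 0.9
    tol: float = 1e-10
    max_iter: int = 10_000
    filter_threshold: float = 0.5
    top_k: int = 3
    expansion_k: int = 3
    cv_folds: int = 10
    seed: int = 0
    gtb: GTBConfig = field(default_factory=GTBConfig)

    def __post_init__(self) -> None:
        for name in ("lam", "alpha", "eta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]; got {v}")
        if isinstance(self.gtb, dict):
            self.gtb = GTBConfig(**self.gtb)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in (
                self.fingerprints, self.fasta, self.annotations,
                self.obo, self.associations, self.positives,
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    metrics: MetricsReport
    features: pd.DataFrame
    benchmark: BenchmarkSet
    artifacts: dict[str, Path]
    manifest: dict


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write every intermediate artifact.

    Stage errors propagate wrapped with the stage name.  Idempotent for
    identical inputs/config (artifacts and metrics are byte-identical).
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        with _timed(name):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # --- load ---------------------------------------------------------------
    fps = stage("read-fingerprints", cwio.read_fingerprints, cfg.fingerprints)
    dag = stage("read-obo", cwio.read_obo, cfg.obo)
    prots = stage(
        "read-proteins", cwio.read_protein_annotation, cfg.fasta, cfg.annotations
    )
    raw_assoc = stage(
        "read-associations",
        cwio.read_associations,
        cfg.associations,
        drug_ids=fps.drug_ids,
        protein_ids=prots.protein_ids,
    )
    positives = stage("read-positives", cwio.read_positives, cfg.positives)

    # --- filter + similarities ----------------------------------------------
    assoc = stage(
        "filter-targets", filter_targets, raw_assoc,
        threshold=cfg.filter_threshold, top_k=cfg.top_k,
    )
    s_d1 = stage("jaccard", jaccard_similarity, fps)
    s_d2 = stage("bipartite-projection", bipartite_projection_similarity, assoc)
    s_d = disjunction_integrate(s_d1, s_d2)
    s_p1 = stage("sequence-similarity", sequence_similarity, prots, AlignmentParams())
    s_p2 = stage("go-similarity", go_semantic_similarity, prots, dag)
    s_p = disjunction_integrate(s_p1, s_p2)
    for name, sim in (
        ("drug_similarity", s_d), ("protein_similarity", s_p),
        ("drug_jaccard", s_d1), ("drug_projection", s_d2),
        ("protein_sequence", s_p1), ("protein_go", s_p2),
    ):
        artifacts[name] = outdir / f"{name}.tsv"
        cwio.write_similarity(sim, artifacts[name])

    # --- network -------------------------------------------------------------
    net = HeteroNetwork(drug_sim=s_d, protein_sim=s_p, assoc=assoc)
    tmat = stage("transition-matrix", build_transition_matrix, net, cfg.lam)
    artifacts["transition_matrix"] = outdir / "transition_matrix.tsv"
    tmat.to_tsv(artifacts["transition_matrix"])

    # --- benchmark -----------------------------------------------------------
    negatives = stage(
        "sample-negatives",
        sample_negatives,
        fps.drug_ids,
        len(positives),
        2,
        positives,
        _stage_seed(cfg.seed, "negatives"),
    )
    samples = [CombinationSample(c, 1) for c in positives] + negatives
    bench = BenchmarkSet(samples=samples, rng_seed=cfg.seed)
    artifacts["benchmark"] = outdir / "benchmark.tsv"
    cwio.write_benchmark(bench, artifacts["benchmark"])

    # --- features + evaluation ------------------------------------------------
    features = stage(
        "assemble-features", assemble_feature_matrix,
        bench, tmat, assoc,
        eta=cfg.eta, alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter,
    )
    artifacts["features"] = outdir / "features.tsv"
    cwio.write_feature_matrix(features, artifacts["features"])

    X = features.drop(columns="label").to_numpy()
    y = features["label"].to_numpy()
    gtb_cfg = dataclasses.replace(cfg.gtb, rng_seed=_stage_seed(cfg.seed, "model"))
    metrics = stage(
        "cross-validate", cross_validate, X, y, gtb_cfg,
        k=cfg.cv_folds, seed=_stage_seed(cfg.seed, "folds"),
    )
    artifacts["metrics"] = outdir / "metrics.json"
    artifacts["metrics"].write_text(
        json.dumps(
            {"mean": metrics.as_dict(), "per_fold": metrics.per_fold}, indent=2,
            sort_keys=True,
        )
    )

    model = stage("train-final-model", train_gtb, X, y, gtb_cfg)
    try:
        import joblib

        artifacts["model"] = outdir / "model.joblib"
        joblib.dump({"model": model, "version": 1}, artifacts["model"])
    except ImportError:  # pragma: no cover - joblib ships with sklearn
        pass

    manifest = {
        "config": _jsonable(cfg.to_dict()),
        "input_hashes": {
            name: _sha256_file(getattr(cfg, name))
            for name in (
                "fingerprints", "fasta", "annotations",
                "obo", "associations", "positives",
            )
        },
        "versions": _versions(),
        "n_drugs": fps.n_drugs,
        "n_proteins": prots.n_proteins,
        "n_samples": len(bench.samples),
    }
    artifacts["manifest"] = outdir / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        metrics=metrics,
        features=features,
        benchmark=bench,
        artifacts=artifacts,
        manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("combowalk", "numpy", "scipy", "pandas", "scikit-learn", "biopython"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            pass
    return out


def sweep_parameter(
    cfg: RunConfig, name: str, values: list[float]
) -> pd.DataFrame:
    """One full CV evaluation per parameter value at constant seeds.

    *name* is a walk parameter (``lambda``, ``alpha``, ``eta``) or a
    classifier knob (``n_trees``, ``max_depth``).  Returns a table with
    columns (value, precision, recall, f_measure, mcc, auc), mirroring a
    per-parameter performance sweep.
    """
    walk_attr = {"lambda": "lam", "alpha": "alpha", "eta": "eta"}.get(name)
    gtb_knobs = {"n_trees", "max_depth"}
    if walk_attr is None and name not in gtb_knobs:
        raise ValueError(f"unknown sweep parameter {name!r}")
    rows = []
    for v in values:
        if walk_attr is not None:
            overrides = {walk_attr: v}
        else:
            overrides = {"gtb": dataclasses.replace(cfg.gtb, **{name: int(v)})}
        run_cfg = dataclasses.replace(
            cfg, outdir=str(Path(cfg.outdir) / f"sweep_{name}_{v:g}"), **overrides
        )
        result = run_pipeline(run_cfg)
        rows.append({"value": v, **result.metrics.as_dict()})
    return pd.DataFrame(rows)
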