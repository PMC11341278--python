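"""End-to-end pipeline: simulate/load -> embed -> train -> evaluate -> report.

A single `RunConfig` (read from YAML, overridable by CLI flags) drives every
stage.  One global seed fans out to per-stage seeds by fixed offsets, so a
single integer reproduces the whole run; with fixed config and seed the
metrics JSON is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import BASELINE_INDICES, baseline_score_matrix, evaluate, write_report
from .gcn import build_bipartite
from .kg_data import (
    HTIDataset,
    KnowledgeGraph,
    SyntheticSpec,
    generate_synthetic_hti,
    generate_synthetic_kg,
    read_pairs,
    read_triples,
    split_dataset,
    write_pairs,
)
from .kg_embedding import HopeConfig, WalkConfig, write_embeddings
from .model import HTIRankingModel
from .training import TrainConfig

__all__ = ["RunConfig", "run_pipeline", "sweep", "load_dataset", "load_kg"]

logger = logging.getLogger(__name__)

# stage seed offsets (global seed + offset, all < 2**31)
SEED_SPLIT = 11
SEED_EMBED = 22
SEED_TRAIN = 33


@dataclass
class RunConfig:
    """Structured configuration for a full pipeline run."""

    # inputs: either file paths or a synthetic spec
    pairs_path: str | None = None
    kg_triples_path: str | None = None
    kg_entities_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    embed_method: str = "deepwalk"
    dim: int = 64
    num_walks: int = 10
    walk_length: int = 40
    window: int = 5
    embed_epochs: int = 5
    negative_samples: int = 5
    p: float = 1.0
    q: float = 1.0
    beta: float = 0.05

    n_layers: int = 2
    residual: bool = True
    normalization: str = "sqrt"
    learn_weights: bool = False

    learning_rate: float = 1e-3
    lambda_reg: float = 1e-4
    negatives_per_positive: int = 1
    batch_size: int = 1024
    train_epochs: int = 200
    patience: int = 20

    eval_ks: tuple[int, ...] = (1, 3, 5, 10)
    top_n: int = 20
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("eval_ks", "split_ratios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eval_ks"] = list(self.eval_ks)
        d["split_ratios"] = list(self.split_ratios)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        from .kg_embedding import EMBED_METHODS

        if self.embed_method not in EMBED_METHODS:
            raise ValueError(
                f"unknown embedding method {self.embed_method!r}; supported: {EMBED_METHODS}"
            )
        if self.normalization not in ("sqrt", "product"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def walk_config(self) -> WalkConfig:
        return WalkConfig(
            num_walks_per_node=self.num_walks,
            walk_length=self.walk_length,
            window_size=self.window,
            dimension=self.dim,
            epochs=self.embed_epochs,
            negative_samples=self.negative_samples,
            p=self.p,
            q=self.q,
            seed=self.seed + SEED_EMBED,
        )

    def hope_config(self) -> HopeConfig:
        dim = self.dim if self.dim % 2 == 0 else self.dim + 1
        return HopeConfig(dimension=dim, beta=self.beta)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            lambda_reg=self.lambda_reg,
            negatives_per_positive=self.negatives_per_positive,
            batch_size=self.batch_size,
            epochs=self.train_epochs,
            seed=self.seed + SEED_TRAIN,
            early_stopping_patience=self.patience,
        )

    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(seed=self.seed, **self.synthetic)


def load_dataset(config: RunConfig) -> HTIDataset:
    """Read the pairs file, or sample the synthetic benchmark; ensure splits."""
    if config.pairs_path:
        dataset = read_pairs(config.pairs_path)
    else:
        dataset = generate_synthetic_hti(config.synthetic_spec())
    if not dataset.split:
        dataset = split_dataset(
            dataset.positives,
            ratios=config.split_ratios,
            seed=config.seed + SEED_SPLIT,
            herbs=dataset.herbs,
            targets=dataset.targets,
        )
    return dataset


def load_kg(config: RunConfig, dataset: HTIDataset) -> KnowledgeGraph | None:
    if config.embed_method == "none":
        return None
    if config.kg_triples_path:
        if not config.kg_entities_path:
            raise ValueError("kg_triples_path requires kg_entities_path")
        return read_triples(config.kg_triples_path, config.kg_entities_path)
    return generate_synthetic_kg(config.synthetic_spec(), dataset)


def _build_model(config: RunConfig, dataset: HTIDataset, kg: KnowledgeGraph | None) -> HTIRankingModel:
    return HTIRankingModel(
        dataset,
        kg=kg,
        embed_method=config.embed_method,
        dim=config.dim,
        n_layers=config.n_layers,
        residual=config.residual,
        normalization=config.normalization,
        learn_weights=config.learn_weights,
        walk_config=config.walk_config(),
        hope_config=config.hope_config(),
        train_config=config.train_config(),
        seed=config.seed + SEED_EMBED,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path, pretrained=None) -> dict:
    """Execute all stages, writing artifacts to ``out_dir``.

    Artifacts: pairs.tsv (with splits), embeddings.txt, training_log.csv,
    checkpoint.txt, metrics.json, predictions.tsv, manifest.json.  On any
    stage failure the artifacts already produced are renamed with a
    ``.partial`` suffix and the exception propagates.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    t0 = time.time()
    try:
        dataset = load_dataset(config)
        write_pairs(dataset, out / "pairs.tsv")
        produced.append(out / "pairs.tsv")
        logger.info("data stage done (%.1fs): %d positives", time.time() - t0, len(dataset.positives))

        kg = load_kg(config, dataset)
        model = _build_model(config, dataset, kg)
        if pretrained is None:
            pretrained = model.pretrain_embeddings()
        write_embeddings(pretrained, out / "embeddings.txt")
        produced.append(out / "embeddings.txt")
        logger.info("embedding stage done (%.1fs)", time.time() - t0)

        results = model.fit(pretrained=pretrained)
        results.history.to_csv(out / "training_log.csv", index=False)
        produced.append(out / "training_log.csv")
        _write_checkpoint(results, config, out / "checkpoint.txt")
        produced.append(out / "checkpoint.txt")
        logger.info("training stage done (%.1fs)", time.time() - t0)

        report = evaluate(results.score_matrix(), dataset, split="test", Ks=config.eval_ks)
        write_report(report, out / "metrics.json", top_n=config.top_n)
        produced.append(out / "metrics.json")
        _write_predictions(report, out / "predictions.tsv", config.top_n)
        produced.append(out / "predictions.tsv")

        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": {
                "split": config.seed + SEED_SPLIT,
                "embed": config.seed + SEED_EMBED,
                "train": config.seed + SEED_TRAIN,
            },
            "versions": {"htipred": __version__, "numpy": np.__version__},
            "metrics": report.metric_dict(),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        produced.append(out / "manifest.json")
        logger.info("pipeline complete (%.1fs)", time.time() - t0)
        return manifest
    except Exception:
        for p in produced:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise


def _write_checkpoint(results, config: RunConfig, path: Path) -> None:
    """Text checkpoint: config hash header, then node E^0 rows."""
    state = results.state
    ids = state.graph.node_ids()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# htipred checkpoint config={config.config_hash()} "
                 f"K={state.K} residual={state.residual}\n")
        fh.write(f"{len(ids)} {state.E0.shape[1]}\n")
        for e, row in zip(ids, state.E0):
            fh.write(e + " " + " ".join(f"{x:.8g}" for x in row) + "\n")
        if state.weights is not None:
            for k, W in enumerate(state.weights):
                fh.write(f"# W{k}\n")
                for row in W:
                    fh.write(" ".join(f"{x:.8g}" for x in row) + "\n")


def _write_predictions(report, path: Path, top_n: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("herb\trank\ttarget\tscore\n")
        for herb in sorted(report.per_herb):
            for rank, (target, s) in enumerate(report.per_herb[herb][:top_n], start=1):
                fh.write(f"{herb}\t{rank}\t{target}\t{s:.6g}\n")


def run_baselines(config: RunConfig, out_dir: str | Path, indices=BASELINE_INDICES) -> pd.DataFrame:
    """Evaluate the local-similarity baselines on the same dataset/split."""
    dataset = load_dataset(config)
    graph = build_bipartite(dataset, "train")
    rows = []
    for index in indices:
        M = baseline_score_matrix(index, graph)
        report = evaluate(M, dataset, split="test", Ks=config.eval_ks)
        for K in config.eval_ks:
            hr, ndcg = report.metrics[K]
            rows.append({"index": index, "K": K, "HR": hr, "NDCG": ndcg})
    df = pd.DataFrame(rows)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "baselines.csv", index=False)
    return df


SWEEP_KNOBS = ("layers", "dim", "window")


def sweep(config: RunConfig, knob: str, values: list, out_dir: str | Path) -> pd.DataFrame:
    """Run the pipeline once per knob value; tidy long-format results.

    Layer sweeps reuse a single pre-trained embedding matrix (the embedding
    stage does not depend on K); dim and window sweeps re-run it.
    """
    if knob not in SWEEP_KNOBS:
        raise ValueError(f"unknown sweep knob {knob!r}; choose from {SWEEP_KNOBS}")
    if not values:
        raise ValueError("sweep values list is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shared_pretrained = None
    if knob == "layers":
        dataset = load_dataset(config)
        kg = load_kg(config, dataset)
        shared_pretrained = _build_model(config, dataset, kg).pretrain_embeddings()
    rows = []
    for value in values:
        if knob == "layers":
            cfg = replace(config, n_layers=int(value))
        elif knob == "dim":
            cfg = replace(config, dim=int(value))
        else:
            cfg = replace(config, window=int(value))
        manifest = run_pipeline(cfg, out / f"{knob}_{value}", pretrained=shared_pretrained)
        for key, val in manifest["metrics"].items():
            metric, K = key.split("@")
            rows.append({"knob": knob, "value": value, "K": int(K), "metric": metric, "score": val})
    df = pd.DataFrame(rows)
    df.to_csv(out / "sweep.csv", index=False)
    return df
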