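"""Model/Results front end tying the pipeline together.

`HTIRankingModel` is constructed from an interaction dataset (and optionally
a knowledge graph); `fit()` runs embedding pre-training followed by BPR
fine-tuning of the residual GCN and returns an `HTIRankingResults` holding
the trained state, the training history, and evaluation/ranking helpers.

    >>> model = HTIRankingModel(dataset, kg=kg, embed_method="deepwalk",
    ...                         dim=32, n_layers=2, seed=7)
    >>> res = model.fit()
    >>> res.evaluate("test").metrics[10]
    (..., ...)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .evaluation import RankingReport, rank_targets
from .kg_data import HTIDataset, KnowledgeGraph, split_dataset
from .kg_embedding import EmbeddingMatrix, HopeConfig, WalkConfig, pretrain
from .training import GCNModelState, TrainConfig, TrainResult, train

__all__ = ["HTIRankingModel", "HTIRankingResults"]


class HTIRankingModel:
    """Herb-target ranking model: KG-embedding pre-training + residual GCN + BPR.

    Parameters
    ----------
    dataset
        Interaction benchmark with train/val/test split labels assigned.
    kg
        Optional knowledge graph for embedding pre-training.  Required for
        ``embed_method`` other than ``"none"``.
    embed_method
        ``"deepwalk"``, ``"node2vec"``, ``"hope"`` or ``"none"`` (random
        initialization; the no-pre-training ablation).
    dim
        Embedding and GCN feature dimension.
    n_layers
        Number of linear propagation layers K.
    residual
        Sum all K+1 layer outputs (True) or keep only E^K (False; the
        no-residual ablation).
    normalization
        ``"sqrt"`` (symmetric D~^{-1/2}(A+I)D~^{-1/2}) or ``"product"``.
    learn_weights
        Learn per-layer linear maps W^k instead of the identity.
    """

    def __init__(
        self,
        dataset: HTIDataset,
        kg: KnowledgeGraph | None = None,
        *,
        embed_method: str = "deepwalk",
        dim: int = 64,
        n_layers: int = 2,
        residual: bool = True,
        normalization: str = "sqrt",
        learn_weights: bool = False,
        walk_config: WalkConfig | None = None,
        hope_config: HopeConfig | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ) -> None:
        if not dataset.split:
            raise ValueError("dataset must carry split labels (use split_dataset)")
        if kg is None and embed_method != "none":
            raise ValueError(f"embed_method {embed_method!r} requires a knowledge graph")
        self.dataset = dataset
        self.kg = kg
        self.embed_method = embed_method
        self.dim = dim
        self.n_layers = n_layers
        self.residual = residual
        self.normalization = normalization
        self.learn_weights = learn_weights
        self.seed = seed
        self.walk_config = walk_config or WalkConfig(dimension=dim, seed=seed)
        self.hope_config = hope_config or HopeConfig(dimension=dim if dim % 2 == 0 else dim + 1)
        self.train_config = train_config or TrainConfig(seed=seed)

    @classmethod
    def from_dataframe(
        cls,
        pairs: pd.DataFrame,
        herb_col: str = "herb",
        target_col: str = "target",
        split_col: str | None = "split",
        ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
        seed: int = 0,
        **kwargs,
    ) -> "HTIRankingModel":
        """Build from a pairs DataFrame; splits are taken from ``split_col``
        when present, otherwise drawn with :func:`split_dataset`."""
        positives = set(zip(pairs[herb_col].astype(str), pairs[target_col].astype(str)))
        if split_col is not None and split_col in pairs.columns:
            herbs = tuple(sorted(pairs[herb_col].astype(str).unique()))
            targets = tuple(sorted(pairs[target_col].astype(str).unique()))
            split = dict(
                zip(
                    zip(pairs[herb_col].astype(str), pairs[target_col].astype(str)),
                    pairs[split_col].astype(str),
                )
            )
            dataset = HTIDataset(herbs=herbs, targets=targets, positives=frozenset(positives), split=split)
        else:
            dataset = split_dataset(positives, ratios=ratios, seed=seed)
        return cls(dataset, seed=seed, **kwargs)

    def pretrain_embeddings(self) -> EmbeddingMatrix:
        """Run the configured pre-training backend (or random init)."""
        kg = self.kg
        if kg is None:  # embed_method == "none": dataset nodes only
            entities = tuple(
                [(h, "herb") for h in self.dataset.herbs]
                + [(t, "target") for t in self.dataset.targets]
            )
            kg = KnowledgeGraph(entities=entities, triples=())
        return pretrain(
            kg,
            method=self.embed_method,
            walk_config=self.walk_config,
            hope_config=self.hope_config,
            dimension=self.dim if self.embed_method != "hope" else None,
            seed=self.seed,
        )

    def fit(self, pretrained: EmbeddingMatrix | None = None) -> "HTIRankingResults":
        """Pre-train (unless embeddings are supplied), fine-tune, and wrap up.

        Passing ``pretrained`` skips the embedding stage, which lets sweeps
        over downstream knobs reuse one embedding matrix.
        """
        if pretrained is None:
            pretrained = self.pretrain_embeddings()
        result = train(
            self.dataset,
            pretrained,
            dim=self.dim,
            n_layers=self.n_layers,
            residual=self.residual,
            normalization=self.normalization,
            learn_weights=self.learn_weights,
            cfg=self.train_config,
        )
        return HTIRankingResults(model=self, pretrained=pretrained, _result=result)


@dataclass
class HTIRankingResults:
    """Fitted state, training history and ranking utilities."""

    model: HTIRankingModel
    pretrained: EmbeddingMatrix
    _result: TrainResult

    @property
    def state(self) -> GCNModelState:
        return self._result.state

    @property
    def history(self) -> pd.DataFrame:
        """Per-epoch train loss and validation HR@10 / NDCG@10."""
        return self._result.history

    @property
    def best_epoch(self) -> int:
        return self._result.best_epoch

    @property
    def final_embeddings(self) -> np.ndarray:
        return self.state.final_embeddings()

    def score_matrix(self) -> np.ndarray:
        return self.state.score_matrix()

    def evaluate(self, split: str = "test", Ks: Sequence[int] = (1, 3, 5, 10)) -> RankingReport:
        """Macro-averaged HR@K / NDCG@K on the chosen held-out split."""
        return evaluation.evaluate(self.score_matrix(), self.model.dataset, split=split, Ks=Ks)

    def rank_targets(self, herb: str, top_n: int | None = None, novel_only: bool = False) -> list[tuple[str, float]]:
        """Ranked candidate targets for one herb (training positives removed).

        ``novel_only`` additionally hides val/test positives, leaving only
        predictions with no known interaction in any split.
        """
        ds = self.model.dataset
        herbs = tuple(sorted(ds.herbs))
        targets = tuple(sorted(ds.targets))
        i = herbs.index(herb)
        exclude = ds.positives_by_herb("train")[herb]
        if novel_only:
            exclude = {t for t in targets if (herb, t) in ds.positives}
        ranked = rank_targets(zip(targets, self.score_matrix()[i]), exclude)
        return ranked[:top_n] if top_n is not None else ranked

    def summary(self, Ks: Sequence[int] = (1, 3, 5, 10)) -> str:
        """Plain-text summary of the configuration, fit and test metrics."""
        m = self.model
        ds = m.dataset
        test = self.evaluate("test", Ks=Ks)
        lines = [
            "Herb-Target Interaction Ranking Results",
            "=" * 48,
            f"herbs: {ds.n_herbs}   targets: {ds.n_targets}   positives: {len(ds.positives)}",
            f"split: train={len(ds.pairs_in_split('train'))} "
            f"val={len(ds.pairs_in_split('val'))} test={len(ds.pairs_in_split('test'))}",
            f"pre-training: {m.embed_method}   dim: {m.dim}   layers: {m.n_layers}",
            f"residual: {m.residual}   normalization: {m.normalization}   "
            f"weights: {'learned' if m.learn_weights else 'identity'}",
            f"epochs run: {len(self.history)}   best epoch (val HR@10): {self.best_epoch}",
            "-" * 48,
            f"test split ({test.n_evaluated_herbs} herbs evaluated):",
        ]
        for K in Ks:
            hr, ndcg = test.metrics[K]
            lines.append(f"  HR@{K:<3d} {hr:8.4f}    NDCG@{K:<3d} {ndcg:8.4f}")
        return "\n".join(lines)
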