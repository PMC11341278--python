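"""Top-K ranking evaluation and classical local-similarity baselines.

For each herb the model scores every candidate target (all targets except the
herb's training positives — held-out positives must stay rankable), sorts
descending with lexicographic tie-break, and the held-out positives G_h are
scored by

    HR@K   = |P_h@K  intersect  G_h| / |G_h|
    NDCG@K = DCG@K / IDCG@K,   DCG@K = sum_{i<=K} (2^{r_i} - 1) / log2(i+1)

with binary relevance r_i.  Note HR@K as defined here is a *recall* at K
(denominator |G_h|, not min(K, |G_h|)); the name follows the convention of
the herb-target prediction literature.  Metrics are macro-averaged uniformly
over herbs with at least one held-out positive.

The baselines are the seven neighbourhood-overlap link-prediction indices
(CN, Salton, Jaccard, HPI, LHN-1, AA, RA) adapted to the bipartite graph by
herb-side projection: herb-herb similarity is computed over shared target
neighbourhoods, and a (herb, target) score is the summed similarity of the
herb to the target's known herbs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gcn import BipartiteGraph
from .kg_data import HTIDataset

__all__ = [
    "RankingReport",
    "rank_targets",
    "hr_at_k",
    "ndcg_at_k",
    "evaluate",
    "baseline_score",
    "baseline_score_matrix",
    "random_ranker_expected_hr",
    "write_report",
    "read_report",
    "BASELINE_INDICES",
]

BASELINE_INDICES = ("CN", "Salton", "Jaccard", "HPI", "LHN1", "AA", "RA")
DEFAULT_KS = (1, 3, 5, 10)


@dataclass
class RankingReport:
    """Per-herb ranked lists plus aggregated HR@K / NDCG@K."""

    per_herb: dict[str, list[tuple[str, float]]]
    metrics: dict[int, tuple[float, float]]  # K -> (HR, NDCG)
    n_evaluated_herbs: int

    def metric_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for K in sorted(self.metrics):
            hr, ndcg = self.metrics[K]
            out[f"HR@{K}"] = hr
            out[f"NDCG@{K}"] = ndcg
        return out


def _as_score_matrix(model, dataset: HTIDataset) -> np.ndarray:
    """Accept a dense (n_herbs x n_targets) array or anything with
    ``score_matrix()``; rows/columns follow the sorted herb/target order."""
    if hasattr(model, "score_matrix"):
        model = model.score_matrix()
    M = np.asarray(model, dtype=float)
    expected = (len(dataset.herbs), len(dataset.targets))
    if M.shape != expected:
        raise ValueError(f"score matrix shape {M.shape} != {expected}")
    return M


def rank_targets(
    scores: Mapping[str, float] | Sequence[tuple[str, float]],
    train_positives: set[str],
) -> list[tuple[str, float]]:
    """Sort candidate targets by descending score, ties broken by id.

    Targets positive for the herb in the *training* split are filtered out;
    validation/test positives remain candidates (otherwise they could never
    be retrieved).
    """
    items = scores.items() if isinstance(scores, Mapping) else scores
    kept = [(t, float(s)) for t, s in items if t not in train_positives]
    return sorted(kept, key=lambda ts: (-ts[1], ts[0]))


def hr_at_k(ranked: Sequence[tuple[str, float]] | Sequence[str], g_h: set[str], k: int) -> float:
    """Fraction of the herb's held-out positives retrieved in the top K."""
    if not g_h:
        raise ValueError("G_h must be non-empty")
    top = [_tid(x) for x in ranked[:k]]
    return len(set(top) & g_h) / len(g_h)


def ndcg_at_k(ranked: Sequence[tuple[str, float]] | Sequence[str], g_h: set[str], k: int) -> float:
    """Binary-relevance NDCG@K.

    The ideal gain sums over *all* |G_h| relevant items ranked first (not
    truncated at K), so NDCG@K is non-decreasing in K and reaches 1 exactly
    when every positive sits in the top K.
    """
    if not g_h:
        raise ValueError("G_h must be non-empty")
    dcg = 0.0
    for i, x in enumerate(ranked[:k], start=1):
        if _tid(x) in g_h:
            dcg += 1.0 / math.log2(i + 1)
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, len(g_h) + 1))
    return dcg / idcg


def _tid(x) -> str:
    return x[0] if isinstance(x, tuple) else x


def evaluate(
    model,
    dataset: HTIDataset,
    split: str = "test",
    Ks: Sequence[int] = DEFAULT_KS,
    top_n: int | None = None,
) -> RankingReport:
    """Rank candidates for every herb with >= 1 positive in ``split`` and
    macro-average HR@K / NDCG@K over those herbs.

    ``model`` is a dense score matrix or an object exposing ``score_matrix()``.
    ``top_n`` truncates the stored per-herb lists (metrics are unaffected).
    """
    M = _as_score_matrix(model, dataset)
    herbs = tuple(sorted(dataset.herbs))
    targets = tuple(sorted(dataset.targets))
    train_by_herb = dataset.positives_by_herb("train")
    split_by_herb = dataset.positives_by_herb(split)

    per_herb: dict[str, list[tuple[str, float]]] = {}
    sums = {K: [0.0, 0.0] for K in Ks}
    n_eval = 0
    for i, h in enumerate(herbs):
        g_h = split_by_herb[h]
        if not g_h:
            continue
        n_eval += 1
        ranked = rank_targets(zip(targets, M[i]), train_by_herb[h])
        for K in Ks:
            sums[K][0] += hr_at_k(ranked, g_h, K)
            sums[K][1] += ndcg_at_k(ranked, g_h, K)
        per_herb[h] = ranked[:top_n] if top_n is not None else ranked
    if n_eval == 0:
        raise ValueError(f"no herb has a positive in split {split!r}")
    metrics = {K: (sums[K][0] / n_eval, sums[K][1] / n_eval) for K in Ks}
    return RankingReport(per_herb=per_herb, metrics=metrics, n_evaluated_herbs=n_eval)


def random_ranker_expected_hr(dataset: HTIDataset, split: str = "test", k: int = 10) -> float:
    """Closed-form expected HR@K of a uniformly random ranking.

    For a herb with n candidates and g held-out positives the expected hit
    count in the top K is hypergeometric, K*g/n, so the expected per-herb
    HR@K is min(K, n)/n; the macro average follows.
    """
    train_by_herb = dataset.positives_by_herb("train")
    split_by_herb = dataset.positives_by_herb(split)
    vals = []
    n_targets = len(dataset.targets)
    for h in dataset.herbs:
        if not split_by_herb[h]:
            continue
        n_cand = n_targets - len(train_by_herb[h])
        vals.append(min(k, n_cand) / n_cand)
    if not vals:
        raise ValueError(f"no herb has a positive in split {split!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Local-similarity baselines
# ---------------------------------------------------------------------------

def _herb_similarity(index: str, B: np.ndarray) -> np.ndarray:
    """Herb-herb similarity over shared target neighbourhoods.

    B is the (n_herbs x n_targets) 0/1 training incidence matrix.
    """
    k = B.sum(axis=1)  # herb degrees
    cn = B @ B.T
    with np.errstate(divide="ignore", invalid="ignore"):
        if index == "CN":
            sim = cn.astype(float)
        elif index == "Salton":
            sim = cn / np.sqrt(np.outer(k, k))
        elif index == "Jaccard":
            union = k[:, None] + k[None, :] - cn
            sim = cn / union
        elif index == "HPI":
            sim = cn / np.minimum(k[:, None], k[None, :])
        elif index == "LHN1":
            sim = cn / np.outer(k, k)
        elif index in ("AA", "RA"):
            kz = B.sum(axis=0)  # target degrees (common-neighbour degrees)
            if index == "AA":
                logkz = np.log(kz, where=kz > 0, out=np.zeros_like(kz, dtype=float))
                w = np.divide(1.0, logkz, where=logkz > 0, out=np.zeros_like(logkz))
            else:
                w = np.divide(1.0, kz, where=kz > 0, out=np.zeros_like(kz, dtype=float))
            sim = (B * w) @ B.T
        else:
            raise ValueError(f"unknown index {index!r}; choose from {BASELINE_INDICES}")
    return np.nan_to_num(sim, nan=0.0, posinf=0.0, neginf=0.0)


def baseline_score_matrix(index: str, graph: BipartiteGraph) -> np.ndarray:
    """Dense (n_herbs x n_targets) baseline score table.

    score(h, t) = sum over herbs h' adjacent to t (h' != h) of sim(h, h').
    """
    nh = graph.n_herbs
    B = graph.adjacency[:nh, nh:].toarray()
    sim = _herb_similarity(index, B)
    scores = sim @ B
    scores -= np.diag(sim)[:, None] * B  # drop the h' = h term
    return scores


def baseline_score(index: str, graph: BipartiteGraph, herb: str, target: str) -> float:
    """Score one (herb, target) pair with the chosen similarity index."""
    i = graph.herbs.index(herb)
    j = graph.targets.index(target)
    return float(baseline_score_matrix(index, graph)[i, j])


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def write_report(report: RankingReport, path: str | Path, top_n: int | None = None) -> None:
    """Serialize metrics (keys "HR@K"/"NDCG@K") and optional per-herb lists."""
    payload = {
        "metrics": report.metric_dict(),
        "n_evaluated_herbs": report.n_evaluated_herbs,
        "per_herb": {
            h: [[t, s] for t, s in (lst[:top_n] if top_n is not None else lst)]
            for h, lst in report.per_herb.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def read_report(path: str | Path) -> RankingReport:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    metrics: dict[int, tuple[float, float]] = {}
    for key, val in payload["metrics"].items():
        kind, K = key.split("@")
        K = int(K)
        hr, ndcg = metrics.get(K, (0.0, 0.0))
        metrics[K] = (val, ndcg) if kind == "HR" else (hr, val)
    return RankingReport(
        per_herb={h: [(t, s) for t, s in lst] for h, lst in payload["per_herb"].items()},
        metrics=metrics,
        n_evaluated_herbs=payload["n_evaluated_herbs"],
    )
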