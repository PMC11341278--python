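"""Data model and I/O for the knowledge graph and the herb-target benchmark.

The package operates on two substrates:

* a typed knowledge graph of traditional-medicine and molecular entities
  (herbs, targets, symptoms, diseases, efficacy terms, ingredients,
  meridians, properties, syndromes, prescriptions, pathways, GO terms, ...)
  given as (head, relation, tail) triples plus an entity-type table;
* a herb-target interaction (HTI) benchmark: a list of positive
  (herb, target) pairs with a train/val/test split at the pair level.

Real curated sources (SymMap-style interaction tables, multi-database
knowledge graphs) are read from plain TSV files; synthetic generators with
planted block structure stand in for them in tests and examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KnowledgeGraph",
    "HTIDataset",
    "EvidenceRecord",
    "SyntheticSpec",
    "SchemaError",
    "ParseError",
    "read_triples",
    "write_triples",
    "read_pairs",
    "write_pairs",
    "filter_evidence",
    "split_dataset",
    "generate_synthetic_hti",
    "generate_synthetic_kg",
    "DEFAULT_ENTITY_TYPES",
    "DEFAULT_RELATION_TEMPLATES",
]

SPLITS = ("train", "val", "test")

#: Entity types emulating the shape of a TCM/clinical knowledge graph.
DEFAULT_ENTITY_TYPES = (
    "herb", "target", "symptom", "disease", "efficacy", "ingredient",
    "meridian", "property", "syndrome", "prescription", "pathway", "go_term",
    "taste", "herb_class", "dosage_form",
)

#: (head_type, relation, tail_type, mean_degree) templates for the synthetic
#: knowledge graph.  The herb-target template is populated from the training
#: split of the interaction benchmark, never sampled.
DEFAULT_RELATION_TEMPLATES = (
    ("herb", "herb-target", "target", 0),
    ("herb", "herb-symptom", "symptom", 3),
    ("herb", "herb-disease", "disease", 3),
    ("herb", "herb-efficacy", "efficacy", 3),
    ("herb", "herb-ingredient", "ingredient", 3),
    ("herb", "herb-meridian", "meridian", 2),
    ("herb", "herb-property", "property", 2),
    ("target", "target-pathway", "pathway", 3),
    ("target", "target-go", "go_term", 3),
)


class SchemaError(ValueError):
    """An entity or relation violates the declared schema."""


class ParseError(ValueError):
    """A file is malformed; the message carries the offending line number."""


@dataclass(frozen=True)
class KnowledgeGraph:
    """Typed entities plus typed triples.

    Invariants (checked at construction): entity ids are unique, triples are
    unique, and every head/tail of every triple appears in the entity table.
    """

    entities: tuple[tuple[str, str], ...]
    triples: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        ids = [e for e, _ in self.entities]
        idset = set(ids)
        if len(ids) != len(idset):
            seen: set[str] = set()
            dup = next(e for e in ids if e in seen or seen.add(e))
            raise SchemaError(f"duplicate entity id: {dup!r}")
        if len(self.triples) != len(set(self.triples)):
            raise SchemaError("duplicate triples")
        for h, r, t in self.triples:
            if h not in idset:
                raise SchemaError(f"triple head {h!r} missing from entity table")
            if t not in idset:
                raise SchemaError(f"triple tail {t!r} missing from entity table")

    @property
    def entity_types(self) -> dict[str, str]:
        return dict(self.entities)

    @property
    def entity_ids(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self.entities)

    @property
    def relation_types(self) -> tuple[str, ...]:
        return tuple(sorted({r for _, r, _ in self.triples}))

    def n_entities(self) -> int:
        return len(self.entities)

    def n_triples(self) -> int:
        return len(self.triples)

    def undirected_edges(self) -> set[tuple[str, str]]:
        """Type- and direction-blind edge set (for walking / proximity)."""
        out: set[tuple[str, str]] = set()
        for h, _, t in self.triples:
            if h != t:
                out.add((h, t) if h <= t else (t, h))
        return out


@dataclass
class HTIDataset:
    """Herb/target vocabularies, positive pairs and their split labels."""

    herbs: tuple[str, ...]
    targets: tuple[str, ...]
    positives: frozenset[tuple[str, str]]
    split: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.herbs) & set(self.targets):
            raise ValueError("herb and target id sets must be disjoint")
        hs, ts = set(self.herbs), set(self.targets)
        for h, t in self.positives:
            if h not in hs:
                raise ValueError(f"positive pair references unknown herb {h!r}")
            if t not in ts:
                raise ValueError(f"positive pair references unknown target {t!r}")
        if self.split:
            if set(self.split) != set(self.positives):
                raise ValueError("split labels must cover exactly the positives")
            bad = {s for s in self.split.values()} - set(SPLITS)
            if bad:
                raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def n_herbs(self) -> int:
        return len(self.herbs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def pairs_in_split(self, name: str) -> set[tuple[str, str]]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}; expected one of {SPLITS}")
        return {p for p, s in self.split.items() if s == name}

    def positives_by_herb(self, split: str | None = None) -> dict[str, set[str]]:
        """Map herb -> its positive targets, optionally restricted to a split."""
        out: dict[str, set[str]] = {h: set() for h in self.herbs}
        pairs = self.positives if split is None else self.pairs_in_split(split)
        for h, t in pairs:
            out[h].add(t)
        return out


@dataclass(frozen=True)
class EvidenceRecord:
    """One scored herb-target association as exported by interaction databases."""

    herb_id: str
    target_id: str
    evidence_score: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in [0,1], got {self.p_value}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block synthetic benchmark and knowledge graph.

    Herbs and targets are assigned round-robin to ``n_blocks`` latent blocks;
    a within-block (herb, target) pair is positive with probability ``p_in``,
    a cross-block pair with ``p_out``.  Auxiliary knowledge-graph entities are
    wired to herbs/targets with the same block preference, so that knowledge-
    graph proximity is informative about interactions.
    """

    n_herbs: int = 40
    n_targets: int = 80
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    kg_entity_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "symptom": 24, "disease": 16, "efficacy": 16, "ingredient": 32,
            "meridian": 8, "property": 8, "pathway": 16, "go_term": 24,
        }
    )
    kg_relation_templates: tuple[tuple[str, str, str, int], ...] = DEFAULT_RELATION_TEMPLATES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if min(self.n_herbs, self.n_targets, self.n_blocks) <= 0:
            raise ValueError("counts must be positive")
        if any(c <= 0 for c in self.kg_entity_counts.values()):
            raise ValueError("kg entity counts must be positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_triples(triples_path: str | Path, entities_path: str | Path) -> KnowledgeGraph:
    """Read a knowledge graph from a triple TSV and an entity-type TSV.

    ``triples_path`` rows are ``head<TAB>relation<TAB>tail``; ``entities_path``
    rows are ``entity<TAB>type``.  No headers, UTF-8.  Triple order is
    preserved.  A triple referencing an entity absent from the type table is a
    :class:`SchemaError` naming the entity; a malformed line is a
    :class:`ParseError` with its line number.
    """
    entities: list[tuple[str, str]] = []
    for lineno, line in enumerate(_read_lines(entities_path), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{entities_path}:{lineno}: expected 2 columns, got {len(parts)}")
        entities.append((parts[0], parts[1]))
    triples: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(_read_lines(triples_path), start=1):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{triples_path}:{lineno}: expected 3 columns, got {len(parts)}")
        triples.append((parts[0], parts[1], parts[2]))
    return KnowledgeGraph(entities=tuple(entities), triples=tuple(triples))


def write_triples(kg: KnowledgeGraph, triples_path: str | Path, entities_path: str | Path) -> None:
    Path(triples_path).write_text(
        "".join(f"{h}\t{r}\t{t}\n" for h, r, t in kg.triples), encoding="utf-8"
    )
    Path(entities_path).write_text(
        "".join(f"{e}\t{ty}\n" for e, ty in kg.entities), encoding="utf-8"
    )


def read_pairs(path: str | Path) -> HTIDataset:
    """Read ``herb<TAB>target[<TAB>split]`` rows into an :class:`HTIDataset`.

    Vocabularies are the sorted distinct ids seen in the file.
    """
    positives: set[tuple[str, str]] = set()
    split: dict[tuple[str, str], str] = {}
    herbs: set[str] = set()
    targets: set[str] = set()
    for lineno, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
        h, t = parts[0], parts[1]
        herbs.add(h)
        targets.add(t)
        positives.add((h, t))
        if len(parts) == 3:
            split[(h, t)] = parts[2]
    return HTIDataset(
        herbs=tuple(sorted(herbs)),
        targets=tuple(sorted(targets)),
        positives=frozenset(positives),
        split=split,
    )


def write_pairs(dataset: HTIDataset, path: str | Path) -> None:
    rows = sorted(dataset.positives)
    with open(path, "w", encoding="utf-8") as fh:
        for h, t in rows:
            if dataset.split:
                fh.write(f"{h}\t{t}\t{dataset.split[(h, t)]}\n")
            else:
                fh.write(f"{h}\t{t}\n")


def _read_lines(path: str | Path) -> Iterable[str]:
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line:
                yield line


# ---------------------------------------------------------------------------
# Benchmark construction
# ---------------------------------------------------------------------------

def filter_evidence(
    records: Iterable[EvidenceRecord],
    score_threshold: float = 0.4616,
    p_threshold: float = 0.05,
) -> set[tuple[str, str]]:
    """Keep pairs whose evidence score strictly exceeds the threshold and
    whose P-value is strictly below it; deduplicate.

    The defaults reproduce the standard SymMap-style reliability filter
    (inferred evidence score above its database-wide mean of 0.4616 and
    P < 0.05).  Idempotent and order-independent.
    """
    if not (math.isfinite(score_threshold) and math.isfinite(p_threshold)):
        raise ValueError("thresholds must be finite")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    return {
        (r.herb_id, r.target_id)
        for r in records
        if r.evidence_score > score_threshold and r.p_value < p_threshold
    }


def split_dataset(
    positives: Iterable[tuple[str, str]],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    herbs: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
) -> HTIDataset:
    """Partition positive pairs into train/val/test by a seeded uniform shuffle.

    Splitting is at the pair (edge) level.  Counts follow the rounding rule
    ``n_val = floor(n * r_val)``, ``n_test = floor(n * r_test)``, remainder to
    train, so the split is deterministic for a fixed seed.
    """
    pairs = sorted(set(positives))
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs to split, got {len(pairs)}")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    split: dict[tuple[str, str], str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            label = "train"
        elif rank < n_train + n_val:
            label = "val"
        else:
            label = "test"
        split[pairs[idx]] = label
    if herbs is None:
        herbs = sorted({h for h, _ in pairs})
    if targets is None:
        targets = sorted({t for _, t in pairs})
    return HTIDataset(
        herbs=tuple(herbs),
        targets=tuple(targets),
        positives=frozenset(pairs),
        split=split,
    )


def _block_of(index: int, n_blocks: int) -> int:
    return index % n_blocks


def generate_synthetic_hti(spec: SyntheticSpec) -> HTIDataset:
    """Sample a planted-block bipartite interaction set.

    Herb ``i`` and target ``j`` belong to blocks ``i % n_blocks`` and
    ``j % n_blocks``; the pair is positive with probability ``p_in`` when the
    blocks coincide, ``p_out`` otherwise.  Every herb is guaranteed at least
    one positive (an empty herb gets one uniformly drawn same-block target).
    Split labels are not assigned; pass the result to :func:`split_dataset`.
    """
    h_in = math.ceil(spec.n_targets / spec.n_blocks)  # within-block targets per herb, +/- 1
    expected = spec.n_herbs * (
        h_in * spec.p_in + (spec.n_targets - h_in) * spec.p_out
    )
    if expected < spec.n_herbs:
        raise ValueError(
            f"expected positive count {expected:.1f} is below n_herbs={spec.n_herbs}; "
            "raise p_in/p_out or target count"
        )
    rng = np.random.default_rng(spec.seed)
    herbs = tuple(f"herb:H{i:04d}" for i in range(spec.n_herbs))
    targets = tuple(f"target:T{j:04d}" for j in range(spec.n_targets))
    hb = np.arange(spec.n_herbs) % spec.n_blocks
    tb = np.arange(spec.n_targets) % spec.n_blocks
    same = hb[:, None] == tb[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    adj = rng.random((spec.n_herbs, spec.n_targets)) < prob
    for i in range(spec.n_herbs):  # guarantee coverage
        if not adj[i].any():
            candidates = np.flatnonzero(same[i])
            adj[i, rng.choice(candidates)] = True
    positives = frozenset(
        (herbs[i], targets[j]) for i, j in zip(*np.nonzero(adj))
    )
    return HTIDataset(herbs=herbs, targets=targets, positives=positives)


def generate_synthetic_kg(spec: SyntheticSpec, hti: HTIDataset) -> KnowledgeGraph:
    """Build a typed knowledge graph around the training interactions.

    Only *train-split* positives enter the graph as herb-target triples, so no
    held-out interaction can leak into embedding pre-training.  Auxiliary
    entities (symptoms, diseases, efficacy terms, ...) are assigned round-robin
    to the same latent blocks as herbs/targets; a head entity draws its
    ``mean_degree`` auxiliary neighbours with sampling weight ``p_in`` for
    same-block entities and ``p_out`` for the rest, so same-block herbs
    preferentially share auxiliary neighbours.
    """
    known_types = set(DEFAULT_ENTITY_TYPES)
    for head_ty, rel, tail_ty, _deg in spec.kg_relation_templates:
        for ty in (head_ty, tail_ty):
            if ty not in known_types:
                raise SchemaError(f"relation template {rel!r} references undeclared type {ty!r}")
    if not hti.split:
        raise ValueError("HTI dataset must carry split labels (run split_dataset first)")

    rng = np.random.default_rng([spec.seed, 7919])  # distinct stream from the HTI sampler
    entities: list[tuple[str, str]] = [(h, "herb") for h in hti.herbs]
    entities += [(t, "target") for t in hti.targets]
    aux_ids: dict[str, list[str]] = {}
    aux_blocks: dict[str, np.ndarray] = {}
    for ty, count in spec.kg_entity_counts.items():
        if ty not in known_types:
            raise SchemaError(f"entity count declared for unknown type {ty!r}")
        aux_ids[ty] = [f"{ty}:{ty[:3].upper()}{i:04d}" for i in range(count)]
        aux_blocks[ty] = np.arange(count) % spec.n_blocks
        entities += [(e, ty) for e in aux_ids[ty]]

    herb_index = {h: i for i, h in enumerate(hti.herbs)}
    target_index = {t: j for j, t in enumerate(hti.targets)}
    triples: list[tuple[str, str, str]] = []
    train_pairs = sorted(hti.pairs_in_split("train"))
    template_rels = {rel for _h, rel, _t, _d in spec.kg_relation_templates}
    if "herb-target" in template_rels:
        triples += [(h, "herb-target", t) for h, t in train_pairs]

    for head_ty, rel, tail_ty, mean_degree in spec.kg_relation_templates:
        if rel == "herb-target" or mean_degree <= 0:
            continue
        if tail_ty not in aux_ids:
            continue
        heads = hti.herbs if head_ty == "herb" else hti.targets
        head_block = (
            (np.arange(len(hti.herbs)) % spec.n_blocks)
            if head_ty == "herb"
            else (np.arange(len(hti.targets)) % spec.n_blocks)
        )
        tails = aux_ids[tail_ty]
        tail_block = aux_blocks[tail_ty]
        for h in heads:
            i = herb_index[h] if head_ty == "herb" else target_index[h]
            weights = np.where(tail_block == head_block[i], spec.p_in, spec.p_out).astype(float)
            weights /= weights.sum()
            k = min(mean_degree, len(tails))
            chosen = rng.choice(len(tails), size=k, replace=False, p=weights)
            triples += [(h, rel, tails[j]) for j in sorted(chosen)]

    return KnowledgeGraph(entities=tuple(entities), triples=tuple(triples))
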