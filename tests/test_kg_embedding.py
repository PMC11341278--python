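import numpy as np
import pytest
from scipy.stats import chi2_contingency

from htipred.kg_data import KnowledgeGraph
from htipred.kg_embedding import (
    EmbeddingMatrix,
    HopeConfig,
    ParseError,
    WalkConfig,
    generate_walks,
    hope_embed,
    katz_matrix,
    pretrain,
    read_embeddings,
    train_skipgram,
    write_embeddings,
)


def path_kg(*names):
    entities = tuple((n, "herb") for n in names)
    triples = tuple((a, "r", b) for a, b in zip(names, names[1:]))
    return KnowledgeGraph(entities=entities, triples=triples)


def cosine(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestGenerateWalks:
    def test_walk_counts_and_lengths_on_triangle(self):
        kg = KnowledgeGraph(
            entities=(("a", "herb"), ("b", "herb"), ("c", "herb")),
            triples=(("a", "r", "b"), ("b", "r", "c"), ("c", "r", "a")),
        )
        cfg = WalkConfig(num_walks_per_node=2, walk_length=5, seed=0)
        corpus = generate_walks(kg, cfg)
        assert len(corpus) == 6
        assert all(len(w) == 5 for w in corpus.walks)

    def test_every_step_is_an_edge(self, planted_kg):
        cfg = WalkConfig(num_walks_per_node=1, walk_length=10, seed=1)
        corpus = generate_walks(planted_kg, cfg)
        edges = planted_kg.undirected_edges()
        for walk in corpus.walks[:200]:
            for a, b in zip(walk, walk[1:]):
                assert ((a, b) if a <= b else (b, a)) in edges

    def test_isolated_node_gives_length_one_walk(self):
        kg = KnowledgeGraph(entities=(("solo", "herb"),), triples=())
        corpus = generate_walks(kg, WalkConfig(num_walks_per_node=3, walk_length=5, seed=0))
        assert corpus.walks == (("solo",),) * 3

    def test_path_midpoint_splits_evenly(self):
        # from the middle of a--b--c the first step is a or c with prob 1/2
        kg = path_kg("a", "b", "c")
        cfg = WalkConfig(num_walks_per_node=700, walk_length=2, seed=3)
        corpus = generate_walks(kg, cfg)
        nexts = [w[1] for w in corpus.walks if w[0] == "b"]
        frac_a = sum(1 for x in nexts if x == "a") / len(nexts)
        assert abs(frac_a - 0.5) < 3 * np.sqrt(0.25 / len(nexts))

    def test_uniform_law_matches_independent_walker(self):
        # package walks at p=q=1 vs a dedicated uniform-walk oracle:
        # per-node transition counts should be statistically indistinguishable
        rng = np.random.default_rng(42)
        names = [f"n{i}" for i in range(20)]
        edges = {(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                 if rng.random() < 0.25}
        kg = KnowledgeGraph(
            entities=tuple((n, "herb") for n in names),
            triples=tuple((a, "r", b) for a, b in sorted(edges)),
        )
        nbrs = {n: sorted({b for a, b in edges if a == n} | {a for a, b in edges if b == n})
                for n in names}
        cfg = WalkConfig(num_walks_per_node=60, walk_length=45, p=1.0, q=1.0, seed=9)
        corpus = generate_walks(kg, cfg)
        counts_pkg = {n: {m: 0 for m in nbrs[n]} for n in names}
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                counts_pkg[a][b] += 1
        oracle_rng = np.random.default_rng(123)
        counts_orc = {n: {m: 0 for m in nbrs[n]} for n in names}
        for _ in range(50000):
            a = names[oracle_rng.integers(len(names))]
            if not nbrs[a]:
                continue
            b = nbrs[a][oracle_rng.integers(len(nbrs[a]))]
            counts_orc[a][b] += 1
        for n in names:
            if len(nbrs[n]) < 2:
                continue
            obs = np.array([
                [counts_pkg[n][m] for m in nbrs[n]],
                [counts_orc[n][m] for m in nbrs[n]],
            ])
            if obs.sum(axis=1).min() < 50:
                continue
            _, p, _, _ = chi2_contingency(obs)
            assert p > 0.01, f"transition law from {n} deviates from uniform"

    def test_biased_walks_differ_from_uniform(self):
        # strongly returning walks (small p) revisit the previous node more often
        kg = path_kg("a", "b", "c", "d", "e")
        base = WalkConfig(num_walks_per_node=200, walk_length=10, seed=5)
        returny = WalkConfig(num_walks_per_node=200, walk_length=10, p=0.05, q=1.0, seed=5)

        def backtrack_rate(corpus):
            back = total = 0
            for w in corpus.walks:
                for i in range(2, len(w)):
                    total += 1
                    back += w[i] == w[i - 2]
            return back / total

        assert backtrack_rate(generate_walks(kg, returny)) > backtrack_rate(
            generate_walks(kg, base)
        ) + 0.1


class TestSkipgram:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_cliques_separate_in_embedding_space(self, two_clique_kg, seed):
        cfg = WalkConfig(num_walks_per_node=8, walk_length=20, dimension=16, seed=seed)
        corpus = generate_walks(two_clique_kg, cfg)
        emb = train_skipgram(corpus, cfg)
        idx = emb.index()
        intra, inter = [], []
        for i in range(16):
            for j in range(i + 1, 16):
                c = cosine(emb.vectors[idx[f"n{i}"]], emb.vectors[idx[f"n{j}"]])
                (intra if (i < 8) == (j < 8) else inter).append(c)
        assert np.mean(intra) > np.mean(inter)

    def test_repeated_walk_pair_more_similar_than_random(self):
        cfg = WalkConfig(num_walks_per_node=1, walk_length=2, dimension=8, epochs=20, seed=4)
        corpus_walks = tuple((("x", "y") if i % 2 else ("y", "x")) for i in range(200))
        from htipred.kg_embedding import WalkCorpus

        emb = train_skipgram(WalkCorpus(corpus_walks), cfg)
        idx = emb.index()
        vx, vy = emb.vectors[idx["x"]], emb.vectors[idx["y"]]
        rng = np.random.default_rng(0)
        baseline = rng.standard_normal(8)
        assert cosine(vx, vy) > cosine(vx, baseline)

    def test_empty_corpus_is_error(self):
        from htipred.kg_embedding import WalkCorpus

        with pytest.raises(ValueError):
            train_skipgram(WalkCorpus(()), WalkConfig())

    def test_unvisited_entities_get_vectors(self, tiny_kg):
        cfg = WalkConfig(num_walks_per_node=2, walk_length=4, dimension=8, epochs=1, seed=0)
        corpus = generate_walks(tiny_kg, cfg)
        emb = train_skipgram(corpus, cfg, all_entities=tiny_kg.entity_ids + ("h1", "t1", "s1"))
        assert set(tiny_kg.entity_ids) <= set(emb.ids)

    def test_deterministic_for_fixed_seed(self, two_clique_kg):
        cfg = WalkConfig(num_walks_per_node=2, walk_length=10, dimension=8, epochs=1, seed=7)
        a = train_skipgram(generate_walks(two_clique_kg, cfg), cfg)
        b = train_skipgram(generate_walks(two_clique_kg, cfg), cfg)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestHope:
    def test_single_edge_katz_closed_form(self):
        kg = path_kg("x", "y")
        beta = 0.1
        S, ids = katz_matrix(kg, beta)
        i, j = ids.index("x"), ids.index("y")
        # geometric series over odd path counts: beta / (1 - beta^2)
        assert S[i, j] == pytest.approx(beta / (1 - beta**2), abs=1e-12)

    def test_edgeless_graph_gives_zero_embeddings(self):
        kg = KnowledgeGraph(entities=(("a", "herb"), ("b", "target")), triples=())
        emb = hope_embed(kg, HopeConfig(dimension=4, beta=0.1))
        np.testing.assert_array_equal(emb.vectors, 0.0)

    def test_divergent_beta_reports_spectral_radius(self):
        kg = path_kg("a", "b", "c")
        with pytest.raises(ValueError, match="spectral_radius"):
            katz_matrix(kg, beta=1.0)

    def test_reconstruction_error_decreases_with_dimension(self):
        rng = np.random.default_rng(8)
        names = [f"n{i}" for i in range(30)]
        edges = sorted({(names[a], names[b]) for a, b in rng.integers(0, 30, (120, 2)) if a < b})
        kg = KnowledgeGraph(
            entities=tuple((n, "herb") for n in names),
            triples=tuple((a, "r", b) for a, b in edges),
        )
        S, ids = katz_matrix(kg, 0.02)
        errors = []
        for dim in (2, 6, 12, 24):
            emb = hope_embed(kg, HopeConfig(dimension=dim, beta=0.02))
            half = dim // 2
            approx = emb.vectors[:, :half] @ emb.vectors[:, half:].T
            errors.append(np.linalg.norm(S - approx))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_exact_recovery_at_full_rank(self):
        kg = path_kg("a", "b", "c", "d", "e", "f")
        S, _ = katz_matrix(kg, 0.2)
        rank = np.linalg.matrix_rank(S)
        emb = hope_embed(kg, HopeConfig(dimension=2 * rank, beta=0.2))
        half = rank
        approx = emb.vectors[:, :half] @ emb.vectors[:, half:].T
        assert np.linalg.norm(S - approx) < 1e-8


class TestPretrainDispatch:
    def test_none_method_is_deterministic_and_scaled(self, tiny_kg):
        a = pretrain(tiny_kg, "none", dimension=64, seed=3)
        b = pretrain(tiny_kg, "none", dimension=64, seed=3)
        np.testing.assert_array_equal(a.vectors, b.vectors)
        # standard-normal / sqrt(dim) rows have unit expected norm
        assert np.linalg.norm(a.vectors, axis=1).mean() == pytest.approx(1.0, rel=0.35)

    def test_deepwalk_covers_all_entities(self, tiny_kg):
        cfg = WalkConfig(num_walks_per_node=2, walk_length=4, dimension=8, epochs=1, seed=0)
        emb = pretrain(tiny_kg, "deepwalk", walk_config=cfg)
        assert sorted(emb.ids) == sorted(tiny_kg.entity_ids)

    def test_odd_hope_dimension_rejected(self, tiny_kg):
        with pytest.raises(ValueError):
            pretrain(tiny_kg, "hope", hope_config=HopeConfig(dimension=33))

    @pytest.mark.parametrize("method", ["line", "grarep", "word2vec"])
    def test_unsupported_backends_named_in_error(self, tiny_kg, method):
        with pytest.raises(ValueError, match="deepwalk"):
            pretrain(tiny_kg, method)


class TestEmbeddingIO:
    def test_round_trip_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        emb = EmbeddingMatrix(
            ids=tuple(f"e{i}" for i in range(5)), vectors=rng.standard_normal((5, 8))
        )
        write_embeddings(emb, tmp_path / "emb.txt")
        back = read_embeddings(tmp_path / "emb.txt")
        assert back.ids == emb.ids
        assert np.abs(back.vectors - emb.vectors).max() < 1e-7

    def test_header_row_mismatch(self, tmp_path):
        (tmp_path / "bad.txt").write_text("5 2\na 1 2\nb 3 4\n")
        with pytest.raises(ParseError, match="5 rows"):
            read_embeddings(tmp_path / "bad.txt")

    def test_dim_mismatch_names_entity(self, tmp_path):
        (tmp_path / "bad.txt").write_text("2 3\na 1 2 3\nb 1 2\n")
        with pytest.raises(ParseError, match="'b'"):
            read_embeddings(tmp_path / "bad.txt")
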