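import numpy as np
import pytest

from htipred.kg_data import (
    EvidenceRecord,
    HTIDataset,
    KnowledgeGraph,
    ParseError,
    SchemaError,
    SyntheticSpec,
    filter_evidence,
    generate_synthetic_hti,
    generate_synthetic_kg,
    read_pairs,
    read_triples,
    split_dataset,
    write_pairs,
    write_triples,
)


class TestKnowledgeGraphIO:
    def test_round_trip_preserves_triples(self, tiny_kg, tmp_path):
        write_triples(tiny_kg, tmp_path / "t.tsv", tmp_path / "e.tsv")
        kg = read_triples(tmp_path / "t.tsv", tmp_path / "e.tsv")
        assert kg.triples == tiny_kg.triples
        assert kg.entities == tiny_kg.entities
        assert kg.n_entities() == 3 and kg.n_triples() == 2

    def test_empty_files_give_empty_graph(self, tmp_path):
        (tmp_path / "t.tsv").write_text("")
        (tmp_path / "e.tsv").write_text("")
        kg = read_triples(tmp_path / "t.tsv", tmp_path / "e.tsv")
        assert kg.n_entities() == 0 and kg.n_triples() == 0

    def test_unknown_entity_in_triple_is_schema_error(self, tmp_path):
        (tmp_path / "t.tsv").write_text("h1\therb-target\tghost\n")
        (tmp_path / "e.tsv").write_text("h1\therb\n")
        with pytest.raises(SchemaError, match="ghost"):
            read_triples(tmp_path / "t.tsv", tmp_path / "e.tsv")

    def test_malformed_line_reports_line_number(self, tmp_path):
        (tmp_path / "t.tsv").write_text("h1\therb-target\tt1\nbroken line\n")
        (tmp_path / "e.tsv").write_text("h1\therb\nt1\ttarget\n")
        with pytest.raises(ParseError, match=":2"):
            read_triples(tmp_path / "t.tsv", tmp_path / "e.tsv")

    @pytest.mark.parametrize(
        "entities,triples",
        [
            ((("a", "herb"), ("a", "target")), ()),  # duplicate id
            ((("a", "herb"), ("b", "target")),
             (("a", "r", "b"), ("a", "r", "b"))),  # duplicate triple
        ],
    )
    def test_invariant_violations_rejected(self, entities, triples):
        with pytest.raises(SchemaError):
            KnowledgeGraph(entities=entities, triples=triples)


class TestFilterEvidence:
    def test_threshold_rule(self):
        records = [
            EvidenceRecord("h1", "t1", 0.5, 0.01),
            EvidenceRecord("h1", "t2", 0.4, 0.01),   # score too low
            EvidenceRecord("h2", "t1", 0.9, 0.2),    # p too high
        ]
        assert filter_evidence(records, 0.4616, 0.05) == {("h1", "t1")}

    def test_empty_and_duplicates(self):
        assert filter_evidence([]) == set()
        dup = [EvidenceRecord("h", "t", 0.9, 0.001)] * 3
        assert filter_evidence(dup) == {("h", "t")}

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        records = [
            EvidenceRecord(f"h{i%5}", f"t{i%7}", rng.random(), rng.random())
            for i in range(50)
        ]
        first = filter_evidence(records)
        assert filter_evidence(reversed(records)) == first

    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError):
            EvidenceRecord("h", "t", 0.5, 1.5)


class TestSplitDataset:
    def test_counts_follow_floor_rule(self):
        pairs = {(f"h{i}", f"t{i}") for i in range(100)}
        ds = split_dataset(pairs, (0.8, 0.1, 0.1), seed=1)
        assert len(ds.pairs_in_split("train")) == 80
        assert len(ds.pairs_in_split("val")) == 10
        assert len(ds.pairs_in_split("test")) == 10

    def test_benchmark_scale_floor_arithmetic(self):
        # 38 002 pairs at 8:1:1 -> floor gives 3 800 + 3 800, remainder 30 402
        pairs = {(f"h{i % 563}", f"t{i}") for i in range(38002)}
        ds = split_dataset(pairs, (0.8, 0.1, 0.1), seed=0)
        assert len(ds.pairs_in_split("val")) == 3800
        assert len(ds.pairs_in_split("test")) == 3800
        assert len(ds.pairs_in_split("train")) == 30402

    def test_deterministic_and_leak_free(self):
        pairs = {(f"h{i}", f"t{i*2}") for i in range(57)}
        a = split_dataset(pairs, seed=3)
        b = split_dataset(pairs, seed=3)
        assert a.split == b.split
        tr, va, te = (a.pairs_in_split(s) for s in ("train", "val", "test"))
        assert not (tr & va) and not (tr & te) and not (va & te)
        assert tr | va | te == set(pairs)

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError):
            split_dataset({("h1", "t1"), ("h2", "t2")})

    def test_bad_ratios_refused(self):
        pairs = {(f"h{i}", f"t{i}") for i in range(10)}
        with pytest.raises(ValueError):
            split_dataset(pairs, (0.5, 0.5, 0.5))


class TestHTIDataset:
    def test_overlapping_vocabularies_rejected(self):
        with pytest.raises(ValueError):
            HTIDataset(herbs=("x",), targets=("x",), positives=frozenset())

    def test_pairs_round_trip(self, tmp_path):
        pairs = {(f"h{i}", f"t{i}") for i in range(10)}
        ds = split_dataset(pairs, seed=0)
        write_pairs(ds, tmp_path / "pairs.tsv")
        back = read_pairs(tmp_path / "pairs.tsv")
        assert back.positives == ds.positives
        assert back.split == ds.split


class TestSyntheticHTI:
    def test_block_structure_dominates(self):
        spec = SyntheticSpec(n_herbs=40, n_targets=80, n_blocks=4, p_in=0.3, p_out=0.01, seed=7)
        ds = generate_synthetic_hti(spec)
        within = sum(
            1 for h, t in ds.positives
            if ds.herbs.index(h) % 4 == ds.targets.index(t) % 4
        )
        assert within / len(ds.positives) > 0.85

    def test_extreme_probabilities_give_block_complete_graph(self):
        spec = SyntheticSpec(n_herbs=8, n_targets=12, n_blocks=2, p_in=1.0, p_out=0.0, seed=0)
        ds = generate_synthetic_hti(spec)
        expected = {
            (h, t)
            for i, h in enumerate(ds.herbs)
            for j, t in enumerate(ds.targets)
            if i % 2 == j % 2
        }
        assert ds.positives == expected

    def test_deterministic(self):
        spec = SyntheticSpec(seed=5)
        assert generate_synthetic_hti(spec).positives == generate_synthetic_hti(spec).positives

    def test_every_herb_has_a_positive(self):
        spec = SyntheticSpec(n_herbs=30, n_targets=40, n_blocks=3, p_in=0.15, p_out=0.001, seed=2)
        ds = generate_synthetic_hti(spec)
        by_herb = ds.positives_by_herb()
        assert all(by_herb[h] for h in ds.herbs)

    def test_underpowered_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_hti(
                SyntheticSpec(n_herbs=50, n_targets=10, n_blocks=2, p_in=0.02, p_out=0.001)
            )

    def test_empirical_rates_match_probabilities(self):
        # 100x100 grid -> 10 000 candidate pairs; rates within 3 binomial SE
        spec = SyntheticSpec(n_herbs=100, n_targets=100, n_blocks=4, p_in=0.3, p_out=0.02, seed=11)
        ds = generate_synthetic_hti(spec)
        pos = ds.positives
        n_in = n_out = k_in = k_out = 0
        for i, h in enumerate(ds.herbs):
            for j, t in enumerate(ds.targets):
                if i % 4 == j % 4:
                    n_in += 1
                    k_in += (h, t) in pos
                else:
                    n_out += 1
                    k_out += (h, t) in pos
        for rate, p, n in ((k_in / n_in, 0.3, n_in), (k_out / n_out, 0.02, n_out)):
            assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestSyntheticKG:
    def test_herb_target_triples_are_exactly_train_positives(self, planted_dataset):
        ds, spec = planted_dataset
        kg = generate_synthetic_kg(spec, ds)
        ht = {(h, t) for h, r, t in kg.triples if r == "herb-target"}
        assert ht == ds.pairs_in_split("train")

    def test_no_heldout_pair_leaks_into_graph(self, planted_dataset, planted_kg):
        ds, _ = planted_dataset
        held_out = ds.pairs_in_split("val") | ds.pairs_in_split("test")
        edges = {(h, t) for h, _, t in planted_kg.triples}
        assert not (held_out & edges)

    def test_every_herb_has_auxiliary_context(self, planted_dataset, planted_kg):
        ds, _ = planted_dataset
        aux_heads = {h for h, r, _ in planted_kg.triples if r != "herb-target"}
        assert set(ds.herbs) <= aux_heads

    def test_herb_target_only_template(self, planted_dataset):
        ds, spec = planted_dataset
        from dataclasses import replace

        only = replace(spec, kg_relation_templates=(("herb", "herb-target", "target", 0),))
        kg = generate_synthetic_kg(only, ds)
        assert {(h, t) for h, _, t in kg.triples} == ds.pairs_in_split("train")

    def test_deterministic(self, planted_dataset):
        ds, spec = planted_dataset
        assert generate_synthetic_kg(spec, ds).triples == generate_synthetic_kg(spec, ds).triples

    def test_undeclared_type_rejected(self, planted_dataset):
        ds, spec = planted_dataset
        from dataclasses import replace

        bad = replace(spec, kg_relation_templates=(("herb", "herb-flavour", "flavour", 2),))
        with pytest.raises(SchemaError):
            generate_synthetic_kg(bad, ds)

    def test_same_block_herbs_share_more_aux_neighbours(self, planted_dataset, planted_kg):
        ds, _ = planted_dataset
        nbrs = {h: set() for h in ds.herbs}
        for h, r, t in planted_kg.triples:
            if h in nbrs and r != "herb-target":
                nbrs[h].add(t)
        same, cross = [], []
        herbs = list(ds.herbs)
        for i, a in enumerate(herbs):
            for b in herbs[i + 1:]:
                shared = len(nbrs[a] & nbrs[b])
                (same if herbs.index(a) % 4 == herbs.index(b) % 4 else cross).append(shared)
        assert np.mean(same) > np.mean(cross)
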