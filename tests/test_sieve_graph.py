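"""Similarity scoring, threshold-graph construction and greedy pruning."""

import itertools

import numpy as np
import pytest

from synsieve import (
    Neighbourhood,
    ProteinGene,
    RBHPair,
    build_graph,
    prune,
    sieve,
    similarity,
)


def stub_neighbourhood(label, n_genes):
    genes = [
        ProteinGene(f"p{i}", i * 100, i * 100 + 90, 1, "M" * 30)
        for i in range(n_genes)
    ]
    return Neighbourhood(label.upper(), "", 0, "A" * (n_genes * 100), genes, label)


def rbh_set(n):
    return {RBHPair(f"a::p{i}", f"b::p{i}") for i in range(n)}


class TestSimilarity:
    def test_identical_neighbourhoods_score_one(self):
        a, b = stub_neighbourhood("a", 5), stub_neighbourhood("b", 5)
        assert similarity(a, b, rbh_set(5)) == 1.0

    def test_proportion_of_smaller_neighbourhood(self):
        a, b = stub_neighbourhood("a", 4), stub_neighbourhood("b", 6)
        assert similarity(a, b, rbh_set(3)) == 0.75

    def test_no_rbh_scores_zero(self):
        a, b = stub_neighbourhood("a", 4), stub_neighbourhood("b", 6)
        assert similarity(a, b, set()) == 0.0

    def test_rbh_exceeding_min_gene_count_is_internal_error(self):
        a, b = stub_neighbourhood("a", 2), stub_neighbourhood("b", 6)
        with pytest.raises(RuntimeError, match="matching"):
            similarity(a, b, rbh_set(3))


class TestBuildGraph:
    def test_strictly_greater_than_threshold(self):
        g = build_graph(["a", "b", "c"], {("a", "b"): 0.9, ("a", "c"): 0.7}, 0.7)
        assert set(map(frozenset, g.graph.edges)) == {frozenset({"a", "b"})}

    def test_threshold_one_gives_edgeless_graph(self):
        g = build_graph(["a", "b"], {("a", "b"): 1.0}, 1.0)
        assert g.graph.number_of_edges() == 0

    def test_labels_without_scores_are_isolated_nodes(self):
        g = build_graph(["a", "b", "c"], {}, 0.7)
        assert sorted(g.graph.nodes) == ["a", "b", "c"]
        assert g.graph.number_of_edges() == 0

    @pytest.mark.parametrize("threshold", [0.0, -0.5, 1.01])
    def test_threshold_out_of_range_rejected(self, threshold):
        with pytest.raises(ValueError):
            build_graph(["a"], {}, threshold)


def reference_prune(nodes, weighted_edges):
    """Independent literal re-implementation of the greedy rules, on plain
    dicts: delete the max-(degree, weight-sum, label) node until edgeless."""
    adjacency = {n: {} for n in nodes}
    for (i, j), w in weighted_edges.items():
        adjacency[i][j] = w
        adjacency[j][i] = w
    removed = []
    while any(adjacency[n] for n in adjacency):
        victim = None
        victim_key = None
        for n in adjacency:
            if not adjacency[n]:
                continue
            key = (len(adjacency[n]), sum(adjacency[n].values()), n)
            if victim_key is None or key > victim_key:
                victim, victim_key = n, key
        removed.append(victim)
        for other in list(adjacency[victim]):
            del adjacency[other][victim]
        del adjacency[victim]
    return sorted(adjacency), removed


class TestPrune:
    def test_two_node_tie_removes_lexicographically_larger(self):
        g = build_graph(["a", "b"], {("a", "b"): 0.9}, 0.7)
        report = prune(g)
        assert report.kept == ["a"]
        assert [r[0] for r in report.removed] == ["b"]

    def test_path_removes_middle_node_first(self):
        g = build_graph(["a", "b", "c"], {("a", "b"): 0.9, ("b", "c"): 0.8}, 0.7)
        report = prune(g)
        assert report.kept == ["a", "c"]
        assert report.removed[0][0] == "b"
        assert report.removed[0][2] == 2  # degree at removal

    def test_edgeless_graph_keeps_everything(self):
        g = build_graph(["a", "b", "c"], {}, 0.7)
        report = prune(g)
        assert report.kept == ["a", "b", "c"]
        assert report.removed == []

    def test_nontransitive_triple_keeps_both_ends(self):
        scores = {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): 0.1}
        report = prune(build_graph(["a", "b", "c"], scores, 0.7))
        assert report.kept == ["a", "c"]

    def test_trigger_neighbour_is_heaviest_edge(self):
        scores = {("b", "a"): 0.8, ("b", "c"): 0.95}
        report = prune(build_graph(["a", "b", "c"], scores, 0.7))
        label, trigger, degree = report.removed[0]
        assert (label, trigger, degree) == ("b", "c", 2)

    def test_agrees_with_reference_on_random_graphs(self):
        rng = np.random.default_rng(101)
        labels = [f"n{i}" for i in range(7)]
        for _ in range(1000):
            n = int(rng.integers(2, 8))
            nodes = labels[:n]
            scores = {}
            for i, j in itertools.combinations(nodes, 2):
                if rng.random() < 0.45:
                    scores[(i, j)] = float(np.round(rng.uniform(0.71, 1.0), 3))
            report = prune(build_graph(nodes, scores, 0.7))
            ref_kept, ref_removed = reference_prune(nodes, scores)
            assert report.kept == ref_kept
            assert [r[0] for r in report.removed] == ref_removed

    def test_safety_and_idempotence_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 16))
            nodes = [f"m{i}" for i in range(n)]
            threshold = float(rng.uniform(0.3, 0.9))
            scores = {
                (i, j): float(rng.random())
                for i, j in itertools.combinations(nodes, 2)
                if rng.random() < 0.5
            }
            report = prune(build_graph(nodes, scores, threshold))
            kept = set(report.kept)
            for (i, j), s in scores.items():
                if i in kept and j in kept:
                    assert s <= threshold
            surviving = {k: v for k, v in scores.items() if set(k) <= kept}
            again = prune(build_graph(sorted(kept), surviving, threshold))
            assert again.kept == report.kept
            assert again.removed == []

    def test_monotonic_in_threshold(self):
        rng = np.random.default_rng(13)
        nodes = [f"t{i}" for i in range(10)]
        scores = {
            (i, j): float(rng.random())
            for i, j in itertools.combinations(nodes, 2)
        }
        kept_counts = [
            len(prune(build_graph(nodes, scores, t)).kept)
            for t in (0.2, 0.4, 0.6, 0.8, 0.99)
        ]
        assert kept_counts == sorted(kept_counts)


class TestSieve:
    def test_redundant_copies_collapse(self, family_set, tmp_path):
        in_dir, manifest = family_set
        report = sieve(in_dir, threshold=0.7, out_dir=tmp_path)
        assert len(report.kept) == 2
        assert "outsider" in report.kept

    def test_kept_files_are_byte_identical_copies(self, family_set, tmp_path):
        in_dir, _ = family_set
        report = sieve(in_dir, threshold=0.7, out_dir=tmp_path)
        for label in report.kept:
            src = (in_dir / f"{label}.gbk").read_bytes()
            dst = (tmp_path / "kept" / f"{label}.gbk").read_bytes()
            assert src == dst

    def test_threshold_above_every_score_keeps_all(self, family_set, tmp_path):
        in_dir, _ = family_set
        report = sieve(in_dir, threshold=1.0, out_dir=tmp_path)
        assert len(report.kept) == 4
        assert report.removed == []

    def test_resieving_output_removes_nothing(self, family_set, tmp_path):
        in_dir, _ = family_set
        first = sieve(in_dir, threshold=0.7, out_dir=tmp_path / "one")
        second = sieve(
            tmp_path / "one" / "kept", threshold=0.7, out_dir=tmp_path / "two"
        )
        assert second.kept == first.kept
        assert second.removed == []

    def test_kept_set_invariant_under_file_order(self, family_set, tmp_path):
        import shutil

        in_dir, _ = family_set
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        # populate in reverse order so directory enumeration differs
        for path in reversed(sorted(in_dir.glob("*.gbk"))):
            shutil.copyfile(path, shuffled / path.name)
        base = sieve(in_dir, threshold=0.7, out_dir=tmp_path / "a")
        again = sieve(shuffled, threshold=0.7, out_dir=tmp_path / "b")
        assert base.kept == again.kept

    def test_fewer_than_two_valid_files_is_error(self, tmp_path):
        only = tmp_path / "only"
        only.mkdir()
        (only / "junk.gbk").write_text("not genbank\n")
        with pytest.raises(ValueError, match="at least 2"):
            sieve(only, out_dir=tmp_path / "out")

    def test_unreadable_file_skipped_and_counted(self, family_set, tmp_path):
        import shutil

        in_dir, _ = family_set
        mixed = tmp_path / "mixed"
        mixed.mkdir()
        for path in in_dir.glob("*.gbk"):
            shutil.copyfile(path, mixed / path.name)
        (mixed / "broken.gbk").write_text("garbage\n")
        report = sieve(mixed, threshold=0.7, out_dir=tmp_path / "out")
        assert [name for name, _ in report.skipped] == ["broken.gbk"]
        assert len(report.kept) == 2
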