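import pytest

from consalign import (
    Alignment,
    build_graph,
    decode_consensus,
    encode_indices,
    merge,
    solve,
)
from consalign.errors import GraphConsistencyError
from consalign.synthetic import (
    SynthConfig,
    brute_force_path,
    generate_truth,
    make_constituents,
)


class TestEncodeIndices:
    def test_two_row_example(self):
        aln = Alignment.from_rows([("a", "AC-"), ("b", "A-G")])
        assert encode_indices(aln).column_keys == ((1, 1), (2, 1), (2, 2))

    def test_gap_free_rows_count_positions(self):
        aln = Alignment.from_rows([("a", "ABC"), ("b", "DEF")])
        assert encode_indices(aln).column_keys == ((1, 1), (2, 2), (3, 3))

    def test_staggered_example(self):
        aln = Alignment.from_rows([("a", "A-"), ("b", "-A")])
        assert encode_indices(aln).column_keys == ((1, 0), (1, 1))

    def test_last_key_is_ungapped_lengths(self, random_alignment_factory):
        aln = random_alignment_factory(seed=7)
        keys = encode_indices(aln).column_keys
        assert keys[-1] == tuple(len(r.ungapped) for r in aln.records)

    def test_keys_advance_by_zero_or_one(self, random_alignment_factory):
        aln = random_alignment_factory(seed=8)
        keys = encode_indices(aln).column_keys
        prev = (0,) * aln.n_sequences
        for key in keys:
            deltas = [b - a for a, b in zip(prev, key)]
            assert set(deltas) <= {0, 1} and any(d == 1 for d in deltas)
            prev = key


class TestBuildGraph:
    def test_identical_chains_superimpose(self):
        aln = Alignment.from_rows([("a", "AC-"), ("b", "A-G")])
        indexed = [encode_indices(aln)] * 4
        graph = build_graph(indexed)
        assert graph.n_edges == 3
        assert all(w == 4 for w in graph.edges.values())

    def test_gap_shift_toy_graph(self, gap_shift_pair):
        staggered, aligned = gap_shift_pair
        graph = build_graph([encode_indices(staggered), encode_indices(aligned)])
        assert graph.nodes == {(0, 0), (1, 0), (1, 1)}
        assert graph.edges == {
            ((0, 0), (1, 0)): 1,
            ((1, 0), (1, 1)): 1,
            ((0, 0), (1, 1)): 1,
        }

    def test_single_constituent_meets_node_bound_exactly(self):
        aln = Alignment.from_rows([("a", "ACGT"), ("b", "ACGT")])
        graph = build_graph([encode_indices(aln)])
        assert graph.n_nodes == aln.length + 1

    def test_edge_weight_mass_is_total_columns(self):
        a = Alignment.from_rows([("a", "AC-"), ("b", "A-G")])
        b = Alignment.from_rows([("a", "A-C"), ("b", "AG-")])
        graph = build_graph([encode_indices(a), encode_indices(b)])
        assert sum(graph.edges.values()) == a.length + b.length

    def test_mismatched_sinks_rejected(self):
        a = Alignment.from_rows([("a", "AC"), ("b", "AG")])
        b = Alignment.from_rows([("a", "ACC"), ("b", "AGG")])
        with pytest.raises(GraphConsistencyError):
            build_graph([encode_indices(a), encode_indices(b)])


class TestSolve:
    def test_chain_graph_single_path(self):
        aln = Alignment.from_rows([("a", "AC-"), ("b", "A-G")])
        graph = build_graph([encode_indices(aln)] * 3)
        path = solve(graph)
        assert [key for key, _ in path] == list(encode_indices(aln).column_keys)
        assert [w for _, w in path] == [3, 3, 3]

    def test_gap_shift_toy_tie_resolution(self, gap_shift_pair):
        # Both source->sink routes have mean edge weight 1; the tie rules
        # (equal ratio, equal weight, smallest source key) pick the direct
        # source->(1,1) edge, giving a single-column consensus.
        graph = build_graph([encode_indices(a) for a in gap_shift_pair])
        assert solve(graph) == [((1, 1), 1)]

    def test_matches_recursive_oracle_on_small_instances(self):
        for seed in range(20):
            config = SynthConfig(
                n_sequences=3, length=8, gap_fraction=0.25,
                k=4, perturb_rate=0.5, seed=seed,
            )
            truth = generate_truth(config)
            indexed = [
                encode_indices(a) for a in make_constituents(truth, config)
            ]
            graph = build_graph(indexed)
            assert solve(graph) == brute_force_path(graph)


class TestDecodeConsensus:
    def test_advancing_transition_emits_residue(self):
        result = decode_consensus(
            [((1, 1), 2)], {"a": "A", "b": "A"}, ["a", "b"], 2
        )
        assert [r.residues for r in result.alignment.records] == ["A", "A"]

    def test_stationary_component_emits_gap(self):
        result = decode_consensus(
            [((1, 0), 1), ((1, 1), 1)], {"a": "A", "b": "A"}, ["a", "b"], 2
        )
        assert [r.residues for r in result.alignment.records] == ["A-", "-A"]


class TestMerge:
    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_idempotent_on_copies(self, k, random_alignment_factory):
        aln = random_alignment_factory(seed=3)
        result = merge([aln] * k)
        assert result.alignment == aln
        assert result.raw_scores == (k,) * aln.length
        assert result.normalized_scores == (1.0,) * aln.length

    def test_gap_shift_toy_consensus(self, gap_shift_pair):
        result = merge(list(gap_shift_pair))
        assert [r.residues for r in result.alignment.records] == ["A", "A"]
        assert result.raw_scores == (1,)
        assert result.normalized_scores == (0.5,)

    def test_residue_conservation(self):
        config = SynthConfig(
            n_sequences=5, length=40, gap_fraction=0.2,
            k=6, perturb_rate=0.4, seed=11,
        )
        truth = generate_truth(config)
        result = merge(make_constituents(truth, config))
        assert result.alignment.ungapped_map() == truth.ungapped_map()

    def test_score_bounds_and_graph_bounds(self):
        for seed in range(5):
            config = SynthConfig(
                n_sequences=4, length=30, gap_fraction=0.2,
                k=5, perturb_rate=0.3, seed=seed,
            )
            truth = generate_truth(config)
            constituents = make_constituents(truth, config)
            indexed = [encode_indices(a) for a in constituents]
            graph = build_graph(indexed)
            max_cols = max(a.length for a in constituents)
            assert graph.n_nodes <= graph.k * max_cols + 1
            assert all(1 <= w <= graph.k for w in graph.edges.values())
            degree_in: dict = {}
            degree_out: dict = {}
            for u, v in graph.edges:
                degree_out[u] = degree_out.get(u, 0) + 1
                degree_in[v] = degree_in.get(v, 0) + 1
            assert max(degree_in.values()) <= graph.k
            assert max(degree_out.values()) <= graph.k
            result = merge(constituents)
            assert all(1 <= w <= graph.k for w in result.raw_scores)
            assert all(0 < s <= 1 for s in result.normalized_scores)
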