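import math

import numpy as np
import pytest

from ldgraphs import (
    ChromGraph,
    FastConfig,
    MarkerMatrix,
    SelectionConfig,
    StitchState,
    backward_prune,
    block_bounds,
    clique_forest,
    delta_score,
    edge_addable,
    edge_removable,
    fast_forward,
    fit_fast,
    fit_standard,
    forward_search,
    is_chordal,
    model_score,
    skeleton,
    stitch,
)
from ldgraphs.simulate import GeneratorConfig, random_ld_model, sample

from .conftest import markov_chain_matrix, nx_is_chordal


class TestSkeleton:
    def test_p1(self):
        assert skeleton(1).edges == frozenset()

    def test_p5(self):
        g = skeleton(5)
        assert g.edges == frozenset({(1, 2), (2, 3), (3, 4), (4, 5)})

    def test_all_heights_one(self):
        from ldgraphs import heights_widths

        ip = heights_widths(skeleton(6))
        assert ip.heights == [1] * 5 and ip.widths == [1] * 5

    def test_rejects_p0(self):
        with pytest.raises(ValueError):
            skeleton(0)


class TestSelectionConfig:
    def test_alpha_presets(self):
        assert SelectionConfig(criterion="aic").resolve_alpha(100) == 2.0
        assert SelectionConfig(criterion="bic").resolve_alpha(100) == pytest.approx(
            math.log(100)
        )

    def test_explicit_alpha_wins(self):
        assert SelectionConfig(criterion="bic", alpha=5.0).resolve_alpha(100) == 5.0

    def test_alpha_positive(self):
        with pytest.raises(ValueError):
            SelectionConfig(alpha=-1.0).resolve_alpha(10)


class TestForwardSearch:
    def test_rejects_non_chordal_start(self, small_binary_matrix):
        g = ChromGraph(4, [(1, 2), (2, 3), (3, 4), (1, 4)])
        m = MarkerMatrix(small_binary_matrix.values[:, :4], "haplotype")
        with pytest.raises(ValueError):
            forward_search(m, g)

    def test_chain_null_rarely_adds(self):
        # v1 _||_ v3 | v2 with strong serial dependence: BIC should keep
        # the skeleton in nearly all replicates
        no_add = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = markov_chain_matrix(rng, 2000, 3)
            res = forward_search(m, skeleton(3))
            if not res.trace:
                no_add += 1
        assert no_add >= 18

    def test_xor_dependence_detected(self):
        # v3 = v1 XOR v2 (noisy): strong conditional dependence of (1,3)
        # given 2 forces the chord to be added
        added = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 2000
            v1 = rng.integers(0, 2, n)
            v2 = rng.integers(0, 2, n)
            noise = rng.random(n) < 0.05
            v3 = np.where(noise, rng.integers(0, 2, n), v1 ^ v2)
            m = MarkerMatrix(
                np.column_stack([v1, v2, v3]).astype(np.int8), "haplotype"
            )
            res = forward_search(m, skeleton(3))
            if res.graph.has_edge(1, 3):
                added += 1
        assert added >= 18

    def test_termination_no_improving_addition(self, rng):
        m = MarkerMatrix(rng.integers(0, 2, size=(300, 8)).astype(np.int8), "haplotype")
        cfg = SelectionConfig()
        res = forward_search(m, skeleton(8), cfg)
        alpha = cfg.resolve_alpha(m.n_rows)
        g = res.graph
        for a in range(1, 9):
            for b in range(a + 1, 9):
                if g.has_edge(a, b):
                    continue
                ok, S = edge_addable(g, None, a, b)
                if ok:
                    d = delta_score(m, None, a, b, S, alpha)
                    assert d.d_ic >= 0

    def test_contains_start_graph_and_chordal(self, rng):
        m = MarkerMatrix(rng.integers(0, 2, size=(200, 10)).astype(np.int8), "haplotype")
        res = forward_search(m, skeleton(10))
        assert skeleton(10).edges <= res.graph.edges
        assert is_chordal(res.graph)


class TestBackwardPrune:
    def test_independent_adjacent_pair_pruned(self):
        pruned = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.integers(0, 2, size=(5000, 2)).astype(np.int8)
            m = MarkerMatrix(vals, "haplotype")
            res = backward_prune(m, skeleton(2))
            if not res.graph.has_edge(1, 2):
                pruned += 1
        assert pruned >= 18

    def test_saturated_clique_on_independent_data(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.integers(0, 2, size=(5000, 3)).astype(np.int8)
            m = MarkerMatrix(vals, "haplotype")
            g = ChromGraph(3, [(1, 2), (1, 3), (2, 3)])
            res = backward_prune(m, g)
            if not res.graph.edges:
                empty += 1
        assert empty >= 18

    def test_termination_no_improving_removal(self, rng):
        m = markov_chain_matrix(rng, 500, 6)
        cfg = SelectionConfig()
        res = backward_prune(m, forward_search(m, skeleton(6), cfg).graph, cfg)
        alpha = cfg.resolve_alpha(m.n_rows)
        for a, b in res.graph.edges:
            ok, S = edge_removable(res.graph, None, a, b)
            if ok:
                d = delta_score(m, None, a, b, S, alpha, direction="remove")
                assert d.d_ic >= 0


class TestFitStandard:
    def test_independent_columns_give_empty_graph(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = MarkerMatrix(
                rng.integers(0, 2, size=(5000, 3)).astype(np.int8), "haplotype"
            )
            if not fit_standard(m).graph.edges:
                empty += 1
        assert empty >= 18

    def test_ic_never_worse_than_skeleton(self, rng):
        m = markov_chain_matrix(rng, 400, 8)
        cfg = SelectionConfig()
        res = fit_standard(m, cfg)
        alpha = cfg.resolve_alpha(m.n_rows)
        ic0 = model_score(m, clique_forest(skeleton(8)), alpha).ic
        assert res.score.ic <= ic0 + 1e-9

    def test_local_optimality_exhaustive(self):
        # p=5: after the search, no single-edge perturbation improves IC
        rng = np.random.default_rng(5)
        tg, model, _ = random_ld_model(GeneratorConfig(p=5, n_extra=2, max_width=3, seed=5))
        m = sample(model, 1000, seed=5)
        cfg = SelectionConfig()
        res = fit_standard(m, cfg)
        alpha = cfg.resolve_alpha(m.n_rows)
        g = res.graph
        for a in range(1, 6):
            for b in range(a + 1, 6):
                if g.has_edge(a, b):
                    ok, S = edge_removable(g, None, a, b)
                    direction = "remove"
                else:
                    ok, S = edge_addable(g, None, a, b)
                    direction = "add"
                if ok:
                    d = delta_score(m, None, a, b, S, alpha, direction=direction)
                    assert d.d_ic >= -1e-9

    def test_trace_replay_reproduces_graph(self, rng):
        m = markov_chain_matrix(rng, 600, 10)
        res = fit_standard(m)
        g = skeleton(10)
        for step in res.trace:
            a, b = step.edge
            g = g.with_edge(a, b) if step.direction == "add" else g.without_edge(a, b)
            assert is_chordal(g)
            assert step.delta.d_ic < 0
        assert g == res.graph


class TestBlockBounds:
    def test_default_blocks(self):
        assert block_bounds(260, FastConfig(100, 20)) == [
            (1, 100),
            (81, 180),
            (161, 260),
        ]

    def test_single_block(self):
        assert block_bounds(100, FastConfig(100, 20)) == [(1, 100)]

    def test_partial_final_block(self):
        assert block_bounds(150, FastConfig(100, 20)) == [(1, 100), (81, 150)]

    def test_small_p(self):
        assert block_bounds(10, FastConfig(100, 20)) == [(1, 10)]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FastConfig(10, 10)
        with pytest.raises(ValueError):
            block_bounds(0, FastConfig(100, 20))


class TestStitch:
    def test_spec_example(self):
        skel = lambda lo, hi: {(i, i + 1) for i in range(lo, hi)}
        state = StitchState(skel(1, 10) | {(5, 8)}, 10)
        block2 = skel(7, 16)
        out = stitch(state, block2, 7, 16, 10, K=4)
        assert out.m_star == 8
        assert out.cum_edges == skel(1, 16) | {(5, 8)}
        assert out.e == 16
        assert not out.violated

    def test_pure_skeletons(self):
        skel = lambda lo, hi: {(i, i + 1) for i in range(lo, hi)}
        state = StitchState(skel(1, 10), 10)
        out = stitch(state, skel(7, 16), 7, 16, 10, K=4)
        assert out.m_star == 7  # largest w among cum edges with v <= 6
        assert out.cum_edges == skel(1, 16)

    def test_violation_flagged(self):
        skel = lambda lo, hi: {(i, i + 1) for i in range(lo, hi)}
        state = StitchState(skel(1, 10) | {(5, 8)}, 10)
        block2 = skel(7, 16) | {(8, 12)}
        out = stitch(state, block2, 7, 16, 10, K=4)
        assert out.m_star == 8
        assert out.violated
        assert out.warnings

    def test_precondition_on_start(self):
        state = StitchState({(1, 2)}, 10)
        with pytest.raises(ValueError):
            stitch(state, set(), 8, 16, 10, K=4)
        with pytest.raises(ValueError):
            stitch(state, set(), 7, 16, 9, K=4)


class TestFastForward:
    def test_single_block_equals_forward_search(self, rng):
        m = markov_chain_matrix(rng, 500, 30)
        g, warns = fast_forward(m, fc=FastConfig(100, 20))
        ref = forward_search(m, skeleton(30))
        assert g == ref.graph

    def test_no_spurious_cross_boundary_edges(self, rng):
        # two independent halves: nothing but the skeleton edge may cross
        left = markov_chain_matrix(rng, 1500, 80)
        right = markov_chain_matrix(rng, 1500, 80)
        m = MarkerMatrix(
            np.column_stack([left.values, right.values]), "haplotype"
        )
        g, warns = fast_forward(m, fc=FastConfig(40, 10))
        for a, b in g.edges:
            if a <= 80 < b:
                assert (a, b) == (80, 81)

    def test_output_chordal_contains_skeleton(self, rng):
        m = markov_chain_matrix(rng, 400, 120)
        g, warns = fast_forward(m, fc=FastConfig(50, 10))
        assert nx_is_chordal(g)
        assert skeleton(120).edges <= g.edges

    def test_deterministic(self, rng):
        m = markov_chain_matrix(rng, 300, 60)
        g1, _ = fast_forward(m, fc=FastConfig(30, 8))
        g2, _ = fast_forward(m, fc=FastConfig(30, 8))
        assert g1 == g2


class TestFitFast:
    def test_close_to_standard(self):
        tg, model, _ = random_ld_model(
            GeneratorConfig(p=120, n_extra=25, max_width=6, seed=3)
        )
        m = sample(model, 1500, seed=3)
        rf = fit_fast(m)
        rs = fit_standard(m)
        sym = len(rf.graph.edges ^ rs.graph.edges)
        assert sym <= max(1, 0.01 * rs.graph.n_edges)

    def test_ic_improves_on_fast_forward(self, rng):
        m = markov_chain_matrix(rng, 400, 50)
        cfg = SelectionConfig()
        g, _ = fast_forward(m, cfg, FastConfig(30, 8))
        res = fit_fast(m, cfg, FastConfig(30, 8))
        alpha = cfg.resolve_alpha(m.n_rows)
        ic_fwd = model_score(m, clique_forest(g), alpha).ic
        assert math.isfinite(res.score.ic)
        assert res.score.ic <= ic_fwd + 1e-9
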