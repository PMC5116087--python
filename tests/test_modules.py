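"""Coexpression distance, clustering, filtering and module merging."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ipanda.modules import (
    CoexpressionMatrix,
    GeneModule,
    ModuleSet,
    build_modules,
    coexpression_distance,
    detect_clusters,
    filter_clusters,
    merge_cluster_sets,
)


def block_corr_matrix(blocks, n_extra=0, rho=0.9, seed=0):
    """Exact block-structured correlation matrix plus uncorrelated genes."""
    genes = [g for blk in blocks for g in blk] + [
        f"x{i}" for i in range(n_extra)
    ]
    n = len(genes)
    corr = np.eye(n)
    pos = {g: i for i, g in enumerate(genes)}
    for blk in blocks:
        for a in blk:
            for b in blk:
                if a != b:
                    corr[pos[a], pos[b]] = rho
    return CoexpressionMatrix(genes, corr)


class TestDistance:
    @pytest.mark.parametrize(
        "corr, expected",
        [(1.0, 0.0), (0.0, math.sqrt(2)), (-1.0, 2.0), (0.5, 1.0)],
    )
    def test_transform(self, corr, expected):
        m = CoexpressionMatrix(["a", "b"], np.array([[1, corr], [corr, 1]], float))
        d = coexpression_distance(m)
        assert d[0, 1] == pytest.approx(expected, abs=1e-12)
        assert d[0, 0] == 0.0 and d[1, 0] == d[0, 1]

    def test_out_of_range_corr_rejected(self):
        with pytest.raises(ValueError):
            CoexpressionMatrix(["a", "b"], np.array([[1, 1.5], [1.5, 1]]))

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            CoexpressionMatrix(
                ["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]])
            )


class TestDetectClusters:
    @pytest.mark.parametrize("method", ["dbscan", "hierarchical_average"])
    def test_two_blocks_recovered(self, method):
        blocks = [[f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]]
        coexpr = block_corr_matrix(blocks)
        found = detect_clusters(
            coexpression_distance(coexpr), coexpr.gene_ids, method=method
        )
        assert sorted(sorted(c) for c in found) == sorted(
            sorted(b) for b in blocks
        )

    def test_identity_correlation_gives_nothing(self):
        coexpr = block_corr_matrix([], n_extra=10)
        assert detect_clusters(
            coexpression_distance(coexpr), coexpr.gene_ids
        ) == []

    def test_planted_block_among_noise(self):
        coexpr = block_corr_matrix([["a", "b", "c"]], n_extra=20, rho=0.95)
        found = detect_clusters(
            coexpression_distance(coexpr), coexpr.gene_ids
        )
        assert found == [frozenset({"a", "b", "c"})]

    def test_single_gene_input(self):
        coexpr = CoexpressionMatrix(["a"], np.array([[1.0]]))
        assert detect_clusters(
            coexpression_distance(coexpr), coexpr.gene_ids
        ) == []

    @pytest.mark.parametrize("b", [1, 2, 4, 7, 10])
    def test_planted_block_counts(self, b):
        sizes = [3 + (i * 5) % 18 for i in range(b)]
        blocks = [
            [f"g{i}_{j}" for j in range(size)] for i, size in enumerate(sizes)
        ]
        coexpr = block_corr_matrix(blocks, n_extra=15, rho=0.8)
        modules = build_modules(coexpr)
        assert len(modules) == b
        recovered = sorted(sorted(m.genes) for m in modules.modules)
        assert recovered == sorted(sorted(blk) for blk in blocks)


class TestFilterClusters:
    def test_threshold_is_strict(self):
        for rho, kept in [(0.31, True), (0.30, False)]:
            coexpr = block_corr_matrix([["a", "b"]], rho=rho)
            out = filter_clusters([{"a", "b"}], coexpr)
            assert bool(out) is kept

    def test_mean_over_pairs(self):
        corr = np.array(
            [[1.0, 0.6, 0.2], [0.6, 1.0, 0.2], [0.2, 0.2, 1.0]]
        )
        coexpr = CoexpressionMatrix(["a", "b", "c"], corr)
        out = filter_clusters([{"a", "b", "c"}], coexpr)
        assert len(out) == 1
        assert out[0].mean_internal_corr == pytest.approx(1 / 3)

    def test_monotone_in_threshold(self):
        coexpr = block_corr_matrix(
            [["a", "b"], ["c", "d"]], rho=0.5
        )
        clusters = [{"a", "b"}, {"c", "d"}]
        kept = [
            len(filter_clusters(clusters, coexpr, min_corr=t))
            for t in (0.1, 0.3, 0.5, 0.7)
        ]
        assert kept == sorted(kept, reverse=True)


class TestMerge:
    def test_high_overlap_merges(self):
        a = [{f"g{i}" for i in range(1, 11)}]
        b = [{f"g{i}" for i in range(1, 9)} | {"g11"}]
        out = merge_cluster_sets(a, b)
        assert len(out) == 1
        assert out.modules[0].genes == {f"g{i}" for i in range(1, 12)}
        assert out.modules[0].source == "merged"

    def test_low_overlap_kept_separate(self):
        a = [{f"g{i}" for i in range(1, 11)}]
        b = [{f"g{i}" for i in range(1, 6)} | {f"g{i}" for i in range(11, 16)}]
        out = merge_cluster_sets(a, b)
        # overlap 5/15 < 0.7: not merged; overlap resolved by disjointness
        assert len(out) == 2

    def test_disjoint_sets_unchanged(self):
        a = [{"a1", "a2"}]
        b = [{"b1", "b2"}]
        out = merge_cluster_sets(a, b)
        assert sorted(sorted(m.genes) for m in out.modules) == [
            ["a1", "a2"], ["b1", "b2"],
        ]

    def test_min_metric_option(self):
        # |A∩B|=8, min size 9 -> 0.889 merges under "min" at 0.85 where
        # Jaccard (8/11) would not
        a = [{f"g{i}" for i in range(1, 11)}]
        b = [{f"g{i}" for i in range(1, 9)} | {"g11"}]
        merged = merge_cluster_sets(a, b, 0.85, overlap_metric="min")
        assert merged.modules[0].genes == {f"g{i}" for i in range(1, 12)}
        kept = merge_cluster_sets(a, b, 0.85, overlap_metric="jaccard")
        assert "g11" not in kept.assignment  # not merged; remnant dropped

    @given(
        st.lists(
            st.sets(st.integers(0, 30), min_size=2, max_size=10),
            min_size=1,
            max_size=6,
        ),
        st.lists(
            st.sets(st.integers(0, 30), min_size=2, max_size=10),
            min_size=0,
            max_size=6,
        ),
    )
    def test_fixpoint_and_disjoint(self, set_a, set_b):
        set_a = [{f"g{i}" for i in s} for s in set_a]
        set_b = [{f"g{i}" for i in s} for s in set_b]
        out = merge_cluster_sets(set_a, set_b)
        # disjointness
        seen = set()
        for mod in out.modules:
            assert len(mod.genes) >= 2
            assert not (mod.genes & seen)
            seen |= mod.genes
        # fixpoint: merging the output with nothing changes nothing
        again = merge_cluster_sets([m.genes for m in out.modules], [])
        assert sorted(sorted(m.genes) for m in again.modules) == sorted(
            sorted(m.genes) for m in out.modules
        )


class TestModuleSet:
    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError):
            ModuleSet.from_modules(
                [GeneModule("a", {"x", "y"}), GeneModule("b", {"y", "z"})]
            )

    def test_single_gene_module_rejected(self):
        with pytest.raises(ValueError):
            GeneModule("a", {"x"})


class TestBuildModules:
    def test_tf_sets_intersected_with_pathway_genes(self):
        coexpr = block_corr_matrix([], n_extra=6)
        tf = {"TF1": {"x0", "x1", "x2", "unrelated"}}
        out = build_modules(
            coexpr, tf, pathway_genes={"x0", "x1", "x2"}
        )
        assert len(out) == 1
        assert out.modules[0].genes == {"x0", "x1", "x2"}
        assert out.modules[0].source == "tf_targets"
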