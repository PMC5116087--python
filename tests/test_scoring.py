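"""Pathway scoring algebra, Z-normalization and weighted Fisher."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipanda.io import SampleAnnotation
from ipanda.modules import GeneModule, ModuleSet
from ipanda.scoring import (
    ScoreMatrix,
    ScoringConfig,
    ipanda_scores,
    unit_contribution,
    weighted_fisher,
    zscore_normalize,
)
from ipanda.topology import PathwayDatabase

from conftest import expr, make_graph

RAW = ScoringConfig(size_normalize=False)


def single_pathway_db(graph):
    return PathwayDatabase([graph])


def gene_values(genes, case_value, n_cases=2, n_normals=2, spread=0.0):
    """Case/normal matrices: normals at 0, cases at case_value per gene."""
    rng = np.random.default_rng(0)
    cases = {
        g: [v + spread * rng.normal() for _ in range(n_cases)]
        for g, v in zip(genes, case_value)
    }
    normals = {g: [0.0] * n_normals for g in genes}
    return (
        expr(cases, [f"c{i}" for i in range(n_cases)]),
        expr(normals, [f"n{i}" for i in range(n_normals)]),
    )


class TestUnitContribution:
    def test_gene_all_unit_weights(self):
        out = unit_contribution("gene", +1, 1.0, [[1.5]], [1.0])
        assert np.allclose(out, 1.5)

    def test_sign_flip(self):
        out = unit_contribution("gene", -1, 1.0, [[1.5]], [1.0])
        assert np.allclose(out, -1.5)

    def test_module_mean_aggregation(self):
        out = unit_contribution(
            "module", +1, 0.5, [[1.0], [3.0]], [1.0, 1.0], agg="mean"
        )
        assert np.allclose(out, 1.0)

    def test_zero_stat_weight_contributes_zero(self):
        out = unit_contribution("gene", +1, 1.0, [[123.0]], [0.0])
        assert np.allclose(out, 0.0)


class TestIpandaScores:
    def test_single_activator(self):
        g = make_graph("p", ["g1"], [])
        cases, normals = gene_values(["g1"], [2.0])
        scores = ipanda_scores(cases, normals, single_pathway_db(g), cfg=RAW)
        assert np.allclose(scores.data.loc["p"], 2.0)

    def test_activator_inhibitor_cancel(self):
        g = make_graph("p", ["g1", "g2"], [], signs={"g2": -1})
        cases, normals = gene_values(["g1", "g2"], [2.0, 2.0])
        scores = ipanda_scores(cases, normals, single_pathway_db(g), cfg=RAW)
        assert np.allclose(scores.data.loc["p"], 0.0)

    def test_diamond_composition(self, diamond):
        cases, normals = gene_values(list("ABCD"), [1.0] * 4)
        raw = ipanda_scores(cases, normals, single_pathway_db(diamond), cfg=RAW)
        assert np.allclose(raw.data.loc["diamond"], 3.0)
        norm = ipanda_scores(cases, normals, single_pathway_db(diamond))
        assert np.allclose(norm.data.loc["diamond"], 3.0 / 4)

    def test_pathway_absent_from_data_scores_zero(self, diamond, caplog):
        g = make_graph("q", ["zz"], [])
        cases, normals = gene_values(list("ABCD"), [1.0] * 4)
        db = PathwayDatabase([diamond, g])
        with caplog.at_level("WARNING", logger="ipanda"):
            scores = ipanda_scores(cases, normals, db, cfg=RAW)
        assert np.allclose(scores.data.loc["q"], 0.0)
        assert "no genes" in caplog.text

    def test_linearity_in_log_fc(self, diamond):
        db = single_pathway_db(diamond)
        cases1, normals = gene_values(list("ABCD"), [1.0, 0.5, 2.0, 1.5])
        cases3 = expr(
            {g: list(3 * cases1.data.loc[g]) for g in cases1.gene_ids},
            cases1.sample_ids,
        )
        s1 = ipanda_scores(cases1, normals, db, cfg=RAW).data
        s3 = ipanda_scores(cases3, normals, db, cfg=RAW).data
        # weights are recomputed, so fix them equal via identical p-values:
        # zero-variance groups give w=1 in both scenarios
        assert np.allclose(s3.to_numpy(), 3 * s1.to_numpy())

    def test_antisymmetry(self, diamond):
        db = single_pathway_db(diamond)
        cases, normals = gene_values(list("ABCD"), [1.0, 0.5, 2.0, 1.5])
        neg = expr(
            {g: list(-cases.data.loc[g]) for g in cases.gene_ids},
            cases.sample_ids,
        )
        s = ipanda_scores(cases, normals, db, cfg=RAW).data
        sn = ipanda_scores(neg, normals, db, cfg=RAW).data
        assert np.allclose(sn.to_numpy(), -s.to_numpy())

    def test_size_normalized_scores_match_across_pathway_sizes(self):
        """With unit weights and equal per-gene response, a 5-gene and a
        40-gene pathway score identically under the default normalization."""
        small = make_graph("small", [f"s{i}" for i in range(5)], [])
        large = make_graph("large", [f"l{i}" for i in range(40)], [])
        genes = [f"s{i}" for i in range(5)] + [f"l{i}" for i in range(40)]
        cases, normals = gene_values(genes, [0.7] * len(genes))
        scores = ipanda_scores(cases, normals, PathwayDatabase([small, large]))
        assert np.allclose(scores.data.loc["small"], scores.data.loc["large"])
        raw = ipanda_scores(cases, normals, PathwayDatabase([small, large]),
                            cfg=RAW)
        assert np.allclose(raw.data.loc["large"],
                           8 * raw.data.loc["small"])

    def test_module_exchangeability(self):
        """Two identical coexpressed genes in parallel positions score the
        same whether kept separate or collapsed into one module."""
        g = make_graph(
            "p", ["A", "g1", "g2", "D"],
            [("A", "g1"), ("A", "g2"), ("g1", "D"), ("g2", "D")],
        )
        db = single_pathway_db(g)
        cases, normals = gene_values(["A", "g1", "g2", "D"],
                                     [1.0, 0.8, 0.8, 1.2])
        mods = ModuleSet.from_modules([GeneModule("m", {"g1", "g2"})])
        separate = ipanda_scores(cases, normals, db, None).data
        collapsed = ipanda_scores(cases, normals, db, mods).data
        assert np.allclose(separate.to_numpy(), collapsed.to_numpy())

    def test_member_weighting_option_matches_spec_form(self):
        g = make_graph("p", ["g1", "g2"], [])
        mods = ModuleSet.from_modules([GeneModule("m", {"g1", "g2"})])
        cases, normals = gene_values(["g1", "g2"], [1.0, 3.0])
        cfg = ScoringConfig(size_normalize=False, module_weight="member")
        scores = ipanda_scores(cases, normals, single_pathway_db(g), mods, cfg)
        # one collapsed unit, w_T = 1, both w_S = 1: mean(1*1, 1*3) = 2
        assert np.allclose(scores.data.loc["p"], 2.0)


class TestZscore:
    def annotations(self, samples, dataset="d1", phenotypes=None):
        return [
            SampleAnnotation(
                s, dataset, "case", (phenotypes or {}).get(s, "unknown")
            )
            for s in samples
        ]

    def test_two_samples_population_sd(self):
        sm = ScoreMatrix(
            pd.DataFrame([[1.0, 3.0]], index=["p"], columns=["s1", "s2"])
        )
        z = zscore_normalize(sm, self.annotations(["s1", "s2"]))
        assert np.allclose(z.data.loc["p"], [-1.0, 1.0])
        assert z.normalized

    def test_constant_row_maps_to_zero(self):
        sm = ScoreMatrix(
            pd.DataFrame([[2.0, 2.0, 2.0]], index=["p"],
                         columns=["s1", "s2", "s3"])
        )
        z = zscore_normalize(sm, self.annotations(["s1", "s2", "s3"]))
        assert np.allclose(z.data.loc["p"], 0.0)

    def test_per_dataset_location_invariance(self):
        base = np.array([[1.0, 3.0, 2.0]])
        sm = ScoreMatrix(
            pd.DataFrame(
                np.hstack([base, base + 10.0]), index=["p"],
                columns=["a1", "a2", "a3", "b1", "b2", "b3"],
            )
        )
        anns = self.annotations(["a1", "a2", "a3"], "dA") + self.annotations(
            ["b1", "b2", "b3"], "dB"
        )
        z = zscore_normalize(sm, anns)
        assert np.allclose(
            z.data[["a1", "a2", "a3"]].to_numpy(),
            z.data[["b1", "b2", "b3"]].to_numpy(),
        )

    def test_balanced_centering_with_phenotypes(self):
        # 3 responders at 1, 1 non-responder at 5: balanced center is 3,
        # not the plain mean 2
        sm = ScoreMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0, 5.0]], index=["p"],
                         columns=["s1", "s2", "s3", "s4"])
        )
        phen = {"s1": "responder", "s2": "responder", "s3": "responder",
                "s4": "non-responder"}
        z = zscore_normalize(sm, self.annotations(list(phen), phenotypes=phen))
        sd = np.std([1, 1, 1, 5])
        assert np.allclose(z.data.loc["p"], (np.array([1, 1, 1, 5]) - 3) / sd)

    def test_single_sample_dataset_rejected(self):
        sm = ScoreMatrix(pd.DataFrame([[1.0]], index=["p"], columns=["s1"]))
        with pytest.raises(ValueError):
            zscore_normalize(sm, self.annotations(["s1"]))


class TestWeightedFisher:
    def test_single_unit_identity(self):
        assert weighted_fisher([0.05], [1.0]) == pytest.approx(0.05, abs=1e-12)

    def test_two_units_chi2(self):
        x = -2 * 2 * np.log(0.05)
        expected = stats.chi2.sf(x, df=4)
        assert weighted_fisher([0.05, 0.05], [1.0, 1.0]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.017479, abs=1e-6)

    def test_zero_weight_unit_excluded(self):
        assert weighted_fisher([0.05, 0.001], [1.0, 0.0]) == pytest.approx(
            0.05, abs=1e-12
        )

    def test_all_zero_weights_return_one(self, caplog):
        with caplog.at_level("WARNING", logger="ipanda"):
            assert weighted_fisher([0.5, 0.5], [0.0, 0.0]) == 1.0

    @pytest.mark.parametrize("n", [1, 2, 5, 10, 20])
    def test_reduces_to_classical_fisher(self, n):
        rng = np.random.default_rng(n)
        p = rng.uniform(1e-6, 1.0, size=n)
        x = -2 * np.sum(np.log(p))
        classical = stats.chi2.sf(x, df=2 * n)
        assert weighted_fisher(p, np.ones(n)) == pytest.approx(
            classical, abs=1e-10
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            weighted_fisher([0.0], [1.0])

    def test_significance_pipeline(self, diamond):
        cases, normals = gene_values(list("ABCD"), [2.0] * 4, n_cases=4,
                                     n_normals=4, spread=0.1)
        _, sig = ipanda_scores(
            cases, normals, PathwayDatabase([diamond]),
            return_significance=True,
        )
        assert 0 < sig["diamond"] < 0.05
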