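"""Desk-scale replications of the method's validation experiments.

Three seeded studies, each fully synthetic and shared by the test suite and
the acceptance script:

* ``noise_reduction_experiment`` — the dual-platform design: the same
  samples measured on two noisy platforms; pathway scores should correlate
  better between platforms than differential-gene fold changes do.
* ``cmp_ablation_experiment`` — the robustness design: several independent
  datasets share planted response pathways; the CMP index with topology and
  modules enabled is compared against switching either off.
* ``planted_recovery_experiment`` — a planted perturbed pathway should top
  the mean-AUC marker ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .differential import group_ttest, log_fold_changes
from .markers import cmp_index, marker_table
from .modules import build_modules
from .scoring import ScoringConfig, ipanda_scores, prepare_pathways
from .simulate import (
    SimulationConfig,
    simulate_coexpression,
    simulate_pathway_db,
    simulate_platform_pair,
    simulate_response_dataset,
)


# ---------------------------------------------------------------------------
# Noise reduction (dual-platform)
# ---------------------------------------------------------------------------

@dataclass
class NoiseReductionResult:
    score_correlations: np.ndarray  # per case sample
    gene_correlations: np.ndarray
    n_pairs: int

    @property
    def mean_score_corr(self) -> float:
        return float(self.score_correlations.mean())

    @property
    def mean_gene_corr(self) -> float:
        return float(self.gene_correlations.mean())


def noise_reduction_experiment(
    seed: int = 0,
    n_pairs: int = 20,
    platform_noise_sd: float = 1.0,
    de_alpha: float = 0.05,
) -> NoiseReductionResult:
    """Sample-wise between-platform correlation of pathway scores vs fold
    changes of differentially expressed genes (t-test p < ``de_alpha`` on
    either platform).

    ``n_pairs`` counts case samples profiled on both platforms; each sample
    contributes one correlation of its two platform score vectors and one of
    its two platform fold-change vectors.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_cases=n_pairs,
        n_planted=3,
        platform_noise_sd=platform_noise_sd,
    )
    db = simulate_pathway_db(cfg)
    (cases_a, normals_a), (cases_b, normals_b), truth = simulate_platform_pair(
        cfg, db
    )
    coexpr = simulate_coexpression(cfg, truth["blocks"], cases_a.gene_ids)
    modules = build_modules(coexpr)
    scfg = ScoringConfig()
    prepared = prepare_pathways(db, modules, scfg)
    scores_a = ipanda_scores(cases_a, normals_a, db, modules, scfg, prepared=prepared)
    scores_b = ipanda_scores(cases_b, normals_b, db, modules, scfg, prepared=prepared)

    lfc_a = log_fold_changes(cases_a, normals_a)
    lfc_b = log_fold_changes(cases_b, normals_b)
    p_a = group_ttest(cases_a, normals_a).p_values
    p_b = group_ttest(cases_b, normals_b).p_values
    de = sorted(set(p_a.index[p_a < de_alpha]) | set(p_b.index[p_b < de_alpha]))

    score_corr, gene_corr = [], []
    for j in range(n_pairs):
        sa = scores_a.data.iloc[:, j].to_numpy()
        sb = scores_b.data.iloc[:, j].to_numpy()
        score_corr.append(np.corrcoef(sa, sb)[0, 1])
        ga = lfc_a.loc[de].iloc[:, j].to_numpy()
        gb = lfc_b.loc[de].iloc[:, j].to_numpy()
        gene_corr.append(np.corrcoef(ga, gb)[0, 1])
    return NoiseReductionResult(
        np.asarray(score_corr), np.asarray(gene_corr), n_pairs
    )


# ---------------------------------------------------------------------------
# CMP ablation (multi-dataset robustness)
# ---------------------------------------------------------------------------

#: study conditions of the CMP ablation design: a moderate uniform response
#: effect on five planted pathways; a co-regulated battery (coexpressed
#: block) in every pathway whose member genes carry private regulatory noise
#: while their shared driver is quiet within the cohort; and peripheral
#: "bystander" genes that are strongly case-vs-normal regulated but
#: phenotype-irrelevant and heterogeneous between tumours
CMP_STUDY_CONFIG = SimulationConfig(
    n_pathways=12,
    pathway_size_range=(15, 24),
    dag_layers=3,
    n_cases=60,
    n_normals=20,
    effect_size=1.5,
    n_planted=5,
    n_coexpr_blocks=12,
    block_size_range=(6, 9),
    block_driver_scale=0.3,
    block_gene_noise_sd=0.8,
    bystander_fraction=0.3,
    bystander_sd=3.0,
)


@dataclass
class CMPAblationResult:
    cmp_full: np.ndarray
    cmp_no_topology: np.ndarray
    cmp_no_modules: np.ndarray
    n_replicates: int

    @property
    def fraction_full_best(self) -> float:
        """Fraction of replicates where the full method's CMP is >= both
        ablations'."""
        ok = (self.cmp_full >= self.cmp_no_topology) & (
            self.cmp_full >= self.cmp_no_modules
        )
        return float(ok.mean())


def cmp_ablation_experiment(
    seed: int = 0,
    n_replicates: int = 50,
    n_datasets: int = 4,
    base_cfg: SimulationConfig = CMP_STUDY_CONFIG,
) -> CMPAblationResult:
    """CMP index with topology+modules on, vs either switched off.

    Each replicate simulates ``n_datasets`` independent response cohorts
    sharing the same planted pathways, scores them under the three method
    variants, and computes each variant's CMP over the datasets.
    """
    variants = {
        "full": ScoringConfig(),
        "no_topology": ScoringConfig(use_topology=False),
        "no_modules": ScoringConfig(use_modules=False),
    }
    results = {k: [] for k in variants}
    for rep in range(n_replicates):
        cfg = replace(base_cfg, seed=seed * 100003 + rep)
        db = simulate_pathway_db(cfg)
        blocks = None
        datasets = []
        for d in range(n_datasets):
            cases, normals, phen, truth = simulate_response_dataset(
                cfg, db, dataset_id=f"DS{d}", salt=d
            )
            blocks = truth["blocks"]
            datasets.append((cases, normals, phen))
        coexpr = simulate_coexpression(cfg, blocks, datasets[0][0].gene_ids)
        modules = build_modules(coexpr)
        sizes = {p.pathway_id: p.size for p in db}
        for name, scfg in variants.items():
            prepared = prepare_pathways(db, modules, scfg)
            scores_by_ds, phenos = {}, {}
            for cases, normals, phen in datasets:
                scores_by_ds[cases.dataset_id] = ipanda_scores(
                    cases, normals, db, modules, scfg, prepared=prepared
                )
                phenos.update(phen)
            table = marker_table(scores_by_ds, phenos, sizes)
            results[name].append(cmp_index(table).cmp)
    return CMPAblationResult(
        np.asarray(results["full"]),
        np.asarray(results["no_topology"]),
        np.asarray(results["no_modules"]),
        n_replicates,
    )


# ---------------------------------------------------------------------------
# Planted-pathway recovery
# ---------------------------------------------------------------------------

def planted_recovery_experiment(
    seed: int = 0,
    n_runs: int = 100,
    n_datasets: int = 2,
    effect_size: float = 2.0,
    pathway_size: int = 10,
    n_pathways: int = 10,
) -> float:
    """Fraction of seeded runs in which the planted pathway tops the
    mean-AUC marker ranking (default: a 10-gene pathway at log2 effect 2)."""
    hits = 0
    for run in range(n_runs):
        cfg = SimulationConfig(
            seed=seed * 100003 + run,
            n_pathways=n_pathways,
            pathway_size_range=(pathway_size, pathway_size),
            n_cases=16,
            n_normals=8,
            n_genes=200,
            effect_size=effect_size,
            n_planted=1,
            n_coexpr_blocks=4,
        )
        db = simulate_pathway_db(cfg)
        planted = [p.pathway_id for p in db][0]
        sizes = {p.pathway_id: p.size for p in db}
        scfg = ScoringConfig()
        prepared = prepare_pathways(db, None, scfg)
        scores_by_ds, phenos = {}, {}
        for d in range(n_datasets):
            cases, normals, phen, _ = simulate_response_dataset(
                cfg, db, dataset_id=f"DS{d}", salt=d
            )
            scores_by_ds[cases.dataset_id] = ipanda_scores(
                cases, normals, db, None, scfg, prepared=prepared
            )
            phenos.update(phen)
        table = marker_table(scores_by_ds, phenos, sizes)
        if table.ranking.index[0] == planted:
            hits += 1
    return hits / n_runs
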