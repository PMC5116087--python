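"""Signed pathway activation scores, Z-normalization and significance.

For one sample, the activation of pathway p is a linear combination of gene
and module contributions:

    iPANDA_p = [ sum_i G_ip + sum_j M_jp ] / N_p^eff        (normalized form)

    G_ip = A_ip * w_i^S * w_ip^T * log2 fc_i
    M_jp = A_jp * w_jp^S * w_jp^T * mean_{g in j} ( log2 fc_g )

A is the +/-1 activation sign of the unit, w^S the statistical weight,
w^T the topological weight, fc the fold change against the normal reference.
A module is one collective variable: its statistical weight w_jp^S comes
from a t-test on the members' averaged log2 profile, where correlated noise
partially cancels, so a coherent module keeps a high, stable weight even
when its individual members' p-values straddle the significance ramp.  (The
alternative, averaging the members' individually weighted fold changes,
stays available as ``module_weight='member'``.)
Positive values mean activation, negative inhibition.  N_p^eff is the number
of pathway member genes contributing to the sum (present in the data); the
division (on by default, configurable) makes scores comparable between small
and large pathways and leaves the score invariant to whether a coexpressed
group enters as separate parallel genes or one collapsed module.

Pathway-level significance uses the weighted Fisher combined probability
test: X = -2 sum_i w_i ln p_i with weights w_i = w_i^S * w_ip^T, referred to
a Gamma(shape = sum w_i, scale = 2) null — exactly Fisher's chi^2_{2N} when
all weights are 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .differential import (
    StatWeightConfig,
    _prepare_groups,
    group_ttest,
    log_fold_changes,
    statistical_weight,
    weight_table,
)
from .io import ExpressionMatrix, SampleAnnotation
from .modules import EMPTY_MODULES, ModuleSet
from .topology import (
    PathwayDatabase,
    PathwayGraph,
    collapse_modules,
    count_walks,
    topological_weights,
)

logger = logging.getLogger("ipanda")


@dataclass
class ScoringConfig:
    """Knobs for the scoring stage.

    size_normalize divides each pathway's sum by the number of contributing
    member genes; module_agg picks how a module pools its members' weighted
    fold changes; use_topology / use_modules are the ablation switches (an
    'off' topology means every unit weight is 1, 'off' modules treats every
    gene individually).
    """

    stat_weights: StatWeightConfig = field(default_factory=StatWeightConfig)
    size_normalize: bool = True
    module_agg: str = "mean"  # "mean" | "sum"
    module_weight: str = "collective"  # "collective" | "member"
    use_topology: bool = True
    use_modules: bool = True
    max_walks: int = 10**6

    def __post_init__(self) -> None:
        if self.module_agg not in ("mean", "sum"):
            raise ValueError("module_agg must be 'mean' or 'sum'")
        if self.module_weight not in ("collective", "member"):
            raise ValueError("module_weight must be 'collective' or 'member'")


@dataclass
class ScoreMatrix:
    """Signed pathway x sample activation values."""

    data: pd.DataFrame
    normalized: bool = False
    dataset_ids: dict[str, str] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def unit_contribution(
    kind: str,
    sign: int,
    w_T: float,
    log_fc: np.ndarray,
    w_S: np.ndarray,
    agg: str = "mean",
) -> np.ndarray:
    """Contribution of one unit, per sample.

    ``log_fc`` has shape (n_member_genes, n_samples); gene units have one row.
    A gene whose statistical weight is 0 contributes exactly 0.
    """
    log_fc = np.atleast_2d(np.asarray(log_fc, dtype=float))
    w_S = np.asarray(w_S, dtype=float).reshape(-1, 1)
    weighted = w_S * log_fc
    if kind == "gene" and weighted.shape[0] == 1:
        pooled = weighted[0]
    elif agg == "mean":
        pooled = weighted.mean(axis=0)
    else:
        pooled = weighted.sum(axis=0)
    return sign * w_T * pooled


@dataclass
class _PreparedPathway:
    graph: PathwayGraph
    weights: dict[str, float]


def prepare_pathways(
    db: PathwayDatabase, modules: ModuleSet, cfg: ScoringConfig
) -> dict[str, _PreparedPathway]:
    """Collapse modules into each pathway and precompute topological weights.

    Depends only on the database and the module set, so the result can be
    computed once and reused across datasets.
    """
    modules = modules if cfg.use_modules else EMPTY_MODULES
    out: dict[str, _PreparedPathway] = {}
    for pw in db:
        collapsed = collapse_modules(pw, modules)
        if cfg.use_topology:
            wt = topological_weights(count_walks(collapsed, cfg.max_walks)).weights
        else:
            wt = {u: 1.0 for u in collapsed.units}
        out[pw.pathway_id] = _PreparedPathway(collapsed, wt)
    return out


def ipanda_scores(
    cases: ExpressionMatrix,
    normals: ExpressionMatrix,
    db: PathwayDatabase,
    modules: ModuleSet | None = None,
    cfg: ScoringConfig | None = None,
    *,
    prepared: dict[str, _PreparedPathway] | None = None,
    return_significance: bool = False,
):
    """Score every pathway for every case sample of one dataset.

    Statistical weights come from this dataset's own case/normal t-tests;
    fold changes are per case sample against the normal reference.  Genes in
    a pathway but absent from the data contribute 0 (a fully absent pathway
    scores 0 with a warning).  Returns a :class:`ScoreMatrix`, plus a
    per-pathway combined p-value Series when ``return_significance`` is set.
    """
    cfg = cfg or ScoringConfig()
    modules = modules or EMPTY_MODULES
    diff = group_ttest(cases, normals)
    wtab = weight_table(diff, cfg.stat_weights)
    lfc = log_fold_changes(cases, normals)
    if prepared is None:
        prepared = prepare_pathways(db, modules, cfg)

    sample_ids = list(lfc.columns)
    gene_index = {g: i for i, g in enumerate(lfc.index)}
    lfc_arr = lfc.to_numpy()
    w_arr = wtab.weights.reindex(lfc.index).to_numpy()
    p_arr = wtab.p_values.reindex(lfc.index).to_numpy()
    ca_log, no_log = _prepare_groups(cases, normals)[:2]
    ca_arr = ca_log.reindex(lfc.index).to_numpy()
    no_arr = no_log.reindex(lfc.index).to_numpy()

    rows = []
    sig = {}
    for pw in db:
        prep = prepared[pw.pathway_id]
        total = np.zeros(len(sample_ids))
        contributing_genes = 0
        unit_ps, unit_ws = [], []
        for uid, unit in prep.graph.units.items():
            idx = [gene_index[g] for g in unit.genes if g in gene_index]
            if not idx:
                continue
            contributing_genes += len(idx)
            w_T = prep.weights[uid]
            if len(idx) > 1 and cfg.module_weight == "collective":
                p_unit = _collective_p(
                    ca_arr[idx], no_arr[idx], cfg.stat_weights
                )
                w_S_unit = statistical_weight(p_unit, cfg.stat_weights)
                pooled = lfc_arr[idx].mean(axis=0)
                if cfg.module_agg == "sum":
                    pooled = lfc_arr[idx].sum(axis=0)
                total += unit.sign * w_T * w_S_unit * pooled
            else:
                total += unit_contribution(
                    unit.kind if len(idx) == 1 else "module",
                    unit.sign,
                    w_T,
                    lfc_arr[idx],
                    w_arr[idx],
                    cfg.module_agg,
                )
                w_S_unit = float(np.mean(w_arr[idx]))
                p_unit = _combine_member_p(p_arr[idx])
            unit_ws.append(w_S_unit * w_T)
            unit_ps.append(p_unit)
        if contributing_genes == 0:
            logger.warning(
                "pathway %s has no genes in the expression data; score 0",
                pw.pathway_id,
            )
        elif cfg.size_normalize:
            total = total / contributing_genes
        rows.append(pd.Series(total, index=sample_ids, name=pw.pathway_id))
        if return_significance:
            sig[pw.pathway_id] = weighted_fisher(unit_ps, unit_ws)

    scores = ScoreMatrix(
        pd.DataFrame(rows),
        dataset_ids={s: cases.dataset_id for s in sample_ids},
    )
    if return_significance:
        return scores, pd.Series(sig, name="p_value")
    return scores


def _collective_p(
    ca: np.ndarray, no: np.ndarray, cfg: StatWeightConfig
) -> float:
    """Welch t-test p-value of a module's collective variable: the members'
    averaged log2 profile in cases vs normals."""
    a, b = ca.mean(axis=0), no.mean(axis=0)
    if a.var() == 0 and b.var() == 0:
        return cfg.p_min if a.mean() != b.mean() else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sp_stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(np.clip(p, 1e-300, 1.0))


def _combine_member_p(p: np.ndarray) -> float:
    """One p-value per unit: the gene's own p, or the members' unweighted
    Fisher combination for multi-gene units."""
    if len(p) == 1:
        return float(p[0])
    x = -2.0 * np.sum(np.log(p))
    return float(sp_stats.chi2.sf(x, df=2 * len(p)))


def weighted_fisher(p_values, weights) -> float:
    """Weighted Fisher combined probability over the units of a pathway.

    Units with zero weight (w^S = 0) are excluded before combination; if all
    weights vanish the test is uninformative and returns 1 with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    keep = w > 0
    if not keep.any():
        logger.warning("all unit weights are zero; combined p set to 1")
        return 1.0
    p, w = p[keep], w[keep]
    x = -2.0 * float(np.sum(w * np.log(p)))
    return float(sp_stats.gamma.sf(x, a=float(np.sum(w)), scale=2.0))


def zscore_normalize(
    scores: ScoreMatrix, annotations: list[SampleAnnotation]
) -> ScoreMatrix:
    """Z-score pathway activation values independently within each dataset.

    The centering expectation is balanced across phenotype groups when
    responder / non-responder labels exist (mean of per-phenotype means), so
    datasets with different responder fractions stay comparable; otherwise
    the plain dataset mean is used.  Scale is the within-dataset population
    standard deviation; constant rows map to 0.
    """
    ann = {a.sample_id: a for a in annotations}
    missing = [s for s in scores.sample_ids if s not in ann]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    by_dataset: dict[str, list[str]] = {}
    for s in scores.sample_ids:
        by_dataset.setdefault(ann[s].dataset_id, []).append(s)
    out = scores.data.copy().astype(float)
    for dataset, samples in by_dataset.items():
        if len(samples) < 2:
            raise ValueError(f"dataset {dataset!r} has a single sample")
        block = scores.data[samples]
        labels = pd.Series(
            {s: ann[s].phenotype for s in samples}, index=samples
        )
        labeled = labels[labels.isin(["responder", "non-responder"])]
        if labeled.nunique() >= 2:
            group_means = [
                block[labeled.index[labeled == ph]].mean(axis=1)
                for ph in sorted(labeled.unique())
            ]
            center = sum(group_means) / len(group_means)
        else:
            center = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        z = block.sub(center, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        out[samples] = z.fillna(0.0)
    return ScoreMatrix(out, normalized=True, dataset_ids=dict(scores.dataset_ids))
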