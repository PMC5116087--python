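"""Per-dataset group statistics: t-tests, log fold changes, statistical weights.

Each dataset is processed independently: a two-sided Welch t-test of case vs
normal samples per gene, per-sample log2 fold changes against the mean log2
of the normal group (a geometric-mean reference, since intensities are taken
to be log-normally distributed), and the smooth cosine-on-log-scale weight

    w^S(p) = 1                                      p <= p_min
           = 0.5 (1 + cos(pi (ln p - ln p_min)
                           / (ln p_max - ln p_min)))  p_min < p < p_max
           = 0                                      p >= p_max

with defaults p_min = 1e-7, p_max = 1e-1.  The smooth ramp replaces a sharp
significance cutoff, so pathway scores do not jump when a gene's p-value
crosses an arbitrary threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("ipanda")

#: floor applied to p-values so logs stay finite
_P_FLOOR = 1e-300


@dataclass
class StatWeightConfig:
    p_min: float = 1e-7
    p_max: float = 1e-1

    def __post_init__(self) -> None:
        if not (0 < self.p_min < self.p_max <= 1):
            raise ValueError("need 0 < p_min < p_max <= 1")


@dataclass
class DifferentialStats:
    """Welch t statistics and p-values per gene, for one dataset."""

    table: pd.DataFrame  # index gene, columns: t_statistic, p_value
    dataset_id: str = ""
    excluded_genes: tuple[str, ...] = ()

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]


@dataclass
class WeightTable:
    """Per-gene statistical weights w^S in [0, 1] for one dataset."""

    weights: pd.Series  # index gene
    p_values: pd.Series
    dataset_id: str = ""

    def get(self, gene: str, default: float = 0.0) -> float:
        return float(self.weights.get(gene, default))


def _prepare_groups(
    cases: ExpressionMatrix, normals: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    if cases.n_samples < 2 or normals.n_samples < 2:
        raise ValueError("each group needs at least 2 samples")
    ca = cases.to_log2().data
    no = normals.to_log2().data
    shared = ca.index.intersection(no.index)
    dropped = sorted(set(ca.index).symmetric_difference(no.index))
    ca, no = ca.loc[shared], no.loc[shared]
    # genes with any missing value in a group leave that comparison entirely
    complete = ~(ca.isna().any(axis=1) | no.isna().any(axis=1))
    dropped += sorted(shared[~complete])
    if dropped:
        logger.info("excluded %d genes absent or incomplete in a group", len(dropped))
    return ca.loc[complete], no.loc[complete], dropped


def group_ttest(
    cases: ExpressionMatrix, normals: ExpressionMatrix
) -> DifferentialStats:
    """Two-sided Welch t-test per gene shared by both groups.

    Genes with zero variance in both groups get p = p_min default (1e-7) when
    the means differ — an unambiguous change should keep full weight — and
    p = 1 when they are identical.
    """
    ca, no, dropped = _prepare_groups(cases, normals)
    a, b = ca.to_numpy(), no.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    both_flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    means_differ = mean_diff != 0
    cfg = StatWeightConfig()
    t_flat = np.where(mean_diff > 0, np.inf, -np.inf)
    p = np.where(both_flat & means_differ, cfg.p_min, p)
    t = np.where(both_flat & means_differ, t_flat, t)
    p = np.where(both_flat & ~means_differ, 1.0, p)
    t = np.where(both_flat & ~means_differ, 0.0, t)
    p = np.clip(p, _P_FLOOR, 1.0)
    table = pd.DataFrame({"t_statistic": t, "p_value": p}, index=ca.index)
    return DifferentialStats(table, cases.dataset_id, tuple(dropped))


def log_fold_changes(
    cases: ExpressionMatrix, normals: ExpressionMatrix
) -> pd.DataFrame:
    """Per-sample log2 fold change of each case sample against the normal
    reference (mean of the normals' log2 values, i.e. their geometric mean)."""
    ca, no, _ = _prepare_groups(cases, normals)
    reference = no.mean(axis=1)
    return ca.sub(reference, axis=0)


def statistical_weight(p, cfg: StatWeightConfig | None = None):
    """Smooth cosine-on-log-scale weight of a t-test p-value (vectorized).

    Exactly 1 at p <= p_min, exactly 0 at p >= p_max, continuous and
    monotone non-increasing in between.  p must lie in (0, 1].
    """
    cfg = cfg or StatWeightConfig()
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    lo, hi = np.log(cfg.p_min), np.log(cfg.p_max)
    with np.errstate(divide="ignore"):
        frac = (np.log(arr) - lo) / (hi - lo)
    w = 0.5 * (1.0 + np.cos(np.pi * np.clip(frac, 0.0, 1.0)))
    w = np.where(arr <= cfg.p_min, 1.0, w)
    w = np.where(arr >= cfg.p_max, 0.0, w)
    return float(w) if np.isscalar(p) else w


def weight_table(
    differential: DifferentialStats, cfg: StatWeightConfig | None = None
) -> WeightTable:
    """Map a dataset's t-test p-values through the smooth threshold."""
    p = differential.p_values
    w = pd.Series(
        statistical_weight(p.to_numpy(), cfg), index=p.index, name="w_S"
    )
    return WeightTable(w, p, differential.dataset_id)
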