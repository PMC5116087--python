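"""Pathway marker ranking by AUC and the CMP cross-dataset robustness index.

A pathway is a phenotype marker in a dataset when its activation score
separates responders from non-responders with AUC above a threshold (0.75
for the robustness index).  Because an inhibited pathway separates groups
just as well as an activated one, the symmetric AUC max(AUC, 1 - AUC) is
used for the marker rule, with the raw responder-oriented AUC reported
alongside.

The common-marker-pathway (CMP) index summarizes robustness over n datasets:

    CMP = sum_{i in common markers} ln(N_i) * (1/n) sum_j (AUC_ij - AUC_R)

where common markers exceed the AUC threshold in *every* dataset, N_i is the
pathway's gene count (larger pathways are less likely to reach a high AUC by
chance, hence the ln(N_i) boost) and AUC_R = 0.5 is the random-classifier
reference.  CMP is 0 exactly when no pathway is a marker in all datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import ScoreMatrix

AUC_THRESHOLD = 0.75
AUC_RANDOM = 0.5


@dataclass
class AUCTable:
    """Per-pathway, per-dataset AUCs plus pathway sizes and the mean ranking."""

    auc: pd.DataFrame  # pathway x dataset, responder-oriented
    auc_symmetric: pd.DataFrame  # max(AUC, 1 - AUC)
    pathway_sizes: dict[str, int]
    ranking: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def datasets(self) -> list[str]:
        return list(self.auc.columns)


@dataclass
class CMPResult:
    cmp: float
    common_markers: list[str]
    auc_threshold: float = AUC_THRESHOLD
    auc_random: float = AUC_RANDOM


def pathway_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC of scores for the positive class.

    Ties get 0.5 credit.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def marker_table(
    scores_by_dataset: dict[str, ScoreMatrix],
    phenotypes: dict[str, str],
    pathway_sizes: dict[str, int],
    *,
    positive: str = "responder",
    top: int = 30,
) -> AUCTable:
    """AUC of every pathway in every dataset, ranked by mean symmetric AUC.

    ``phenotypes`` maps sample id to class label; samples labelled neither
    ``positive`` nor anything else binary are simply contrasted as positive
    vs rest.  Mean-AUC ties break toward the larger pathway, then the
    lexicographically smaller id, so the ranking is deterministic.
    """
    auc_cols, sym_cols = {}, {}
    for dataset, scores in sorted(scores_by_dataset.items()):
        labeled = [s for s in scores.sample_ids if s in phenotypes]
        y = np.array([phenotypes[s] == positive for s in labeled])
        if y.all() or not y.any():
            raise ValueError(f"dataset {dataset!r} lacks one phenotype class")
        block = scores.data[labeled]
        col = {}
        for pid in scores.pathway_ids:
            col[pid] = pathway_auc(block.loc[pid].to_numpy(), y)
        auc_cols[dataset] = pd.Series(col)
        sym_cols[dataset] = auc_cols[dataset].combine(
            1 - auc_cols[dataset], max
        )
    auc = pd.DataFrame(auc_cols)
    sym = pd.DataFrame(sym_cols)
    mean_sym = sym.mean(axis=1)
    order = sorted(
        mean_sym.index,
        key=lambda pid: (-mean_sym[pid], -pathway_sizes.get(pid, 0), pid),
    )
    ranking = pd.DataFrame(
        {
            "mean_auc": mean_sym.loc[order],
            "mean_auc_raw": auc.mean(axis=1).loc[order],
            "n_genes": [pathway_sizes.get(pid, 0) for pid in order],
        }
    ).head(top)
    ranking.index.name = "pathway"
    return AUCTable(auc, sym, dict(pathway_sizes), ranking)


def cmp_index(
    auc_table: AUCTable,
    threshold: float = AUC_THRESHOLD,
    auc_random: float = AUC_RANDOM,
    *,
    symmetric: bool = True,
) -> CMPResult:
    """Common-marker-pathway index over the datasets of an AUC table.

    A pathway joins the common-marker set only when its AUC exceeds
    ``threshold`` in every dataset (strict).  Each common marker contributes
    ln(N_i) times its mean AUC excess over the random classifier.
    """
    table = auc_table.auc_symmetric if symmetric else auc_table.auc
    if table.shape[1] < 2:
        raise ValueError("CMP needs at least 2 datasets")
    common = [
        pid for pid in table.index if bool((table.loc[pid] > threshold).all())
    ]
    total = 0.0
    for pid in common:
        n_genes = auc_table.pathway_sizes.get(pid, 0)
        if n_genes < 1:
            continue
        excess = float((table.loc[pid] - auc_random).mean())
        total += np.log(n_genes) * excess
    return CMPResult(total, sorted(common), threshold, auc_random)
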