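"""Gene-module construction from coexpression data and TF target lists.

Coexpressed genes move together and carry redundant evidence; grouping them
into modules lets the scoring stage treat each group as a single unit, so a
correlated block contributes once rather than once per member.  The pipeline
is: correlation -> distance d_ij = sqrt(2 (1 - corr_ij)) -> DBSCAN and
average-linkage hierarchical clustering (pooled) -> keep clusters whose mean
internal pairwise correlation exceeds 0.3 -> recursively merge overlapping
clusters (intersection level > 0.7) -> enforce a disjoint assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN

logger = logging.getLogger("ipanda")

MIN_INTERNAL_CORR = 0.3
MIN_OVERLAP = 0.7


@dataclass
class CoexpressionMatrix:
    """Symmetric gene-gene correlation matrix with unit diagonal."""

    gene_ids: list[str]
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.gene_ids)
        if self.corr.shape != (n, n):
            raise ValueError("correlation matrix shape does not match gene list")
        if np.abs(self.corr - self.corr.T).max(initial=0.0) > 1e-12:
            raise ValueError("correlation matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be exactly 1")
        if np.nanmin(self.corr) < -1 - 1e-12 or np.nanmax(self.corr) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    def index_of(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes], dtype=int)

    def mean_internal_corr(self, genes) -> float:
        """Mean correlation over all unordered internal pairs."""
        idx = self.index_of(genes)
        if len(idx) < 2:
            return float("nan")
        sub = self.corr[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())


@dataclass
class GeneModule:
    module_id: str
    genes: set[str]
    mean_internal_corr: float = float("nan")
    source: str = "coexpression"  # "coexpression" | "tf_targets" | "merged"

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"module {self.module_id!r} needs >= 2 genes")


@dataclass
class ModuleSet:
    """Disjoint gene modules plus the induced gene -> module assignment."""

    modules: list[GeneModule] = field(default_factory=list)
    assignment: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_modules(cls, modules: list[GeneModule]) -> "ModuleSet":
        assignment: dict[str, str] = {}
        for mod in modules:
            for g in mod.genes:
                if g in assignment:
                    raise ValueError(
                        f"gene {g!r} assigned to both {assignment[g]!r} "
                        f"and {mod.module_id!r}"
                    )
                assignment[g] = mod.module_id
        return cls(list(modules), assignment)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, module_id: str) -> GeneModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


EMPTY_MODULES = ModuleSet()


# ---------------------------------------------------------------------------
# Distance and clustering
# ---------------------------------------------------------------------------

def coexpression_distance(coexpr: CoexpressionMatrix) -> np.ndarray:
    """Distance between standardized expression profiles.

    d_ij = sqrt(2 (1 - corr_ij)): 0 at perfect coexpression, sqrt(2) at
    independence, 2 at perfect anticorrelation.
    """
    d2 = 2.0 * (1.0 - coexpr.corr)
    np.clip(d2, 0.0, None, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


def detect_clusters(
    dist: np.ndarray,
    gene_ids: list[str],
    method: str = "both",
    *,
    eps: float = 1.0,
    min_samples: int = 3,
    cut_distance: float = 1.0,
) -> list[frozenset[str]]:
    """Find candidate coexpression clusters on a precomputed distance matrix.

    ``method`` is ``dbscan``, ``hierarchical_average`` or ``both`` (outputs
    pooled).  Only clusters of size >= 2 are returned.
    """
    n = len(gene_ids)
    if n < 2:
        return []
    genes = np.asarray(gene_ids, dtype=object)
    clusters: list[frozenset[str]] = []
    if method in ("dbscan", "both"):
        labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(
            dist
        ).labels_
        for lab in np.unique(labels):
            if lab == -1:
                continue
            members = genes[labels == lab]
            if len(members) >= 2:
                clusters.append(frozenset(members))
    if method in ("hierarchical_average", "both"):
        condensed = squareform(dist, checks=False)
        tree = linkage(condensed, method="average")
        labels = fcluster(tree, t=cut_distance, criterion="distance")
        for lab in np.unique(labels):
            members = genes[labels == lab]
            if len(members) >= 2:
                clusters.append(frozenset(members))
    # drop exact duplicates while preserving order
    seen: set[frozenset[str]] = set()
    out = []
    for c in clusters:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def filter_clusters(
    clusters,
    coexpr: CoexpressionMatrix,
    min_corr: float = MIN_INTERNAL_CORR,
) -> list[GeneModule]:
    """Keep clusters whose mean internal pairwise correlation strictly exceeds
    ``min_corr``."""
    out = []
    for i, cluster in enumerate(clusters):
        mc = coexpr.mean_internal_corr(cluster)
        if mc > min_corr:
            out.append(
                GeneModule(f"M{i:04d}", set(cluster), mc, source="coexpression")
            )
    return out


# ---------------------------------------------------------------------------
# Merging and disjointness
# ---------------------------------------------------------------------------

def _overlap(a: set[str], b: set[str], metric: str) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "min":
        return inter / min(len(a), len(b))
    raise ValueError(f"unknown overlap metric {metric!r}")


def merge_cluster_sets(
    set_a,
    set_b,
    min_overlap: float = MIN_OVERLAP,
    *,
    overlap_metric: str = "jaccard",
    coexpr: CoexpressionMatrix | None = None,
) -> ModuleSet:
    """Pool two cluster collections and merge overlapping pairs to a fixpoint.

    Any pair whose intersection level (Jaccard by default, ``min`` for
    intersection over the smaller set) strictly exceeds ``min_overlap`` is
    unioned; merging repeats until no pair qualifies.  The result is made
    disjoint: a gene left in several modules goes to the module with the
    higher mean internal correlation (ties: larger module, then lexicographic
    module id).
    """

    def as_module(obj, i: int, origin: str) -> GeneModule:
        if isinstance(obj, GeneModule):
            return obj
        return GeneModule(f"{origin}{i:04d}", set(obj), float("nan"), origin)

    pool = [as_module(c, i, "A") for i, c in enumerate(set_a)]
    pool += [as_module(c, i, "B") for i, c in enumerate(set_b)]

    merged = True
    while merged:
        merged = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if _overlap(pool[i].genes, pool[j].genes, overlap_metric) > min_overlap:
                    union = pool[i].genes | pool[j].genes
                    mc = (
                        coexpr.mean_internal_corr(sorted(union))
                        if coexpr is not None and set(union) <= set(coexpr.gene_ids)
                        else float("nan")
                    )
                    keep_id = min(pool[i].module_id, pool[j].module_id)
                    pool[i] = GeneModule(keep_id, union, mc, source="merged")
                    del pool[j]
                    merged = True
                    break
            if merged:
                break
    return _make_disjoint(pool)


def _module_priority(mod: GeneModule) -> tuple:
    mc = mod.mean_internal_corr
    mc = -math.inf if math.isnan(mc) else mc
    return (-mc, -len(mod.genes), mod.module_id)


def _make_disjoint(modules: list[GeneModule]) -> ModuleSet:
    ordered = sorted(modules, key=_module_priority)
    taken: set[str] = set()
    final: list[GeneModule] = []
    for mod in ordered:
        genes = mod.genes - taken
        if len(genes) < 2:
            if genes:
                logger.info(
                    "module %s reduced below 2 genes by disjointness; dropped",
                    mod.module_id,
                )
            continue
        taken |= genes
        final.append(GeneModule(mod.module_id, genes, mod.mean_internal_corr, mod.source))
    final.sort(key=lambda m: m.module_id)
    return ModuleSet.from_modules(final)


# ---------------------------------------------------------------------------
# End-to-end module building
# ---------------------------------------------------------------------------

def build_modules(
    coexpr: CoexpressionMatrix,
    tf_target_sets: dict[str, set[str]] | None = None,
    *,
    pathway_genes: set[str] | None = None,
    min_corr: float = MIN_INTERNAL_CORR,
    min_overlap: float = MIN_OVERLAP,
    overlap_metric: str = "jaccard",
    eps: float = 1.0,
    min_samples: int = 3,
    cut_distance: float = 1.0,
) -> ModuleSet:
    """Full module pipeline: cluster, filter, merge with TF target sets.

    TF target lists enter as ready-made gene sets, intersected with the
    pathway-covered gene universe when one is given.
    """
    dist = coexpression_distance(coexpr)
    clusters = detect_clusters(
        dist,
        coexpr.gene_ids,
        method="both",
        eps=eps,
        min_samples=min_samples,
        cut_distance=cut_distance,
    )
    coexpr_modules = filter_clusters(clusters, coexpr, min_corr=min_corr)
    tf_sets: list[GeneModule] = []
    for i, (tf, targets) in enumerate(sorted((tf_target_sets or {}).items())):
        genes = set(targets)
        if pathway_genes is not None:
            genes &= pathway_genes
        if len(genes) >= 2:
            tf_sets.append(GeneModule(f"TF_{tf}", genes, float("nan"), "tf_targets"))
    return merge_cluster_sets(
        coexpr_modules,
        tf_sets,
        min_overlap=min_overlap,
        overlap_metric=overlap_metric,
        coexpr=coexpr,
    )
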