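"""Seeded generators for synthetic pathway databases and expression data.

These fixtures stand in for curated pathway maps, coexpression databases and
case/control microarray series.  They reproduce the structural features the
scoring method relies on — layered acyclic signed topologies, log-normally
distributed intensities, coexpressed gene blocks, planted pathway
perturbations, phenotype-linked response signal and paired platforms with
independent technical noise — while making no attempt at microarray physics
(probe effects, background models).

Everything is driven by a single integer seed through
:class:`numpy.random.Generator`; the same configuration always yields
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .topology import (
    ACTIVATION,
    INHIBITION,
    PathwayDatabase,
    PathwayGraph,
    PathwayUnit,
    count_walks,
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic test bed.

    Defaults describe a desk-scale case/control cohort: a few hundred genes,
    a dozen pathways of realistic shape, log2 intensities around 7 with unit
    biological spread, and a planted log2 effect of 2 (a four-fold change).
    """

    seed: int = 0
    n_genes: int = 400
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (8, 25)
    dag_layers: int = 4
    n_cases: int = 20
    n_normals: int = 10
    effect_size: float = 2.0  # log2 units added to planted pathway genes
    block_corr: float = 0.7  # rho_in of coexpressed blocks
    platform_noise_sd: float = 1.0
    planted_pathways: tuple[str, ...] = ()
    n_planted: int = 1
    inhibitor_fraction: float = 0.1
    bio_sd: float = 1.0  # per-gene biological sd, log2 scale
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_coexpr_blocks: int = 6
    block_size_range: tuple[int, int] = (3, 6)
    effect_profile: str = "uniform"  # "uniform" | "cascade"
    confound_sd: float = 0.0  # per-dataset spurious block-phenotype shift
    crosstalk_sd: float = 0.0  # off-pathway noise on walk-sparse genes
    block_gene_noise_sd: float = 0.0  # private inputs of block member genes
    block_driver_scale: float = 1.0  # cohort fluctuation of a block's driver
    bystander_fraction: float = 0.0  # share of peripheral genes per pathway
    bystander_shift: float = 2.0  # case-vs-normal shift of bystander genes
    bystander_sd: float = 2.0  # their per-case-sample heterogeneity
    allow_cycles: bool = False

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_pathways <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.block_corr < 1):
            raise ValueError("block_corr must lie in [0, 1)")
        if self.effect_profile not in ("uniform", "cascade"):
            raise ValueError("effect_profile must be 'uniform' or 'cascade'")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ---------------------------------------------------------------------------
# Pathway database
# ---------------------------------------------------------------------------

def simulate_pathway_db(cfg: SimulationConfig) -> PathwayDatabase:
    """Random layered signed DAGs, one gene per node, pathways gene-disjoint.

    Nodes are spread over ``dag_layers`` layers and edges only run forward
    (to the next layer, occasionally skipping one), so every pathway has at
    least one source and one sink and simple-walk counting terminates.
    Roughly ``inhibitor_fraction`` of nodes carry sign -1.  With
    ``allow_cycles`` a single backward edge is injected per pathway to
    exercise cyclic walk counting.
    """
    rng = cfg.rng(salt=1)
    lo, hi = cfg.pathway_size_range
    pathways = []
    gene_counter = 0
    for p in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        genes = [f"G{gene_counter + k:04d}" for k in range(size)]
        gene_counter += size
        n_layers = min(cfg.dag_layers, size)
        # every layer gets at least one node
        layer_of = list(range(n_layers)) + list(
            rng.integers(0, n_layers, size=size - n_layers)
        )
        layer_of.sort()
        layers: list[list[int]] = [[] for _ in range(n_layers)]
        for node, lay in enumerate(layer_of):
            layers[lay].append(node)
        signs = np.where(rng.random(size) < cfg.inhibitor_fraction, -1, +1)
        units = {
            g: PathwayUnit(g, (g,), int(signs[k])) for k, g in enumerate(genes)
        }
        edges: list[tuple[str, str, str]] = []
        for lay in range(1, n_layers):
            for node in layers[lay]:
                source_layer = lay - 1
                if lay >= 2 and rng.random() < 0.15:  # occasional skip edge
                    source_layer = lay - 2
                n_parents = int(rng.integers(1, min(2, len(layers[source_layer])) + 1))
                parents = rng.choice(layers[source_layer], size=n_parents, replace=False)
                for parent in parents:
                    etype = INHIBITION if rng.random() < 0.1 else ACTIVATION
                    edges.append((genes[parent], genes[node], etype))
        if cfg.allow_cycles and n_layers >= 2 and rng.random() < 0.8:
            src = genes[int(rng.choice(layers[n_layers - 1]))]
            dst = genes[int(rng.choice(layers[0]))]
            edges.append((src, dst, ACTIVATION))
        pathways.append(PathwayGraph(f"PW{p:03d}", units, edges))
    return PathwayDatabase(pathways, name="synthetic", version="1")


def _planted_ids(cfg: SimulationConfig, db: PathwayDatabase) -> list[str]:
    if cfg.planted_pathways:
        return list(cfg.planted_pathways)
    return [p.pathway_id for p in db][: cfg.n_planted]


def _effect_per_gene(cfg: SimulationConfig, pw: PathwayGraph) -> dict[str, float]:
    """Per-gene planted effect: flat delta, or graded along the signalling axis.

    The cascade profile scales the effect by each gene's share of start->end
    walks (floored at 0.25), modelling a perturbation that propagates along
    the pathway's main routes and touches peripheral genes more weakly.
    """
    sign = {g: u.sign for u in pw.units.values() for g in u.genes}
    if cfg.effect_profile == "uniform":
        return {g: cfg.effect_size * s for g, s in sign.items()}
    counts = count_walks(pw).counts
    max_n = max(counts.values()) or 1
    grade = {
        g: 0.25 + 0.75 * (counts[u.unit_id] / max_n)
        for u in pw.units.values()
        for g in u.genes
    }
    return {g: cfg.effect_size * sign[g] * grade[g] for g in sign}


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

def _gene_universe(cfg: SimulationConfig, db: PathwayDatabase) -> list[str]:
    genes = sorted(db.genes)
    background = [f"B{k:04d}" for k in range(max(0, cfg.n_genes - len(genes)))]
    return genes + background


def _coexpr_blocks(
    cfg: SimulationConfig, db: PathwayDatabase, rng: np.random.Generator
) -> list[list[str]]:
    """Coexpressed blocks: runs of genes inside pathways (co-regulated
    batteries), cycling through pathways so planted ones are covered first.

    Blocks are drawn from same-sign genes at the same graph depth: positively
    coexpressed genes respond in the same direction, and a co-regulated
    battery (e.g. one factor's targets) sits at one level of the cascade, in
    parallel graph positions, rather than spanning it.
    """
    blocks = []
    lo, hi = cfg.block_size_range
    pws = list(db)
    # bystander genes answer to other programs, hence are not coexpressed
    # with any battery and never join a block
    excluded = set(_bystanders(cfg, db))
    for b in range(cfg.n_coexpr_blocks):
        pw = pws[b % len(pws)]
        nxg = pw.to_networkx()
        if nx.is_directed_acyclic_graph(nxg):
            depth = {n: 0 for n in nxg}
            for n in nx.topological_sort(nxg):
                for succ in nxg.successors(n):
                    depth[succ] = max(depth[succ], depth[n] + 1)
        else:
            depth = {n: 0 for n in nxg}
        levels: dict[tuple[int, int], list[str]] = {}
        for u in pw.units.values():
            if u.sign > 0:
                genes_ok = [g for g in u.genes if g not in excluded]
                levels.setdefault((depth[u.unit_id], u.sign), []).extend(genes_ok)
        candidates = [sorted(v) for v in levels.values() if len(v) >= 2]
        if not candidates:
            continue
        # the largest co-level group: the pathway's main co-regulated battery
        genes = max(candidates, key=len)
        size = min(int(rng.integers(lo, hi + 1)), len(genes))
        if size < 2:
            continue
        start = int(rng.integers(0, len(genes) - size + 1))
        blocks.append(genes[start : start + size])
    # a gene belongs to at most one block
    seen: set[str] = set()
    out = []
    for blk in blocks:
        blk = [g for g in blk if g not in seen]
        if len(blk) >= 2:
            seen.update(blk)
            out.append(blk)
    return out


def _walk_shares(db: PathwayDatabase) -> dict[str, float]:
    """Per gene: its pathway's N_ip / max N_jp (walk share), 1 elsewhere."""
    shares: dict[str, float] = {}
    for pw in db:
        counts = count_walks(pw).counts
        max_n = max(counts.values()) or 1
        for u in pw.units.values():
            for g in u.genes:
                shares[g] = counts[u.unit_id] / max_n
    return shares


def _draw_matrix(
    cfg: SimulationConfig,
    genes: list[str],
    baseline: np.ndarray,
    blocks: list[list[str]],
    n_samples: int,
    rng: np.random.Generator,
    crosstalk: np.ndarray | None = None,
) -> np.ndarray:
    """Log2 intensities: baseline + block-correlated biological noise.

    ``crosstalk`` is a per-gene extra noise sd — variation driven by other
    processes a gene participates in, strongest for walk-sparse peripheral
    genes and absent for dedicated core-cascade genes.
    """
    gene_pos = {g: i for i, g in enumerate(genes)}
    rho = cfg.block_corr
    eps = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    values = baseline[:, None] + cfg.bio_sd * eps
    for blk in blocks:
        idx = [gene_pos[g] for g in blk]
        z = rng.normal(0.0, 1.0, size=n_samples)
        # block_driver_scale < 1 models a shared driver that is quieter in
        # this cohort than across the broad compendia coexpression databases
        # aggregate, where the nominal block correlation is measured
        values[idx, :] = (
            baseline[idx, None]
            + cfg.bio_sd * (
                cfg.block_driver_scale * np.sqrt(rho) * z[None, :]
                + np.sqrt(1 - rho) * eps[idx, :]
            )
        )
        if cfg.block_gene_noise_sd > 0:
            # each battery member also answers to private regulatory inputs;
            # the shared driver survives averaging, the private parts do not
            values[idx, :] += rng.normal(
                0.0, cfg.block_gene_noise_sd, size=(len(idx), n_samples)
            )
    if crosstalk is not None and np.any(crosstalk > 0):
        values += crosstalk[:, None] * rng.normal(
            0.0, 1.0, size=(len(genes), n_samples)
        )
    return values


def _bystanders(
    cfg: SimulationConfig, db: PathwayDatabase
) -> dict[str, float]:
    """Disease-related but phenotype-irrelevant genes at pathway peripheries.

    Pathway maps include genes shared with broad disease processes
    (proliferation, immune infiltration): strongly case-vs-normal regulated,
    heterogeneous between tumours, yet uninformative about the phenotype
    under study.  They occupy walk-sparse positions, so topological
    weighting — unlike the statistical weight, which sees a highly
    significant change — can discount them.  Returns gene -> signed shift;
    the choice is derived from the seed only, so it is identical across the
    datasets of one study.
    """
    if cfg.bystander_fraction <= 0:
        return {}
    rng = cfg.rng(salt=5)
    shares = _walk_shares(db)
    out: dict[str, float] = {}
    for pw in db:
        genes = sorted(pw.genes, key=lambda g: (shares[g], g))
        n_pick = int(round(cfg.bystander_fraction * len(genes)))
        for g in genes[:n_pick]:
            out[g] = cfg.bystander_shift * (1 if rng.random() < 0.5 else -1)
    return out


def _crosstalk_sds(
    cfg: SimulationConfig, db: PathwayDatabase, genes: list[str]
) -> np.ndarray | None:
    if cfg.crosstalk_sd <= 0:
        return None
    shares = _walk_shares(db)
    return np.array(
        [cfg.crosstalk_sd * (1.0 - shares.get(g, 1.0)) for g in genes]
    )


def simulate_expression(
    cfg: SimulationConfig, db: PathwayDatabase, *, dataset_id: str = "sim"
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Case and normal log2 expression with planted pathway perturbations.

    Case samples of planted pathways receive the configured log2 effect,
    sign-consistent with each node's activation sign.  The truth record
    lists planted pathways, coexpression blocks and the per-gene effects.
    """
    rng = cfg.rng(salt=2)
    genes = _gene_universe(cfg, db)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    blocks = _coexpr_blocks(cfg, db, rng)
    crosstalk = _crosstalk_sds(cfg, db, genes)
    normals = _draw_matrix(cfg, genes, baseline, blocks, cfg.n_normals, rng, crosstalk)
    cases = _draw_matrix(cfg, genes, baseline, blocks, cfg.n_cases, rng, crosstalk)

    planted = _planted_ids(cfg, db) if cfg.effect_size != 0 else []
    gene_pos = {g: i for i, g in enumerate(genes)}
    effects: dict[str, float] = {}
    for pid in planted:
        effects.update(_effect_per_gene(cfg, db[pid]))
    for g, eff in effects.items():
        cases[gene_pos[g], :] += eff

    sample_ids_c = [f"{dataset_id}_case{j:02d}" for j in range(cfg.n_cases)]
    sample_ids_n = [f"{dataset_id}_norm{j:02d}" for j in range(cfg.n_normals)]
    truth = {
        "planted_pathways": planted,
        "blocks": blocks,
        "effects": effects,
        "effect_size": cfg.effect_size,
    }
    return (
        ExpressionMatrix(
            pd.DataFrame(cases, index=genes, columns=sample_ids_c),
            scale="log2",
            dataset_id=dataset_id,
        ),
        ExpressionMatrix(
            pd.DataFrame(normals, index=genes, columns=sample_ids_n),
            scale="log2",
            dataset_id=dataset_id,
        ),
        truth,
    )


def simulate_response_dataset(
    cfg: SimulationConfig,
    db: PathwayDatabase,
    *,
    dataset_id: str = "sim",
    salt: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict[str, str], dict]:
    """One dataset with responder / non-responder case phenotypes.

    Planted pathway effects apply to responder cases only, so the planted
    pathways separate the two phenotype groups.  ``confound_sd`` adds a
    per-dataset, per-block random phenotype-associated shift shared by the
    genes of a coexpressed block — the spurious co-regulated programs that
    make single-dataset marker lists unstable.
    """
    rng = cfg.rng(salt=1000 + salt)
    genes = _gene_universe(cfg, db)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    blocks = _coexpr_blocks(cfg, db, rng)
    crosstalk = _crosstalk_sds(cfg, db, genes)
    normals = _draw_matrix(cfg, genes, baseline, blocks, cfg.n_normals, rng, crosstalk)
    cases = _draw_matrix(cfg, genes, baseline, blocks, cfg.n_cases, rng, crosstalk)
    gene_pos = {g: i for i, g in enumerate(genes)}

    n_resp = cfg.n_cases // 2
    responder = np.zeros(cfg.n_cases, dtype=bool)
    responder[:n_resp] = True

    planted = _planted_ids(cfg, db)
    effects: dict[str, float] = {}
    for pid in planted:
        effects.update(_effect_per_gene(cfg, db[pid]))
    for g, eff in effects.items():
        cases[gene_pos[g], responder] += eff

    for g, shift in _bystanders(cfg, db).items():
        cases[gene_pos[g], :] += shift + rng.normal(
            0.0, cfg.bystander_sd, size=cfg.n_cases
        )

    if cfg.confound_sd > 0:
        for blk in blocks:
            shift = rng.normal(0.0, cfg.confound_sd)
            idx = [gene_pos[g] for g in blk]
            cases[np.ix_(idx, np.where(responder)[0])] += shift

    sample_ids_c = [f"{dataset_id}_case{j:02d}" for j in range(cfg.n_cases)]
    sample_ids_n = [f"{dataset_id}_norm{j:02d}" for j in range(cfg.n_normals)]
    phenotypes = {
        s: ("responder" if responder[j] else "non-responder")
        for j, s in enumerate(sample_ids_c)
    }
    truth = {"planted_pathways": planted, "blocks": blocks, "effects": effects}
    return (
        ExpressionMatrix(
            pd.DataFrame(cases, index=genes, columns=sample_ids_c),
            scale="log2",
            dataset_id=dataset_id,
        ),
        ExpressionMatrix(
            pd.DataFrame(normals, index=genes, columns=sample_ids_n),
            scale="log2",
            dataset_id=dataset_id,
        ),
        phenotypes,
        truth,
    )


def simulate_platform_pair(
    cfg: SimulationConfig, db: PathwayDatabase
) -> tuple[
    tuple[ExpressionMatrix, ExpressionMatrix],
    tuple[ExpressionMatrix, ExpressionMatrix],
    dict,
]:
    """The same biological samples measured on two synthetic platforms.

    A shared biological matrix (with planted effects) is distorted per
    platform by fixed gene-wise offsets (probe affinity analogue, sd half the
    noise level) plus independent Gaussian noise of sd ``platform_noise_sd``.
    With zero noise the two platforms are identical.
    """
    cases, normals, truth = simulate_expression(cfg, db, dataset_id="shared")
    rng = cfg.rng(salt=3)
    out = []
    for platform in ("plA", "plB"):
        offsets = rng.normal(
            0.0, 0.5 * cfg.platform_noise_sd, size=len(cases.gene_ids)
        )
        pair = []
        for base, n_samples, tag in (
            (cases, cfg.n_cases, "case"),
            (normals, cfg.n_normals, "norm"),
        ):
            noise = rng.normal(
                0.0, cfg.platform_noise_sd, size=base.data.shape
            ) if cfg.platform_noise_sd > 0 else 0.0
            values = base.data.to_numpy() + offsets[:, None] + noise
            cols = [f"{platform}_{tag}{j:02d}" for j in range(n_samples)]
            pair.append(
                ExpressionMatrix(
                    pd.DataFrame(values, index=base.gene_ids, columns=cols),
                    scale="log2",
                    dataset_id=platform,
                )
            )
        out.append(tuple(pair))
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# Coexpression matrix
# ---------------------------------------------------------------------------

def simulate_coexpression(
    cfg: SimulationConfig, blocks: list[list[str]], genes: list[str]
):
    """Correlation matrix with the given blocks at rho_in and zero elsewhere,
    plus a touch of seeded estimation noise (symmetrized, clipped)."""
    from .modules import CoexpressionMatrix

    rng = cfg.rng(salt=4)
    n = len(genes)
    corr = np.zeros((n, n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    noise = rng.normal(0.0, 0.02, size=(n, n))
    corr += np.triu(noise, k=1)
    corr += corr.T
    for blk in blocks:
        idx = [gene_pos[g] for g in blk if g in gene_pos]
        for a in idx:
            for b in idx:
                if a != b:
                    corr[a, b] = cfg.block_corr
    np.clip(corr, -0.99, 0.99, out=corr)
    np.fill_diagonal(corr, 1.0)
    return CoexpressionMatrix(list(genes), corr)


def empirical_coexpression(matrix: ExpressionMatrix):
    """Pearson correlation of log2 expression across samples."""
    from .modules import CoexpressionMatrix

    corr = np.corrcoef(matrix.to_log2().data.to_numpy())
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CoexpressionMatrix(matrix.gene_ids, np.nan_to_num(corr))


def write_fixture_directory(cfg: SimulationConfig, outdir) -> dict:
    """Materialize a complete fixture set: pathways.json, coexpr.tsv,
    cases.tsv, normals.tsv, annotations.tsv and truth.json."""
    import json
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = simulate_pathway_db(cfg)
    cases, normals, truth = simulate_expression(cfg, db)
    coexpr = simulate_coexpression(cfg, truth["blocks"], cases.gene_ids)
    io.write_pathway_db(db, outdir / "pathways.json")
    io.write_expression(cases, outdir / "cases.tsv")
    io.write_expression(normals, outdir / "normals.tsv")
    io.write_coexpression(coexpr, outdir / "coexpr.tsv")
    annotations = [
        io.SampleAnnotation(s, cases.dataset_id, "case") for s in cases.sample_ids
    ] + [
        io.SampleAnnotation(s, normals.dataset_id, "normal")
        for s in normals.sample_ids
    ]
    io.write_annotations(annotations, outdir / "annotations.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
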