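"""End-to-end orchestration: weights -> modules -> topology -> scores.

`run_pipeline` executes the four stages for one or more case/normal dataset
pairs, each dataset weighted independently, and writes scores, significance
and a machine-readable run-metadata sidecar.  Module and topology artifacts
depend only on the pathway database and coexpression input, so they are
computed once and shared across datasets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .differential import StatWeightConfig
from .modules import EMPTY_MODULES, build_modules
from .scoring import ScoringConfig, ipanda_scores, prepare_pathways, zscore_normalize

logger = logging.getLogger("ipanda")


@dataclass
class RunConfig:
    """Everything needed to reproduce a scoring run."""

    cases: list[str] = field(default_factory=list)  # one TSV/GCT per dataset
    normals: list[str] = field(default_factory=list)
    pathways: str = ""
    coexpression: str | None = None
    tf_targets: str | None = None
    modules: str | None = None  # precomputed module table overrides building
    annotations: str | None = None
    out_scores: str = "scores.tsv"
    out_significance: str | None = None
    p_min: float = 1e-7
    p_max: float = 1e-1
    size_normalize: bool = True
    module_agg: str = "mean"
    use_topology: bool = True
    use_modules: bool = True
    zscore: bool = False
    seed: int = 0

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(
            stat_weights=StatWeightConfig(self.p_min, self.p_max),
            size_normalize=self.size_normalize,
            module_agg=self.module_agg,
            use_topology=self.use_topology,
            use_modules=self.use_modules,
        )


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, *exc):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            logger.info("stage %s finished in %.2fs", name, timings[name])
            return False

    return _Timer()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline and return the run metadata dictionary.

    Raises with the failing stage's name attached; callers (the CLI) turn
    that into a nonzero exit status.
    """
    if len(cfg.cases) != len(cfg.normals) or not cfg.cases:
        raise ValueError("need matching, non-empty --cases/--normals lists")
    timings: dict[str, float] = {}
    meta = {"config": asdict(cfg), "stages": timings}

    with _stage("read_inputs", timings):
        db = io.read_pathway_db(cfg.pathways)
        pairs = []
        for case_path, normal_path in zip(cfg.cases, cfg.normals):
            cases = io.read_expression(case_path)
            normals = io.read_expression(normal_path)
            normals.dataset_id = cases.dataset_id
            pairs.append((cases, normals))

    with _stage("build_modules", timings):
        if cfg.modules:
            modules = io.read_modules(cfg.modules)
        elif cfg.coexpression and cfg.use_modules:
            coexpr = io.read_coexpression(cfg.coexpression)
            tf_sets = io.read_gene_sets(cfg.tf_targets) if cfg.tf_targets else None
            modules = build_modules(coexpr, tf_sets, pathway_genes=db.genes)
        else:
            modules = EMPTY_MODULES
        meta["n_modules"] = len(modules)

    scfg = cfg.scoring_config()
    with _stage("topological_weights", timings):
        prepared = prepare_pathways(db, modules, scfg)

    with _stage("score", timings):
        score_blocks, sig_blocks = [], []
        dataset_ids: dict[str, str] = {}
        for cases, normals in pairs:
            scores, sig = ipanda_scores(
                cases, normals, db, modules, scfg,
                prepared=prepared, return_significance=True,
            )
            score_blocks.append(scores.data)
            sig_blocks.append(sig.rename(cases.dataset_id))
            dataset_ids.update(scores.dataset_ids)
        merged = pd.concat(score_blocks, axis=1)
        from .scoring import ScoreMatrix

        all_scores = ScoreMatrix(merged, dataset_ids=dataset_ids)
        if cfg.zscore:
            if cfg.annotations:
                annotations = io.read_annotations(cfg.annotations)
            else:
                annotations = [
                    io.SampleAnnotation(s, dataset_ids[s], "case")
                    for s in all_scores.sample_ids
                ]
            all_scores = zscore_normalize(all_scores, annotations)

    with _stage("write_outputs", timings):
        io.write_scores(all_scores, cfg.out_scores)
        if cfg.out_significance:
            sig_df = pd.concat(sig_blocks, axis=1)
            sig_df.index.name = "pathway"
            sig_df.to_csv(cfg.out_significance, sep="\t", float_format="%.10g")
        meta_path = Path(cfg.out_scores).with_suffix(".meta.json")
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
    return meta
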