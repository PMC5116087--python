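"""Readers and writers for expression matrices, pathway databases and tables.

Expression input is tab-separated (first column header ``gene``, one column
per sample) or GCT 1.2.  Pathway topology uses a small JSON dialect — one
directed signed graph per pathway — with GMT accepted as a topology-free
fallback where every gene becomes an isolated node of sign +1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import (
    ACTIVATION,
    INHIBITION,
    PathwayDatabase,
    PathwayGraph,
    PathwayUnit,
    SchemaError,
)

logger = logging.getLogger("ipanda")

LINEAR = "linear"
LOG2 = "log2"

#: linear microarray intensities exceed this; log2 values essentially never do
_AUTO_SCALE_CUTOFF = 50.0


class FormatError(ValueError):
    """Raised for malformed expression input."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression intensities with an explicit scale.

    ``data`` rows are gene symbols, columns sample identifiers.  Missing
    entries are NaN; downstream statistics exclude a gene from a group when
    any of its values in that group is missing.
    """

    data: pd.DataFrame
    scale: str = LOG2
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate gene identifiers")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample identifiers")
        with np.errstate(invalid="ignore"):
            arr = self.data.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise FormatError("expression values must be finite where present")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy; linear data gets a pseudo-count if needed.

        Zeros are offset by half the smallest positive value in the matrix
        before taking logs; negative linear intensities are an error.
        """
        if self.scale == LOG2:
            return self
        arr = self.data.to_numpy(dtype=float)
        if np.nanmin(arr) < 0:
            raise FormatError(
                "negative linear intensities cannot be log-transformed"
            )
        if (arr == 0).any():
            positive = arr[arr > 0]
            if positive.size == 0:
                raise FormatError("all-zero linear expression matrix")
            eps = 0.5 * positive.min()
            arr = arr + eps
            logger.info("applied pseudo-count %.4g before log2", eps)
        return ExpressionMatrix(
            pd.DataFrame(np.log2(arr), index=self.data.index, columns=self.data.columns),
            scale=LOG2,
            dataset_id=self.dataset_id,
        )


@dataclass
class SampleAnnotation:
    """Per-sample metadata: dataset of origin, group and optional phenotype."""

    sample_id: str
    dataset_id: str
    group: str  # "case" | "normal"
    phenotype: str = "unknown"  # "responder" | "non-responder" | "unknown"

    def __post_init__(self) -> None:
        if self.group not in ("case", "normal"):
            raise ValueError(f"group must be 'case' or 'normal', got {self.group!r}")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _infer_scale(values: np.ndarray) -> str:
    finite = values[np.isfinite(values)]
    if finite.size and finite.max() > _AUTO_SCALE_CUTOFF:
        return LINEAR
    return LOG2


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    n_dropped = len(df) - df.index.nunique()
    # keep, per gene, the row with the highest mean intensity
    order = df.mean(axis=1, skipna=True).to_numpy()
    df = df.iloc[np.argsort(-order, kind="stable")]
    df = df[~df.index.duplicated(keep="first")]
    logger.info("collapsed %d duplicate gene rows by max mean intensity", n_dropped)
    return df


def read_expression(
    path: str | Path, scale: str = "auto", dataset_id: str | None = None
) -> ExpressionMatrix:
    """Read a TSV or GCT 1.2 expression matrix.

    Duplicate gene rows are collapsed to the row with the highest mean
    intensity (count logged).  ``scale='auto'`` infers linear vs log2 from
    the magnitude of the values.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = _read_gct(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns")
        df.index = df.index.astype(str)
    df = df.apply(pd.to_numeric, errors="coerce")
    df = _collapse_duplicates(df)
    values = df.to_numpy(dtype=float)
    resolved = _infer_scale(values) if scale == "auto" else scale
    return ExpressionMatrix(
        df, scale=resolved, dataset_id=dataset_id or path.stem
    )


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}: unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    else:  # GCT mandates the Description column; tolerate its absence
        logger.warning("%s: GCT file lacks a Description column", path)
    if df.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: declared dims {n_genes}x{n_samples} but found "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    df.index = df.index.astype(str)
    return df


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect (first column header ``gene``)."""
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a TSV of sample_id, dataset_id, group and optional phenotype."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "dataset_id", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation file needs columns {sorted(required)}")
    seen: dict[str, str] = {}
    out = []
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        did = str(row.dataset_id)
        if sid in seen and seen[sid] != did:
            raise FormatError(f"sample {sid!r} assigned to multiple datasets")
        seen[sid] = did
        phenotype = str(getattr(row, "phenotype", "unknown") or "unknown")
        out.append(SampleAnnotation(sid, did, str(row.group), phenotype))
    return out


def write_annotations(annotations: list[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            (a.sample_id, a.dataset_id, a.group, a.phenotype)
            for a in annotations
        ],
        columns=["sample_id", "dataset_id", "group", "phenotype"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathway databases
# ---------------------------------------------------------------------------

def read_pathway_db(path: str | Path) -> PathwayDatabase:
    """Read the pathway-topology JSON dialect, or GMT as topology-free fallback."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        return _read_gmt(path)
    with open(path) as fh:
        doc = json.load(fh)
    pathways = []
    for pw in doc.get("pathways", []):
        units = {}
        for node in pw.get("nodes", []):
            sign = node.get("sign", 1)
            if sign not in (1, -1):
                raise SchemaError(
                    f"pathway {pw.get('id')!r} node {node.get('id')!r}: "
                    f"sign {sign!r} outside {{+1,-1}}"
                )
            unit = PathwayUnit(
                str(node["id"]), tuple(str(g) for g in node["genes"]), sign
            )
            units[unit.unit_id] = unit
        edges = []
        for edge in pw.get("edges", []):
            etype = edge.get("type", ACTIVATION)
            if etype not in (ACTIVATION, INHIBITION):
                raise SchemaError(
                    f"pathway {pw.get('id')!r}: edge type {etype!r} invalid"
                )
            edges.append((str(edge["src"]), str(edge["dst"]), etype))
        pathways.append(PathwayGraph(str(pw["id"]), units, edges))
    return PathwayDatabase(
        pathways, name=doc.get("name", path.stem), version=str(doc.get("version", "0"))
    )


def _read_gmt(path: Path) -> PathwayDatabase:
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}: GMT line with fewer than 3 fields")
            pid, _desc, *genes = parts
            units = {
                g: PathwayUnit(g, (g,), +1) for g in dict.fromkeys(genes) if g
            }
            pathways.append(PathwayGraph(pid, units, []))
    return PathwayDatabase(pathways, name=path.stem)


def write_pathway_db(db: PathwayDatabase, path: str | Path) -> None:
    doc = {
        "name": db.name,
        "version": db.version,
        "pathways": [
            {
                "id": p.pathway_id,
                "nodes": [
                    {"id": u.unit_id, "genes": list(u.genes), "sign": u.sign}
                    for u in p.units.values()
                ],
                "edges": [
                    {"src": s, "dst": d, "type": t} for s, d, t in p.edges
                ],
            }
            for p in db.pathways
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Score matrices and tables
# ---------------------------------------------------------------------------

def write_scores(scores, path: str | Path) -> None:
    """Write a pathway x sample score matrix as full-precision TSV."""
    df = scores.data if hasattr(scores, "data") else scores
    if df.empty:
        raise ValueError("refusing to write an empty score matrix")
    df = df.copy()
    df.index.name = "pathway"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_coexpression(path: str | Path):
    """Read a square gene x gene correlation matrix TSV."""
    from .modules import CoexpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("coexpression matrix must have identical row/column genes")
    return CoexpressionMatrix(list(df.index), df.to_numpy(dtype=float))


def write_coexpression(coexpr, path: str | Path) -> None:
    df = pd.DataFrame(coexpr.corr, index=coexpr.gene_ids, columns=coexpr.gene_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets (e.g. transcription-factor target lists)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_modules(module_set, path: str | Path) -> None:
    rows = []
    for mod in module_set.modules:
        for gene in sorted(mod.genes):
            corr = "" if math.isnan(mod.mean_internal_corr) else f"{mod.mean_internal_corr:.6g}"
            rows.append((mod.module_id, gene, corr, mod.source))
    pd.DataFrame(
        rows, columns=["module_id", "gene", "mean_internal_corr", "source"]
    ).to_csv(path, sep="\t", index=False)


def read_modules(path: str | Path):
    from .modules import GeneModule, ModuleSet

    df = pd.read_csv(path, sep="\t")
    mods = []
    for mid, grp in df.groupby("module_id", sort=True):
        corr = grp["mean_internal_corr"].iloc[0]
        mods.append(
            GeneModule(
                str(mid),
                set(grp["gene"].astype(str)),
                float(corr) if pd.notna(corr) else float("nan"),
                str(grp["source"].iloc[0]),
            )
        )
    return ModuleSet.from_modules(mods)
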