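"""Readers and writers for the pipeline's on-disk formats.

Counts travel as a gene x sample TSV (or MatrixMarket with row/column index
files), metadata and networks as TSV, binding sites as BED6, gene sets as
GMT, and planted simulation truth as JSON.  All writers are deterministic:
the same in-memory object always serializes to identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .norm import METADATA_COLUMNS, CountMatrix
from .simulate import SimTruth

__all__ = [
    "write_counts_tsv", "read_counts_tsv",
    "write_counts_mtx", "read_counts_mtx",
    "write_metadata", "read_metadata",
    "write_annotation", "read_annotation",
    "write_bed6", "read_bed6",
    "write_ppi", "read_ppi",
    "write_gmt", "read_gmt",
    "write_truth", "read_truth",
]

_FLOAT_FMT = "%.10g"


# --- counts ----------------------------------------------------------------

def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, metadata: pd.DataFrame | None = None) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        genes=list(frame.index.astype(str)),
        samples=list(frame.columns.astype(str)),
        counts=frame.to_numpy(),
        metadata=metadata,
    )


def write_counts_mtx(cm: CountMatrix, prefix: str | Path) -> None:
    """Write counts as MatrixMarket plus .rows/.cols index files."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(cm.counts))
    prefix.with_suffix(".rows").write_text("\n".join(cm.genes) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(cm.samples) + "\n")


def read_counts_mtx(prefix: str | Path, metadata: pd.DataFrame | None = None) -> CountMatrix:
    prefix = Path(prefix)
    counts = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".rows").read_text().splitlines()
    samples = prefix.with_suffix(".cols").read_text().splitlines()
    return CountMatrix(genes=genes, samples=samples, counts=counts, metadata=metadata)


# --- metadata --------------------------------------------------------------

def write_metadata(cm: CountMatrix, path: str | Path) -> None:
    cm.metadata[list(METADATA_COLUMNS)].to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# --- gene annotation -------------------------------------------------------

_ANNOT_COLS = ["gene_id", "chrom", "strand", "tss", "span_start", "span_end"]


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot[_ANNOT_COLS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t")
    missing = set(_ANNOT_COLS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return annot


# --- BED6 ------------------------------------------------------------------

def write_bed6(track: pd.DataFrame, path: str | Path) -> None:
    track[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Parse a BED6 file; malformed lines raise with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED fields, "
                                 f"got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start_i < 0 or end_i <= start_i:
                raise ValueError(f"{path}: line {lineno}: invalid interval "
                                 f"[{start_i}, {end_i})")
            rows.append({"chrom": chrom, "start": start_i, "end": end_i,
                         "name": name, "score": score, "strand": strand})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# --- PPI -------------------------------------------------------------------

def write_ppi(ppi: pd.DataFrame, path: str | Path) -> None:
    ppi[["gene_a", "gene_b", "score"]].to_csv(path, sep="\t", index=False)


def read_ppi(path: str | Path) -> pd.DataFrame:
    ppi = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b", "score"} - set(ppi.columns)
    if missing:
        raise ValueError(f"PPI file missing columns: {sorted(missing)}")
    if ((ppi["score"] < 0) | (ppi["score"] > 1000)).any():
        raise ValueError("PPI scores must lie in [0, 1000]")
    return ppi


# --- GMT gene sets ---------------------------------------------------------

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "stingsig") -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            genes = sorted(set(map(str, gene_sets[name])))
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs name, "
                                 "description and at least one gene")
            sets[fields[0]] = set(fields[2:])
    return sets


# --- simulation truth ------------------------------------------------------

def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "module_assignment": {g: m for g, m in sorted(truth.module_assignment.items())},
        "core_genes": sorted(truth.core_genes),
        "induced_genes": sorted(truth.induced_genes),
        "tf_targets": {tf: sorted(gs) for tf, gs in sorted(truth.tf_targets.items())},
        "activation_curve": {m: list(map(float, v))
                             for m, v in sorted(truth.activation_curve.items())},
        "module_core": {m: sorted(gs) for m, gs in sorted(truth.module_core.items())},
        "responders": sorted(truth.responders) if truth.responders is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    return SimTruth(
        module_assignment=dict(payload["module_assignment"]),
        core_genes=set(payload["core_genes"]),
        induced_genes=set(payload["induced_genes"]),
        tf_targets={tf: set(gs) for tf, gs in payload["tf_targets"].items()},
        activation_curve={m: np.asarray(v) for m, v in payload["activation_curve"].items()},
        module_core={m: set(gs) for m, gs in payload.get("module_core", {}).items()},
        responders=set(payload["responders"]) if payload.get("responders") is not None else None,
    )
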