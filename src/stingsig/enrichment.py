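"""Promoter windows, TF binding-site target mapping, and module enrichment.

Core promoters span +-500 nt and proximal promoters +-1000 nt around the
transcription start site (half-open, clipped at zero).  A gene is a TF
target if any binding site of that TF overlaps the window by at least one
base pair on the same chromosome; per-module enrichment is a one-sided
Fisher test against the expressed-gene background with BH adjustment across
TFs within each window kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .discovery import GeneModule
from .stats import Table2x2, bh_adjust, fisher_exact_2x2

__all__ = [
    "PromoterWindow",
    "EnrichmentResult",
    "promoter_windows",
    "map_tf_targets",
    "module_tf_enrichment",
]

WindowKind = Literal["core", "proximal"]

#: Half-widths of the promoter windows around the TSS, in nt.
WINDOW_HALF_WIDTH = {"core": 500, "proximal": 1000}


@dataclass(frozen=True)
class PromoterWindow:
    """0-based half-open promoter interval of one gene."""

    gene: str
    chrom: str
    start: int
    end: int
    kind: WindowKind

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end}) for {self.gene}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-TF promoter-target enrichment within one module."""

    tf: str
    module_id: str
    window_kind: WindowKind
    table: Table2x2
    odds_ratio: float
    p: float
    q: float
    n_module_targets: int


def promoter_windows(annot: pd.DataFrame, kind: WindowKind) -> list[PromoterWindow]:
    """Promoter windows centered on each gene's TSS, clipped at zero.

    ``annot`` needs columns gene_id, chrom, strand, tss.  Minus-strand genes
    use their annotated TSS, which is the 3'-most genomic coordinate of the
    span; if a gene carries several TSS annotations the 5'-most (in gene
    orientation) is used.
    """
    if kind not in WINDOW_HALF_WIDTH:
        raise ValueError(f"kind must be 'core' or 'proximal', got {kind!r}")
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required <= set(annot.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if annot["strand"].isna().any() or not set(annot["strand"]) <= {"+", "-"}:
        raise ValueError("every gene needs a '+' or '-' strand")
    half = WINDOW_HALF_WIDTH[kind]

    frame = annot.copy()
    if frame["gene_id"].duplicated().any():
        # Multiple TSS records per gene: keep the 5'-most in gene orientation.
        plus = frame[frame["strand"] == "+"].groupby("gene_id", as_index=False).min()
        minus = frame[frame["strand"] == "-"].groupby("gene_id", as_index=False).max()
        frame = pd.concat([plus, minus], ignore_index=True).sort_values("gene_id")

    windows = []
    for row in frame.itertuples(index=False):
        tss = int(row.tss)
        start = max(0, tss - half)
        windows.append(
            PromoterWindow(str(row.gene_id), str(row.chrom), start, tss + half, kind)
        )
    return windows


def map_tf_targets(
    tfbs: pd.DataFrame, windows: Iterable[PromoterWindow]
) -> dict[str, set[str]]:
    """TF -> set of genes whose window a binding site overlaps by >= 1 bp.

    ``tfbs`` is a BED6 frame (chrom, start, end, name, score, strand) with
    0-based half-open intervals; the site's strand is ignored.
    """
    required = {"chrom", "start", "end", "name"}
    if not required <= set(tfbs.columns):
        raise ValueError(f"tfbs must have columns {sorted(required)}")
    win_list = list(windows)
    targets: dict[str, set[str]] = {tf: set() for tf in tfbs["name"].unique()}
    by_chrom: dict[str, pd.DataFrame] = {
        str(chrom): grp for chrom, grp in tfbs.groupby("chrom")
    }
    for w in win_list:
        sites = by_chrom.get(w.chrom)
        if sites is None:
            continue
        hit = (sites["start"].to_numpy() < w.end) & (sites["end"].to_numpy() > w.start)
        for tf in sites.loc[hit, "name"].unique():
            targets[str(tf)].add(w.gene)
    return targets


def module_tf_enrichment(
    targets: Mapping[str, set[str]],
    module: GeneModule,
    background: set[str],
    window_kind: WindowKind = "core",
) -> list[EnrichmentResult]:
    """Per-TF target enrichment in a module versus the expressed background.

    Builds the 2x2 table (in-module vs background-only) x (target vs
    non-target), applies a one-sided "greater" Fisher test, adjusts across
    TFs with BH, and sorts by q then descending odds ratio.
    """
    module_genes = set(module.genes)
    if not module_genes <= background:
        raise ValueError("module genes must be a subset of the background")
    bg_only = background - module_genes
    n_mod, n_bg = len(module_genes), len(bg_only)

    tfs = sorted(targets)
    raw = []
    for tf in tfs:
        tset = targets[tf] & background
        a = len(tset & module_genes)
        c = len(tset) - a
        table = Table2x2(a=a, b=n_mod - a, c=c, d=n_bg - c)
        res = fisher_exact_2x2(table, sidedness="greater")
        raw.append((tf, table, res))
    q = bh_adjust([res.p for _, _, res in raw])
    results = [
        EnrichmentResult(
            tf=tf,
            module_id=module.module_id,
            window_kind=window_kind,
            table=table,
            odds_ratio=res.effect,
            p=res.p,
            q=float(qv),
            n_module_targets=table.a,
        )
        for (tf, table, res), qv in zip(raw, q)
    ]
    results.sort(key=lambda r: (r.q, -r.odds_ratio, r.tf))
    return results
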