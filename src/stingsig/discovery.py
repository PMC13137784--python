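"""Stimulus-driven gene-module discovery from the time course.

Stage 1 fits, per gene, ordinary least-squares polynomials of degree 1-3 in
time, keeps the degree with the best adjusted R², and screens genes by the
F-test of that model at a Benjamini–Hochberg FDR gate.  Stage 2 builds a
co-expression graph over the selected genes (Pearson r of z-scored
per-timepoint mean profiles) and partitions it with Markov clustering (MCL).
Stage 3 refines clusters with a minimum-size filter followed by a
within-module protein-interaction filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "GeneModule",
    "fit_timecourse_models",
    "select_genes",
    "cluster_genes",
    "refine_modules",
]

#: Adjusted-R² tie tolerance when comparing candidate polynomial degrees.
DEGREE_TIE_TOL = 1e-12

# MCL numerics.
MCL_INFLATION = 2.0
MCL_PRUNE = 1e-5
MCL_TOL = 1e-8
MCL_MAX_ITER = 100


@dataclass(frozen=True)
class RegressionFit:
    """Best polynomial fit of expression on time for one gene."""

    gene: str
    degree: int
    r2: float
    adj_r2: float
    f_stat: float
    p: float
    q: float | None = None


@dataclass(frozen=True)
class GeneModule:
    """A named gene set with provenance through the refinement stages."""

    module_id: str
    genes: frozenset[str]
    stage: str = "raw_cluster"  # raw_cluster | ppi_filtered | final

    def __len__(self) -> int:
        return len(self.genes)


def fit_timecourse_models(
    expr: pd.DataFrame, times: Sequence[float]
) -> list[RegressionFit]:
    """Per-gene best polynomial (degree 1-3) of expression on time.

    ``expr`` is a gene x sample log-expression frame; ``times`` gives the
    hours post-stimulation of each column (replicate-level observations).
    The best degree maximizes adjusted R² (ties within ``DEGREE_TIE_TOL``
    resolve to the lowest degree); significance is the overall F test of the
    selected model.  Constant genes get R² = 0, F = 0, p = 1.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size != expr.shape[1]:
        raise ValueError("times must match the number of samples")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    n = t.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct times")

    y = expr.to_numpy(dtype=float).T  # samples x genes
    ybar = y.mean(axis=0)
    ss_tot = ((y - ybar) ** 2).sum(axis=0)
    constant = ss_tot <= 0

    n_genes = expr.shape[0]
    best_deg = np.ones(n_genes, dtype=int)
    best_adj = np.full(n_genes, -np.inf)
    best_r2 = np.zeros(n_genes)
    for degree in (1, 2, 3):
        df_resid = n - degree - 1
        if df_resid <= 0:
            logger.warning("skipping degree %d: no residual degrees of freedom", degree)
            continue
        design = np.vander(t, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = (resid**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
        better = adj > best_adj + DEGREE_TIE_TOL
        best_deg = np.where(better, degree, best_deg)
        best_adj = np.where(better, adj, best_adj)
        best_r2 = np.where(better, r2, best_r2)

    fits: list[RegressionFit] = []
    for i, gene in enumerate(expr.index):
        if constant[i]:
            fits.append(RegressionFit(gene, 1, 0.0, 0.0, 0.0, 1.0))
            continue
        d = int(best_deg[i])
        r2 = float(best_r2[i])
        df_resid = n - d - 1
        if r2 >= 1.0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (r2 / d) / ((1.0 - r2) / df_resid)
            p = float(sps.f.sf(f_stat, d, df_resid))
        fits.append(RegressionFit(gene, d, r2, float(best_adj[i]), float(f_stat), p))
    return fits


def select_genes(fits: Sequence[RegressionFit], fdr: float = 0.10) -> set[str]:
    """Genes whose selected-model F test passes the BH gate (q < fdr)."""
    if not fits:
        raise ValueError("fits must be non-empty")
    q = bh_adjust([f.p for f in fits])
    return {f.gene for f, qv in zip(fits, q) if qv < fdr}


def attach_q(fits: Sequence[RegressionFit]) -> list[RegressionFit]:
    """Return fits with BH q-values filled in."""
    q = bh_adjust([f.p for f in fits])
    return [replace(f, q=float(qv)) for f, qv in zip(fits, q)]


def _mcl(adjacency: np.ndarray, inflation: float = MCL_INFLATION) -> list[set[int]]:
    """Markov clustering on a weighted adjacency matrix.

    Self-loops of weight 1 are added, columns are stochastic-normalized, and
    expansion (matrix square) alternates with inflation (elementwise power)
    plus pruning until convergence.  Clusters are read off the attractor
    rows; overlaps are resolved by the caller.
    """
    m = adjacency.astype(float).copy()
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0)
    for _ in range(MCL_MAX_ITER):
        prev = m
        m = m @ m
        m = m**inflation
        m /= m.sum(axis=0)
        m[m < MCL_PRUNE] = 0.0
        colsum = m.sum(axis=0)
        dead = colsum == 0
        if dead.any():  # restore isolated columns as self-attractors
            m[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
            colsum = m.sum(axis=0)
        m /= colsum
        if np.max(np.abs(m - prev)) < MCL_TOL:
            break
    attractors = np.flatnonzero(np.diag(m) > 0)
    clusters: list[set[int]] = []
    seen: set[frozenset[int]] = set()
    for i in attractors:
        members = frozenset(np.flatnonzero(m[i] > 0).tolist())
        if members and members not in seen:
            seen.add(members)
            clusters.append(set(members))
    return clusters


def cluster_genes(
    expr: pd.DataFrame,
    genes: set[str],
    times: Sequence[float],
    r_min: float = 0.7,
    inflation: float = MCL_INFLATION,
) -> list[GeneModule]:
    """Partition selected genes into co-expression modules with MCL.

    Per-gene profiles are per-timepoint means (replicates averaged),
    z-scored; the graph links gene pairs with Pearson r >= ``r_min``
    (edge weight = r).  Nodes landing in several MCL clusters are assigned
    to the largest one (ties to the cluster whose lexicographically smallest
    member gene id is smallest); unassigned nodes become singletons.
    """
    if not 0.0 < r_min < 1.0:
        raise ValueError(f"r_min must lie in (0, 1), got {r_min}")
    if len(genes) < 1:
        raise ValueError("need at least one gene")
    gene_list = sorted(genes & set(expr.index))
    if len(gene_list) != len(genes):
        raise ValueError("some genes are missing from the expression matrix")
    t = np.asarray(times, dtype=float)
    sub = expr.loc[gene_list].to_numpy(dtype=float)

    uniq_t = np.unique(t)
    profiles = np.column_stack([sub[:, t == u].mean(axis=1) for u in uniq_t])
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (profiles - mu) / sd, 0.0)

    if len(gene_list) == 1:
        return [GeneModule(module_id="C1", genes=frozenset(gene_list))]

    corr = np.corrcoef(z)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.where(corr >= r_min, corr, 0.0)
    np.fill_diagonal(adj, 0.0)

    raw = _mcl(adj, inflation=inflation)

    garr = np.asarray(gene_list)
    # Assign multi-cluster nodes to the largest cluster; tie-break on the
    # cluster's smallest member gene id.
    keyed = sorted(raw, key=lambda c: (-len(c), min(garr[sorted(c)])))
    assigned: dict[int, int] = {}
    for ci, cluster in enumerate(keyed):
        for node in cluster:
            assigned.setdefault(node, ci)
    final: dict[int, set[int]] = {}
    for node, ci in assigned.items():
        final.setdefault(ci, set()).add(node)
    leftovers = set(range(len(gene_list))) - set(assigned)
    member_sets = [final[ci] for ci in sorted(final)] + [{n} for n in sorted(leftovers)]
    member_sets.sort(key=lambda s: (-len(s), min(garr[sorted(s)])))
    return [
        GeneModule(module_id=f"C{i + 1}", genes=frozenset(garr[sorted(s)].tolist()))
        for i, s in enumerate(member_sets)
    ]


def refine_modules(
    modules: Sequence[GeneModule],
    ppi: pd.DataFrame,
    min_size: int = 50,
    min_ppi_score: float = 400,
) -> list[GeneModule]:
    """Size filter, then within-module protein-interaction filter.

    Raw clusters below ``min_size`` are dropped first; then genes lacking
    any within-module PPI edge with score >= ``min_ppi_score`` are removed.
    Modules that fall below ``min_size`` after the PPI step are dropped so
    every final module respects the size floor.
    """
    if not {"gene_a", "gene_b", "score"} <= set(ppi.columns):
        raise ValueError("ppi must have columns gene_a, gene_b, score")
    strong = ppi[ppi["score"] >= min_ppi_score]
    partners: dict[str, set[str]] = {}
    for ga, gb in zip(strong["gene_a"], strong["gene_b"]):
        partners.setdefault(str(ga), set()).add(str(gb))
        partners.setdefault(str(gb), set()).add(str(ga))

    sized = [m for m in modules if len(m.genes) >= min_size]
    logger.info(
        "refine_modules: %d/%d clusters pass the size filter (>=%d genes)",
        len(sized), len(modules), min_size,
    )
    result: list[GeneModule] = []
    for mod in sized:
        kept = {
            g for g in mod.genes if partners.get(g, set()) & (mod.genes - {g})
        }
        dropped = len(mod.genes) - len(kept)
        if dropped:
            logger.info(
                "refine_modules: %s lost %d genes without strong within-module PPI",
                mod.module_id, dropped,
            )
        if len(kept) >= min_size:
            result.append(GeneModule(mod.module_id, frozenset(kept), stage="final"))
        else:
            logger.warning(
                "refine_modules: %s fell below %d genes after PPI filtering; dropped",
                mod.module_id, min_size,
            )
    if not result:
        logger.warning("refine_modules produced no modules")
    return result
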