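"""Differential expression, core-signature derivation, and sample scoring.

Differential expression uses a negative-binomial exact test between two
groups after TMM normalization: libraries are equalized by scaling to the
geometric-mean effective library size, group sums are treated as aggregated
negative binomials with a common dispersion (estimated by maximizing the
conditional likelihood given per-gene group totals), and the two-sided
p-value sums the probabilities of all conditional splits no more likely
than the observed one.  The core signature is the intersection of a
module's genes, a TF's promoter targets, and the significantly induced
genes; a sample's signature score is the median expression of the core
genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .discovery import GeneModule
from .norm import CountMatrix, NormFactors, tmm_factors
from .stats import TWO_SIDED_RTOL, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "DeResult",
    "SignatureScore",
    "estimate_common_dispersion",
    "nb_exact_test",
    "derive_core_signature",
    "signature_score",
]

#: Search interval for the common dispersion (phi), optimized on log scale.
DISPERSION_BOUNDS = (1e-6, 10.0)

#: Prior count added to each group's normalized mean when computing LFC.
LFC_PRIOR = 0.125

ScoreMode = Literal["median_log2cpm", "median_z"]


@dataclass(frozen=True)
class DeResult:
    """Per-gene two-group differential-expression result."""

    gene: str
    lfc: float
    p: float
    q: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class SignatureScore:
    """Per-sample signature activity: median over signature genes."""

    sample: str
    score: float
    mode: ScoreMode
    n_genes_used: int


def _equalized_pseudocounts(
    cm: CountMatrix, nf: NormFactors | None = None
) -> tuple[np.ndarray, float]:
    """Counts rescaled (and rounded) to the geometric-mean effective library."""
    if nf is None:
        nf = tmm_factors(cm)
    eff = nf.effective_library_sizes(cm)
    geo = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(cm.counts * (geo / eff)[None, :]).astype(np.int64)
    return pseudo, geo


def _cond_log_lik(pseudo_groups: list[np.ndarray], phi: float) -> float:
    """Summed NB conditional log-likelihood given per-gene group totals."""
    r = 1.0 / phi
    total = 0.0
    for y in pseudo_groups:  # genes x samples within one group
        n_samples = y.shape[1]
        n_genes = y.shape[0]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            - n_genes * n_samples * gammaln(r)
            + n_genes * gammaln(n_samples * r)
            - np.sum(gammaln(z + n_samples * r))
        )
    return total


def estimate_common_dispersion(
    cm: CountMatrix, groups: Mapping[str, Sequence[str]]
) -> float:
    """Common NB dispersion maximizing the conditional likelihood.

    ``groups`` maps group labels to sample-id lists (>= 2 samples each).
    Counts are first equalized to the geometric-mean library size; the
    optimizer is a deterministic golden-section search over log-dispersion
    in ``DISPERSION_BOUNDS``.
    """
    for label, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
    pseudo, _ = _equalized_pseudocounts(cm)
    col = {s: j for j, s in enumerate(cm.samples)}
    pseudo_groups = []
    for members in groups.values():
        idx = [col[s] for s in members]
        y = pseudo[:, idx]
        y = y[y.sum(axis=1) > 0]  # all-zero genes carry no conditional information
        pseudo_groups.append(y)

    lo, hi = (math.log(b) for b in DISPERSION_BOUNDS)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _cond_log_lik(pseudo_groups, math.exp(c))
    fd = _cond_log_lik(pseudo_groups, math.exp(d))
    for _ in range(200):
        if b - a < 1e-10:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _cond_log_lik(pseudo_groups, math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _cond_log_lik(pseudo_groups, math.exp(d))
    return float(math.exp(0.5 * (a + b)))


def _split_logpmf(total: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Log-probabilities of S_a = 0..total conditional on S_a + S_b = total.

    For dispersion 0 this is Binomial(total, n_a/(n_a+n_b)); otherwise the
    conditional law of aggregated negative binomials with sizes n_a/phi and
    n_b/phi given their sum.
    """
    k = np.arange(total + 1)
    if dispersion <= 0:
        p = n_a / (n_a + n_b)
        logpmf = (
            gammaln(total + 1) - gammaln(k + 1) - gammaln(total - k + 1)
            + k * math.log(p) + (total - k) * math.log1p(-p)
        )
        return logpmf
    ra = n_a / dispersion
    rb = n_b / dispersion
    logw = (
        gammaln(k + ra) - gammaln(k + 1)
        + gammaln(total - k + rb) - gammaln(total - k + 1)
    )
    return logw - logsumexp(logw)


def nb_exact_test(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dispersion: float,
    nf: NormFactors | None = None,
) -> list[DeResult]:
    """Exact NB test of group A vs group B per gene, BH-adjusted.

    Returns results in gene order; genes with zero pseudo-counts in both
    groups are excluded (logged).  ``lfc`` is log2 of the ratio of
    TMM-normalized group means with a prior of ``LFC_PRIOR`` per group.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    if nf is None:
        nf = tmm_factors(cm)
    pseudo, _ = _equalized_pseudocounts(cm, nf)
    col = {s: j for j, s in enumerate(cm.samples)}
    ia = [col[s] for s in ga]
    ib = [col[s] for s in gb]
    sa = pseudo[:, ia].sum(axis=1)
    sb = pseudo[:, ib].sum(axis=1)
    totals = sa + sb

    # Normalized per-group means for fold changes (CPM-like units).
    eff = nf.effective_library_sizes(cm)
    norm = cm.counts / eff[None, :] * 1e6
    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)

    n_skipped = 0
    rows: list[tuple[str, float, float, float]] = []
    for i, gene in enumerate(cm.genes):
        t = int(totals[i])
        if t == 0:
            n_skipped += 1
            continue
        logpmf = _split_logpmf(t, len(ia), len(ib), dispersion)
        log_obs = logpmf[int(sa[i])]
        p = float(np.exp(logsumexp(logpmf[logpmf <= log_obs + math.log1p(TWO_SIDED_RTOL)])))
        lfc = math.log2((mean_a[i] + LFC_PRIOR) / (mean_b[i] + LFC_PRIOR))
        rows.append((gene, lfc, min(1.0, p), i))
    if n_skipped:
        logger.info("nb_exact_test: excluded %d genes with zero counts in both groups",
                    n_skipped)
    if not rows:
        return []
    q = bh_adjust([r[2] for r in rows])
    return [
        DeResult(
            gene=g, lfc=lfc, p=p, q=float(qv),
            mean_a=float(mean_a[i]), mean_b=float(mean_b[i]),
        )
        for (g, lfc, p, i), qv in zip(rows, q)
    ]


def derive_core_signature(
    module: GeneModule,
    tf_targets: set[str],
    de: Sequence[DeResult],
    fdr: float = 0.05,
) -> tuple[set[str], dict[str, str]]:
    """Core signature: module genes that are TF targets and induced.

    Returns ``(core, provenance)`` where provenance records, for each module
    gene excluded, which criterion removed it ("not_tf_target",
    "not_induced", or "no_de_result").
    """
    de_by_gene = {r.gene: r for r in de}
    core: set[str] = set()
    provenance: dict[str, str] = {}
    for g in sorted(module.genes):
        res = de_by_gene.get(g)
        if g not in tf_targets:
            provenance[g] = "not_tf_target"
        elif res is None:
            provenance[g] = "no_de_result"
        elif not (res.q < fdr and res.lfc > 0):
            provenance[g] = "not_induced"
        else:
            core.add(g)
            provenance[g] = "core"
    if not core:
        logger.warning("derive_core_signature: empty core signature")
    return core, provenance


def signature_score(
    expr: pd.DataFrame,
    core: Iterable[str],
    mode: ScoreMode = "median_log2cpm",
) -> list[SignatureScore]:
    """Per-sample median expression of the signature genes.

    ``median_log2cpm`` takes the median of the genes' log2-CPM values in the
    sample; ``median_z`` first z-scores each gene across the analyzed
    cohort, dropping zero-variance genes.  An even number of genes yields
    the mean of the central pair.
    """
    if mode not in ("median_log2cpm", "median_z"):
        raise ValueError(f"unknown score mode {mode!r}")
    core_list = sorted(set(core))
    present = [g for g in core_list if g in expr.index]
    missing = len(core_list) - len(present)
    if missing:
        logger.info("signature_score: %d signature genes absent from matrix", missing)
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expr.loc[present]
    if mode == "median_z":
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all signature genes have zero variance; cannot z-score")
        sub = sub.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    med = sub.median(axis=0)
    n_used = sub.shape[0]
    return [
        SignatureScore(sample=str(s), score=float(med[s]), mode=mode, n_genes_used=n_used)
        for s in expr.columns
    ]
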