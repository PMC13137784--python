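"""End-to-end orchestration of discovery, enrichment, derivation and scoring.

These helpers wire the per-module operations into the canonical flow: fit
the time course, gate by FDR, cluster, refine with the PPI network, find
the top promoter-enriched TF of the focal module, test induction with the
NB exact test, intersect to the core signature, and score samples.  The
CLI and analysis scripts are thin wrappers around this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import (
    GeneModule,
    RegressionFit,
    attach_q,
    cluster_genes,
    fit_timecourse_models,
    refine_modules,
    select_genes,
)
from .enrichment import EnrichmentResult, map_tf_targets, module_tf_enrichment, promoter_windows
from .norm import CountMatrix, group_lfc, log2_cpm, tmm_factors
from .signature import (
    DeResult,
    derive_core_signature,
    estimate_common_dispersion,
    nb_exact_test,
)

logger = logging.getLogger(__name__)

__all__ = ["DiscoveryResult", "SignatureDerivation", "discover_modules", "derive_signature"]


@dataclass
class DiscoveryResult:
    """Everything the discovery stage produced."""

    fits: list[RegressionFit]
    selected: set[str]
    raw_modules: list[GeneModule]
    final_modules: list[GeneModule]
    expr: pd.DataFrame  # log2-CPM, all samples
    treated_samples: list[str]
    control_samples: list[str]
    times: np.ndarray


@dataclass
class SignatureDerivation:
    """Core-signature derivation record for one focal module."""

    focal_module: GeneModule
    top_tf: str
    enrichment: dict[str, list[EnrichmentResult]]  # per window kind
    de: list[DeResult]
    core: set[str]
    provenance: dict[str, str] = field(default_factory=dict)


def discover_modules(
    cm: CountMatrix,
    ppi: pd.DataFrame,
    fdr: float = 0.10,
    r_min: float = 0.7,
    inflation: float = 2.0,
    min_size: int = 50,
    min_ppi_score: float = 400,
) -> DiscoveryResult:
    """Run regression screening, MCL clustering and module refinement.

    Treated samples (metadata ``condition == "treated"``) drive the
    regression and clustering; the control arm is kept for downstream
    contrasts.
    """
    md = cm.metadata
    treated = [s for s in cm.samples if md.loc[s, "condition"] == "treated"]
    control = [s for s in cm.samples if md.loc[s, "condition"] == "control"]
    if not treated:
        raise ValueError("no samples with condition == 'treated'")
    times = md.loc[treated, "time_h"].to_numpy(dtype=float)
    nf = tmm_factors(cm)
    expr = log2_cpm(cm, nf)

    fits = attach_q(fit_timecourse_models(expr[treated], times))
    selected = select_genes(fits, fdr=fdr)
    logger.info("discover_modules: %d/%d genes pass the FDR<%g gate",
                len(selected), len(fits), fdr)
    if not selected:
        return DiscoveryResult(fits, selected, [], [], expr, treated, control, times)
    raw = cluster_genes(expr[treated], selected, times, r_min=r_min, inflation=inflation)
    final = refine_modules(raw, ppi, min_size=min_size, min_ppi_score=min_ppi_score)
    logger.info("discover_modules: %d raw clusters -> %d final modules",
                len(raw), len(final))
    return DiscoveryResult(fits, selected, raw, final, expr, treated, control, times)


def _focal_module(disc: DiscoveryResult) -> GeneModule:
    """The module with the strongest mean induction (treated vs control)."""
    post = [s for s, t in zip(disc.treated_samples, disc.times) if t > 0]
    lfc = group_lfc(disc.expr, post, disc.control_samples)
    best, best_lfc = None, -np.inf
    for mod in disc.final_modules:
        val = float(lfc[list(mod.genes)].mean())
        if val > best_lfc:
            best, best_lfc = mod, val
    if best is None:
        raise ValueError("no final modules to derive a signature from")
    logger.info("focal module %s (mean LFC %.2f)", best.module_id, best_lfc)
    return best


def derive_signature(
    cm: CountMatrix,
    disc: DiscoveryResult,
    annot: pd.DataFrame,
    tfbs: pd.DataFrame,
    focal: GeneModule | None = None,
    fdr_de: float = 0.05,
    dispersion: float | None = None,
    target_windows: tuple[str, ...] = ("core", "proximal"),
) -> SignatureDerivation:
    """Derive the core signature of the focal (default: strongest-induced)
    module: promoter-target enrichment picks the top TF, the NB exact test
    (treated vs control, post-stimulation timepoints pooled) defines the
    induced genes, and the core is the three-way intersection.

    A gene counts as a TF target if targeted in any of ``target_windows``.
    """
    if focal is None:
        focal = _focal_module(disc)
    background = set(disc.expr.index)

    enrichment: dict[str, list[EnrichmentResult]] = {}
    targets_by_kind: dict[str, dict[str, set[str]]] = {}
    for kind in ("core", "proximal"):
        windows = promoter_windows(annot, kind)  # type: ignore[arg-type]
        targets = map_tf_targets(tfbs, windows)
        targets_by_kind[kind] = targets
        enrichment[kind] = module_tf_enrichment(targets, focal, background, kind)  # type: ignore[arg-type]

    ranked = enrichment[target_windows[0]]
    top_tf = ranked[0].tf
    tf_target_set: set[str] = set()
    for kind in target_windows:
        tf_target_set |= targets_by_kind[kind].get(top_tf, set())

    post = [s for s, t in zip(disc.treated_samples, disc.times) if t > 0]
    t0_controls = disc.control_samples
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            cm, {"treated": post, "control": t0_controls}
        )
        logger.info("common dispersion estimate: %.4f", dispersion)
    de = nb_exact_test(cm, post, t0_controls, dispersion)
    core, provenance = derive_core_signature(focal, tf_target_set, de, fdr=fdr_de)
    logger.info("core signature: %d genes (module %s, TF %s)",
                len(core), focal.module_id, top_tf)
    return SignatureDerivation(
        focal_module=focal, top_tf=top_tf, enrichment=enrichment,
        de=de, core=core, provenance=provenance,
    )
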