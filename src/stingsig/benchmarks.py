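"""Study-condition benchmarks: recovery and calibration of the pipeline on
its own synthetic designs.

Each function simulates the named design across seeds and measures how well
the pipeline recovers the planted structure (module partition, core
signature, dose monotonicity, case/control separation, responder status,
dispersion).  They power both the test suite and the results-reproduction
script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import (
    SimConfig,
    cohort_auroc,
    discover_modules,
    derive_signature,
    dose_response_correlation,
    estimate_common_dispersion,
    group_lfc,
    log2_cpm,
    responder_test,
    signature_score,
    simulate_annotations,
    simulate_cohort,
    simulate_dose_ladder,
    simulate_paired_inhibition,
    simulate_timecourse,
    tmm_factors,
)
from .discovery import fit_timecourse_models, select_genes

__all__ = [
    "null_timecourse_fdp",
    "end_to_end_recovery",
    "dose_score_correlation",
    "cohort_aurocs",
    "responder_counts",
    "dispersion_estimates",
]

#: All-null time course used for false-discovery calibration: 6 timepoints,
#: duplicates, no planted modules.
NULL_TIMECOURSE = dict(n_modules=0, timepoints=(0.0, 2.0, 4.0, 8.0, 16.0, 24.0))


def null_timecourse_fdp(seeds: Sequence[int]) -> list[float]:
    """Per-seed false-discovery proportion of the regression screen under an
    all-null time course (every selection is a false discovery)."""
    out = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, **NULL_TIMECOURSE)
        cm, _ = simulate_timecourse(cfg)
        expr = log2_cpm(cm, tmm_factors(cm))
        treated = [s for s in cm.samples if cm.metadata.loc[s, "condition"] == "treated"]
        times = cm.metadata.loc[treated, "time_h"].to_numpy(dtype=float)
        fits = fit_timecourse_models(expr[treated], times)
        n_selected = len(select_genes(fits, fdr=0.10))
        out.append(1.0 if n_selected > 0 else 0.0)
    return out


def end_to_end_recovery(seeds: Sequence[int]) -> tuple[list[float], list[float]]:
    """Module-partition ARI and core-signature Jaccard per seed.

    ARI compares the final-module partition against the planted assignment
    over the genes the final modules contain (non-planted genes count as a
    "background" class).  Jaccard compares the derived core signature of the
    strongest-induced final module against the planted core of its
    best-matching module.
    """
    aris, jaccards = [], []
    for seed in seeds:
        cfg = SimConfig(seed=seed)
        cm, truth = simulate_timecourse(cfg)
        annot, tfbs, ppi = simulate_annotations(cfg, truth)
        disc = discover_modules(cm, ppi)
        pred = {g: m.module_id for m in disc.final_modules for g in m.genes}
        universe = sorted(pred)
        aris.append(
            adjusted_rand_score(
                [truth.module_assignment[g] or "background" for g in universe],
                [pred[g] for g in universe],
            )
            if universe
            else 0.0
        )
        deriv = derive_signature(cm, disc, annot, tfbs)
        best = max(truth.module_core,
                   key=lambda m: len(truth.module_core[m] & deriv.core))
        planted = truth.module_core[best]
        union = deriv.core | planted
        jaccards.append(len(deriv.core & planted) / len(union) if union else 0.0)
    return aris, jaccards


def dose_score_correlation(seeds: Sequence[int], noise_sd: float = 0.1) -> list[float]:
    """Pearson r of the signature score against the stimulus dose ladder."""
    out = []
    for seed in seeds:
        cfg = replace(SimConfig(seed=seed), noise_sd=noise_sd)
        cm, truth = simulate_dose_ladder(cfg)
        expr = log2_cpm(cm, tmm_factors(cm))
        scores = signature_score(expr, truth.core_genes)
        r, _ = dose_response_correlation(scores, cm.metadata["dose"].to_dict())
        out.append(r)
    return out


def cohort_aurocs(
    seeds: Sequence[int], effect: float, n_case: int = 20, n_control: int = 20
) -> list[float]:
    """AUROC of the signature score on simulated case/control cohorts."""
    out = []
    for seed in seeds:
        cm, truth = simulate_cohort(SimConfig(seed=seed), n_case, n_control, effect)
        expr = log2_cpm(cm, tmm_factors(cm))
        scores = signature_score(expr, truth.core_genes)
        labels = {s: 1 if cm.metadata.loc[s, "label"] == "case" else 0
                  for s in cm.samples}
        out.append(cohort_auroc(scores, labels))
    return out


def responder_counts(
    seeds: Sequence[int], responder_fraction: float, n_patients: int = 28
) -> list[tuple[int, int]]:
    """(detected responders, patients tested) per seed for the paired
    antagonist design."""
    out = []
    for seed in seeds:
        cm, truth = simulate_paired_inhibition(
            SimConfig(seed=seed), n_patients, responder_fraction
        )
        expr = log2_cpm(cm, tmm_factors(cm))
        md = cm.metadata
        paired = {}
        for pid, grp in md.groupby("pair_id"):
            arms = grp.reset_index().set_index("condition")["sample_id"]
            paired[str(pid)] = group_lfc(expr, [arms["treated"]], [arms["vehicle"]])
        results = responder_test(paired, truth.core_genes)
        out.append((sum(r.responder for r in results), len(results)))
    return out


def dispersion_estimates(seeds: Sequence[int], phi: float = 0.2) -> list[float]:
    """Common-dispersion estimates on pure NB cohorts with known phi."""
    out = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, n_genes=500, n_modules=0, noise_sd=0.0,
                        dispersion_log_mean_sd=(float(np.log(phi)), 0.0))
        cm, _ = simulate_cohort(cfg, 4, 4, 0.0)
        groups = {"case": [s for s in cm.samples if s.startswith("CASE")],
                  "control": [s for s in cm.samples if s.startswith("HC")]}
        out.append(estimate_common_dispersion(cm, groups))
    return out
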