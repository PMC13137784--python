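"""Downstream diagnostics on a derived signature.

Activation calling (per-sample correlation of induction profiles with the
reference stimulation response), antagonist responder testing (per-patient
rank-sum of signature-gene fold changes against the transcriptome
background), responsiveness ranking of signature genes, dose-response
correlation of the signature score, and PCA variance explained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signature import SignatureScore
from .stats import auroc, bh_adjust, pearson_r, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationCall",
    "ResponderResult",
    "activation_call",
    "responder_test",
    "responsiveness_rank",
    "dose_response_correlation",
    "pca_variance_explained",
    "cohort_auroc",
]

#: Pearson-correlation threshold above which (strictly) a sample is called
#: pathway-activated.
ACTIVATION_THRESHOLD = 0.6

#: BH-adjusted p-value below which a patient counts as an antagonist
#: responder (with median signature-gene suppression).
RESPONDER_Q = 0.05


@dataclass(frozen=True)
class ActivationCall:
    """Per-sample activation status against a reference induction profile."""

    sample: str
    r: float
    activated: bool
    reference: str


@dataclass(frozen=True)
class ResponderResult:
    """Per-patient antagonist-response test outcome."""

    patient: str
    p: float
    q: float
    responder: bool
    median_core_lfc: float


def activation_call(
    sample_lfc: pd.Series,
    reference_lfc: pd.Series,
    core: set[str],
    threshold: float = ACTIVATION_THRESHOLD,
    sample_id: str = "",
    reference: str = "stimulation",
) -> ActivationCall:
    """Call a sample activated if its core-gene induction correlates with the
    reference induction profile with Pearson r strictly above ``threshold``.
    """
    shared = sorted(core & set(sample_lfc.index) & set(reference_lfc.index))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared signature genes")
    r, _ = pearson_r(sample_lfc[shared].to_numpy(), reference_lfc[shared].to_numpy())
    return ActivationCall(
        sample=sample_id, r=r, activated=bool(r > threshold), reference=reference
    )


def responder_test(
    paired_lfc: Mapping[str, pd.Series], core: set[str]
) -> list[ResponderResult]:
    """Per-patient test of signature-gene suppression after treatment.

    ``paired_lfc`` maps patient id to a per-gene treated-vs-vehicle log2
    fold-change series covering signature and background genes.  Each
    patient gets a one-sided rank-sum test (signature LFCs stochastically
    less than all other genes' LFCs); q-values are BH across patients, and a
    responder needs q < RESPONDER_Q and a negative median signature LFC.
    """
    patients = sorted(paired_lfc)
    raw = []
    for pid in patients:
        lfc = paired_lfc[pid]
        core_vals = lfc[lfc.index.isin(core)].to_numpy(dtype=float)
        other_vals = lfc[~lfc.index.isin(core)].to_numpy(dtype=float)
        if core_vals.size == 0 or other_vals.size == 0:
            logger.warning("responder_test: patient %s lacks core or background LFCs; excluded",
                           pid)
            continue
        res = rank_sum_test(core_vals, other_vals, sidedness="less")
        raw.append((pid, res.p, float(np.median(core_vals))))
    if not raw:
        return []
    q = bh_adjust([p for _, p, _ in raw])
    return [
        ResponderResult(
            patient=pid,
            p=p,
            q=float(qv),
            responder=bool(qv < RESPONDER_Q and med < 0),
            median_core_lfc=med,
        )
        for (pid, p, med), qv in zip(raw, q)
    ]


def responsiveness_rank(
    baseline_expr: pd.DataFrame, lfc: pd.DataFrame, core: set[str]
) -> list[tuple[str, float]]:
    """Rank signature genes by responsiveness to the antagonist.

    For each signature gene, simple linear regression of its per-patient
    treatment LFC on its per-patient baseline (vehicle) expression; genes
    are ranked by descending R².  Zero-variance baselines get R² = 0 and
    rank last (ties broken by gene id).
    """
    patients = [p for p in baseline_expr.columns if p in set(lfc.columns)]
    if len(patients) < 3:
        raise ValueError("need at least 3 patients")
    out = []
    for g in sorted(core & set(baseline_expr.index) & set(lfc.index)):
        x = baseline_expr.loc[g, patients].to_numpy(dtype=float)
        y = lfc.loc[g, patients].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append((g, 0.0))
            continue
        r, _ = pearson_r(x, y)
        out.append((g, float(r * r)))
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


def dose_response_correlation(
    scores: Sequence[SignatureScore], doses: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation of per-sample signature score against dose.

    Replicates enter as separate points; at least 3 distinct dose levels are
    required.
    """
    pairs = [(s.score, float(doses[s.sample])) for s in scores if s.sample in doses]
    if len({d for _, d in pairs}) < 3:
        raise ValueError("need at least 3 distinct dose levels")
    score_vals = [s for s, _ in pairs]
    dose_vals = [d for _, d in pairs]
    return pearson_r(score_vals, dose_vals)


def pca_variance_explained(expr: pd.DataFrame, n_components: int = 2) -> list[float]:
    """Fractions of total expression variance along the leading PCs.

    Genes (rows) are centered; fractions are squared singular values over
    their sum and always total at most 1.
    """
    if expr.shape[1] < 2 or expr.shape[0] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    total = float((s**2).sum())
    if total == 0:
        return [0.0] * n_components
    frac = (s**2) / total
    out = frac[:n_components].tolist()
    out += [0.0] * (n_components - len(out))
    return [float(f) for f in out]


def cohort_auroc(scores: Sequence[SignatureScore], labels: Mapping[str, int]) -> float:
    """AUROC of the signature score for a labeled case/control cohort."""
    pairs = [(s.score, int(labels[s.sample])) for s in scores if s.sample in labels]
    return auroc([s for s, _ in pairs], [l for _, l in pairs])
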