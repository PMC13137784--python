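"""Count containers, TMM normalization, log2-CPM, and group log fold changes.

The trimmed-mean-of-M-values (TMM) procedure estimates, for every sample, a
scaling factor that makes the bulk of genes comparable across libraries: M
(log expression ratio) and A (log mean abundance) values against a reference
sample are doubly trimmed and the surviving M values averaged with
inverse-variance weights.  These are the expression units every downstream
stage of the pipeline consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Metadata columns recognized throughout the pipeline.
METADATA_COLUMNS = ("condition", "time_h", "dose", "pair_id", "label")

__all__ = ["CountMatrix", "NormFactors", "tmm_factors", "log2_cpm", "group_lfc"]


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix plus per-sample metadata.

    ``metadata`` is indexed by sample id and may carry ``condition``,
    ``time_h``, ``dose``, ``pair_id`` and ``label`` columns; missing
    columns are added as NA on construction.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        self.samples = list(map(str, self.samples))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        self.counts = counts.astype(np.int64)
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.samples, name="sample_id"))
        else:
            md = self.metadata.copy()
            md.index = md.index.astype(str)
            missing = set(self.samples) - set(md.index)
            if missing:
                raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
            self.metadata = md.loc[self.samples]
            self.metadata.index.name = "sample_id"
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                self.metadata[col] = pd.NA

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = [self.samples.index(s) for s in samples]
        return CountMatrix(
            genes=self.genes,
            samples=list(samples),
            counts=self.counts[:, idx],
            metadata=self.metadata.loc[list(samples)],
        )


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM factors; geometric mean is constrained to 1."""

    samples: tuple[str, ...]
    factors: np.ndarray

    def __post_init__(self) -> None:
        gm = float(np.exp(np.mean(np.log(self.factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"TMM factors must have geometric mean 1, got {gm}")
        if np.any(self.factors <= 0):
            raise ValueError("TMM factors must be positive")

    def effective_library_sizes(self, cm: CountMatrix) -> np.ndarray:
        if tuple(cm.samples) != self.samples:
            raise ValueError("sample mismatch between counts and factors")
        return cm.library_sizes * self.factors


# TMM trim fractions: 30% of each M tail, 5% of each A tail (the method's
# established defaults).
_TRIM_M = 0.30
_TRIM_A = 0.05


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float
) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    p_o = o / lib_obs
    p_r = r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * _TRIM_M)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * _TRIM_A)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    # Inverse asymptotic binomial variance of M as precision weight.
    var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    w = 1.0 / var[keep2]
    f = float(np.sum(w * m[keep2]) / np.sum(w))
    return float(2.0**f)


def tmm_factors(cm: CountMatrix) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the sample whose 75th-percentile count proportion is
    closest to the mean of those quantiles across samples.  Genes that are
    zero in either member of a comparison pair are excluded; M values are
    trimmed by 30% on each tail and A values by 5%; the factor is the
    precision-weighted mean of the surviving M values.  Factors are rescaled
    to geometric mean 1.
    """
    if len(cm.samples) < 2:
        raise ValueError("TMM requires at least 2 samples")
    counts = cm.counts
    nonzero_any = counts.sum(axis=1) > 0
    if not nonzero_any.all():
        n_dropped = int(np.count_nonzero(~nonzero_any))
        logger.warning("dropping %d all-zero genes before TMM", n_dropped)
        counts = counts[nonzero_any]
    lib = counts.sum(axis=0).astype(float)
    for s, l in zip(cm.samples, lib):
        if l <= 0:
            raise ValueError(f"sample {s!r} has an all-zero library")
    q75 = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(len(cm.samples))
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(samples=tuple(cm.samples), factors=factors)


def log2_cpm(cm: CountMatrix, nf: NormFactors | None = None) -> pd.DataFrame:
    """log2(1 + CPM) on TMM-effective library sizes (gene x sample frame).

    With a prior count of 1 inside the log, a zero count maps to exactly 0.
    """
    if nf is None:
        eff = cm.library_sizes
    else:
        eff = nf.effective_library_sizes(cm)
    cpm = cm.counts / eff[None, :] * 1e6
    return pd.DataFrame(np.log2(1.0 + cpm), index=cm.genes, columns=cm.samples)


def group_lfc(
    expr: pd.DataFrame, group_a: Iterable[str], group_b: Iterable[str]
) -> pd.Series:
    """Per-gene mean(group_a) - mean(group_b) on log2-scale expression.

    Single-sample groups are allowed (per-patient fold changes).
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    unknown = (set(a) | set(b)) - set(expr.columns)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)[:5]}")
    return expr[a].mean(axis=1) - expr[b].mean(axis=1)
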