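"""Synthetic count data with planted ground truth.

Generates the four experimental designs the pipeline consumes — a paired
stimulation time course, a case/control cohort, a paired antagonist
experiment, and a stimulus dose ladder — together with matching gene
annotations, a TF binding-site track, and a protein-interaction network.

The generative model: each gene has a lognormal baseline abundance (CPM
units) and a lognormal negative-binomial dispersion; counts are drawn
gamma-Poisson with lognormal library sizes.  Module genes share a latent
logistic activation curve in time (distinct midpoints per module, sharp by
default so module profiles decorrelate); a "core" subset of each module is
additionally a planted TF's promoter target.  All randomness flows from
``SimConfig.seed`` via independent named streams, so every output is
byte-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .norm import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_timecourse",
    "simulate_cohort",
    "simulate_paired_inhibition",
    "simulate_dose_ladder",
    "simulate_annotations",
]

# Named RNG sub-streams (second word of the seed sequence), so that each
# operation's draws are independent of the others at a fixed seed.
_STREAM_GENES = 1
_STREAM_TIMECOURSE = 2
_STREAM_COHORT = 3
_STREAM_PAIRED = 4
_STREAM_DOSE = 5
_STREAM_ANNOT = 6

#: Fraction of baseline activity removed in responders of the paired
#: antagonist design (treated log2-mean of core genes drops by this times
#: the patient's baseline activation).
INHIBITION_COEFFICIENT = 0.8

#: Decoy TFs (background target rate only) written alongside the planted
#: per-module TFs in the binding-site track.
N_DECOY_TFS = 8


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Lognormal parameters are (mean, sd) of the natural log; ``effect_size``
    and ``noise_sd`` are on the log2 scale.  Defaults describe a
    2,000-gene transcriptome with five 100-gene stimulus-driven modules, an
    eight-point 24 h time course with duplicates, and a moderately deep
    (~2M read) library.
    """

    n_genes: int = 2000
    n_modules: int = 5
    module_size: int = 100
    core_fraction: float = 0.3
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0)
    replicates: int = 2
    baseline_log_mean_sd: tuple[float, float] = (4.5, 1.0)
    dispersion_log_mean_sd: tuple[float, float] = (-4.0, 0.5)
    libsize_log_mean_sd: tuple[float, float] = (14.5, 0.2)
    effect_size: float = 2.0
    noise_sd: float = 0.3
    dose_levels: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
    ppi_p_in: float = 0.3
    ppi_p_out: float = 0.002
    tfbs_target_rate_bg: float = 0.05
    curve_steepness: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "module_size", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_modules < 0:
            raise ValueError("n_modules must be >= 0")
        for name in ("core_fraction", "ppi_p_in", "ppi_p_out", "tfbs_target_rate_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module_size * n_modules must not exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.curve_steepness <= 0:
            raise ValueError("curve_steepness must be positive")
        for name in ("baseline_log_mean_sd", "dispersion_log_mean_sd", "libsize_log_mean_sd"):
            pair = getattr(self, name)
            if len(pair) != 2 or pair[1] < 0:
                raise ValueError(f"{name} must be a (mean, sd) pair with sd >= 0")
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "dose_levels", tuple(float(d) for d in self.dose_levels))


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    module_assignment: dict[str, str | None]
    core_genes: set[str]
    induced_genes: set[str]
    tf_targets: dict[str, set[str]]
    activation_curve: dict[str, np.ndarray]
    module_core: dict[str, set[str]] = field(default_factory=dict)
    responders: set[str] | None = None

    def validate(self) -> None:
        module_genes = {g for g, m in self.module_assignment.items() if m is not None}
        if not self.core_genes <= module_genes:
            raise ValueError("core genes must belong to modules")
        all_targets = set().union(*self.tf_targets.values()) if self.tf_targets else set()
        if not self.core_genes <= (all_targets & self.induced_genes):
            raise ValueError("core genes must be TF-targeted and induced")


@dataclass(frozen=True)
class _GenePool:
    """Gene-level parameters shared by every design at a fixed seed."""

    genes: tuple[str, ...]
    baseline_cpm: np.ndarray  # lognormal abundance, CPM units
    dispersion: np.ndarray
    module_of: np.ndarray  # module index per gene, -1 outside modules
    module_ids: tuple[str, ...]
    module_signs: np.ndarray  # +1 induced / -1 repressed, alternating
    core_mask: np.ndarray  # bool, planted TF-targeted-and-induced subset


def _module_midpoints(cfg: SimConfig) -> np.ndarray:
    """Activation midpoints: midpoints of consecutive timepoint gaps, cycled.

    Interior gaps are preferred when there are enough of them, so no module's
    transition collapses onto the first or last observation.
    """
    t = np.sort(np.unique(np.asarray(cfg.timepoints)))
    n = max(cfg.n_modules, 1)
    if len(t) < 2:
        return np.full(n, float(t[0]))
    mids = 0.5 * (t[:-1] + t[1:])
    if len(mids) >= n + 2:
        mids = mids[1:-1]
    reps = int(np.ceil(n / len(mids)))
    return np.tile(mids, reps)[:n]


def _activation_curves(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-module logistic activation over the timepoint grid, scaled to [0, 1]."""
    t = np.asarray(cfg.timepoints)
    curves: dict[str, np.ndarray] = {}
    for k, mid in enumerate(_module_midpoints(cfg)[: cfg.n_modules]):
        raw = 1.0 / (1.0 + np.exp(-(t - mid) / cfg.curve_steepness))
        span = raw.max() - raw.min()
        curves[f"M{k + 1}"] = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return curves


def _gene_pool(cfg: SimConfig) -> _GenePool:
    rng = np.random.default_rng([cfg.seed, _STREAM_GENES])
    genes = tuple(f"G{i:05d}" for i in range(cfg.n_genes))
    baseline = np.exp(rng.normal(*cfg.baseline_log_mean_sd, size=cfg.n_genes))
    dispersion = np.exp(rng.normal(*cfg.dispersion_log_mean_sd, size=cfg.n_genes))
    module_of = np.full(cfg.n_genes, -1, dtype=int)
    core_mask = np.zeros(cfg.n_genes, dtype=bool)
    perm = rng.permutation(cfg.n_genes)
    n_core = int(round(cfg.core_fraction * cfg.module_size))
    # Modules alternate direction (induced, repressed, ...): stimulus-driven
    # programs include both, and opposite signs keep neighboring activation
    # waves from co-clustering.  Cores are planted in induced modules only,
    # since a core gene must be induced.
    module_signs = np.array([1 if k % 2 == 0 else -1 for k in range(cfg.n_modules)])
    for k in range(cfg.n_modules):
        members = perm[k * cfg.module_size : (k + 1) * cfg.module_size]
        module_of[members] = k
        if module_signs[k] > 0:
            core_mask[rng.choice(members, size=n_core, replace=False)] = True
    module_ids = tuple(f"M{k + 1}" for k in range(cfg.n_modules))
    return _GenePool(
        genes, baseline, dispersion, module_of, module_ids, module_signs, core_mask
    )


def _truth_from_pool(pool: _GenePool, cfg: SimConfig, induced_mask: np.ndarray) -> SimTruth:
    garr = np.asarray(pool.genes)
    assignment = {
        g: (pool.module_ids[m] if m >= 0 else None) for g, m in zip(pool.genes, pool.module_of)
    }
    module_core = {
        mid: set(garr[(pool.module_of == k) & pool.core_mask])
        for k, mid in enumerate(pool.module_ids)
        if pool.module_signs[k] > 0
    }
    tf_targets = {f"TF_{mid}": set(core) for mid, core in module_core.items()}
    return SimTruth(
        module_assignment=assignment,
        core_genes=set(garr[pool.core_mask]),
        induced_genes=set(garr[induced_mask]),
        tf_targets=tf_targets,
        activation_curve=_activation_curves(cfg),
        module_core=module_core,
    )


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw; mean is gene x sample."""
    phi = np.broadcast_to(dispersion[:, None], mean.shape)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _assemble(
    rng: np.random.Generator,
    cfg: SimConfig,
    pool: _GenePool,
    log2_shift: np.ndarray,
    sample_ids: list[str],
    metadata: pd.DataFrame,
) -> CountMatrix:
    """Draw one count matrix given per-(gene, sample) log2 expression shifts."""
    n_s = len(sample_ids)
    libsize = np.exp(rng.normal(*cfg.libsize_log_mean_sd, size=n_s))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_s))
    mean_cpm = pool.baseline_cpm[:, None] * np.exp2(log2_shift + noise)
    mean_counts = mean_cpm * (libsize[None, :] / 1e6)
    counts = _draw_counts(rng, mean_counts, pool.dispersion)
    metadata = metadata.copy()
    metadata["lib_size"] = libsize  # drawn scaling factor, kept as ground truth
    return CountMatrix(
        genes=list(pool.genes), samples=sample_ids, counts=counts, metadata=metadata
    )


def simulate_timecourse(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Paired stimulation time course: a treated and a control arm.

    Module genes follow their module's activation curve scaled by
    ``effect_size`` in the treated arm; the control arm shares all gene-level
    parameters but has zero effect.  Each (timepoint, replicate) carries a
    pair id linking the two arms.
    """
    if len(set(config.timepoints)) < 3:
        raise ValueError("timepoints must contain at least 3 distinct times")
    if config.replicates < 2:
        raise ValueError("replicates must be >= 2")
    pool = _gene_pool(config)
    curves = _activation_curves(config)
    rng = np.random.default_rng([config.seed, _STREAM_TIMECOURSE])

    sample_ids: list[str] = []
    rows = []
    shifts = []
    for condition in ("treated", "control"):
        for ti, t in enumerate(config.timepoints):
            for rep in range(config.replicates):
                sid = f"{condition}_t{t:g}_r{rep + 1}"
                sample_ids.append(sid)
                rows.append(
                    {
                        "sample_id": sid,
                        "condition": condition,
                        "time_h": t,
                        "dose": np.nan,
                        "pair_id": f"t{t:g}_r{rep + 1}",
                        "label": condition,
                    }
                )
                col = np.zeros(config.n_genes)
                if condition == "treated" and config.n_modules > 0:
                    in_module = pool.module_of >= 0
                    curve_now = np.array(
                        [curves[mid][ti] for mid in pool.module_ids]
                    )
                    signed = pool.module_signs * curve_now
                    col[in_module] = (
                        config.effect_size * signed[pool.module_of[in_module]]
                    )
                shifts.append(col)
    metadata = pd.DataFrame(rows).set_index("sample_id")
    cm = _assemble(rng, config, pool, np.column_stack(shifts), sample_ids, metadata)
    truth = _truth_from_pool(pool, config, _induced_mask(pool))
    truth.validate()
    return cm, truth


def _induced_mask(pool: _GenePool) -> np.ndarray:
    """Genes belonging to positively-signed (induced) modules."""
    mask = np.zeros(len(pool.genes), dtype=bool)
    in_module = pool.module_of >= 0
    mask[in_module] = pool.module_signs[pool.module_of[in_module]] > 0
    return mask


def simulate_cohort(
    config: SimConfig, n_case: int, n_control: int, effect: float
) -> tuple[CountMatrix, SimTruth]:
    """Case/control cohort with signature-gene shifts in cases.

    Each core gene receives a case-only log2 shift drawn from
    Normal(effect, effect/4); controls sit at baseline.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("n_case and n_control must both be >= 2")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    pool = _gene_pool(config)
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    delta = np.zeros(config.n_genes)
    if effect > 0:
        delta[pool.core_mask] = rng.normal(effect, effect / 4.0, size=int(pool.core_mask.sum()))
    else:
        rng.normal(0.0, 1.0, size=int(pool.core_mask.sum()))  # keep stream alignment

    sample_ids, rows, shifts = [], [], []
    for i in range(n_control):
        sid = f"HC{i + 1:03d}"
        sample_ids.append(sid)
        rows.append({"sample_id": sid, "condition": "control", "time_h": np.nan,
                     "dose": np.nan, "pair_id": pd.NA, "label": "control"})
        shifts.append(np.zeros(config.n_genes))
    for i in range(n_case):
        sid = f"CASE{i + 1:03d}"
        sample_ids.append(sid)
        rows.append({"sample_id": sid, "condition": "case", "time_h": np.nan,
                     "dose": np.nan, "pair_id": pd.NA, "label": "case"})
        shifts.append(delta)
    metadata = pd.DataFrame(rows).set_index("sample_id")
    cm = _assemble(rng, config, pool, np.column_stack(shifts), sample_ids, metadata)
    truth = _truth_from_pool(pool, config, induced_mask=pool.core_mask.copy())
    truth.validate()
    return cm, truth


def simulate_paired_inhibition(
    config: SimConfig, n_patients: int, responder_fraction: float
) -> tuple[CountMatrix, SimTruth]:
    """Paired vehicle/antagonist design with baseline-dependent suppression.

    Every patient's vehicle sample carries elevated core-gene expression
    (baseline activation ~ effect_size * Uniform(0.3, 1.7)).  In responders
    the treated sample's core-gene log2 mean drops by
    ``INHIBITION_COEFFICIENT`` times that activation, so suppression
    magnitude anticorrelates with baseline activity; non-responders are
    unchanged.  ``truth.responders`` records the planted responder patients.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must lie in [0, 1]")
    pool = _gene_pool(config)
    rng = np.random.default_rng([config.seed, _STREAM_PAIRED])
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    activation = config.effect_size * rng.uniform(0.3, 1.7, size=n_patients)
    n_resp = int(round(responder_fraction * n_patients))
    responder_idx = set(rng.choice(n_patients, size=n_resp, replace=False).tolist())

    sample_ids, rows, shifts = [], [], []
    core = pool.core_mask
    for i, pid in enumerate(patients):
        for arm in ("vehicle", "treated"):
            sid = f"{pid}_{arm}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "condition": arm, "time_h": np.nan,
                         "dose": np.nan, "pair_id": pid, "label": "patient"})
            col = np.zeros(config.n_genes)
            col[core] = activation[i]
            if arm == "treated" and i in responder_idx:
                col[core] -= INHIBITION_COEFFICIENT * activation[i]
            shifts.append(col)
    metadata = pd.DataFrame(rows).set_index("sample_id")
    cm = _assemble(rng, config, pool, np.column_stack(shifts), sample_ids, metadata)
    truth = _truth_from_pool(pool, config, induced_mask=core.copy())
    truth.responders = {patients[i] for i in responder_idx}
    truth.validate()
    return cm, truth


def simulate_dose_ladder(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Stimulus dose ladder: module-gene induction proportional to dose."""
    doses = config.dose_levels
    if len(set(doses)) < 3:
        raise ValueError("dose_levels must contain at least 3 distinct doses")
    pool = _gene_pool(config)
    rng = np.random.default_rng([config.seed, _STREAM_DOSE])
    dmax = max(doses)
    in_module = pool.module_of >= 0

    sample_ids, rows, shifts = [], [], []
    for d in doses:
        for rep in range(config.replicates):
            sid = f"dose{d:g}_r{rep + 1}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "condition": "stimulated", "time_h": np.nan,
                         "dose": d, "pair_id": pd.NA, "label": "stimulated"})
            col = np.zeros(config.n_genes)
            if dmax > 0:
                signs = pool.module_signs[pool.module_of[in_module]]
                col[in_module] = signs * config.effect_size * d / dmax
            shifts.append(col)
    metadata = pd.DataFrame(rows).set_index("sample_id")
    cm = _assemble(rng, config, pool, np.column_stack(shifts), sample_ids, metadata)
    truth = _truth_from_pool(pool, config, induced_mask=_induced_mask(pool))
    truth.validate()
    return cm, truth


# --- annotations: gene coordinates, TF binding sites, PPI network ----------

#: Genes are tiled along one synthetic chromosome at this spacing.
GENE_SPACING = 10_000
_GENE_SPAN = 2_000
_CHROM = "chrS"
_TFBS_HALF_WIDTH = 100


def simulate_annotations(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene annotation, TF binding-site track, and PPI edge list.

    Genes are tiled every 10 kb on one synthetic chromosome with alternating
    strands (minus-strand genes store their 3'-most genomic coordinate as
    the TSS).  Each planted TF receives a 200 bp site centered on the TSS of
    its target genes and of a ``tfbs_target_rate_bg`` fraction of the other
    genes; decoy TFs have background targets only.  PPI edges are Bernoulli
    (``ppi_p_in`` within modules, ``ppi_p_out`` otherwise) with scores in
    [400, 1000) for within-module edges and [150, 400) for the rest.

    Returns ``(annotation, tfbs, ppi)`` data frames with columns
    (gene_id, chrom, strand, tss, span_start, span_end), BED6
    (chrom, start, end, name, score, strand) and (gene_a, gene_b, score).
    """
    genes = sorted(truth.module_assignment)
    if len(genes) != config.n_genes:
        raise ValueError("truth is inconsistent with config (gene count mismatch)")
    rng = np.random.default_rng([config.seed, _STREAM_ANNOT])

    records = []
    tss_of: dict[str, int] = {}
    for i, g in enumerate(genes):
        start = 5_000 + i * GENE_SPACING
        end = start + _GENE_SPAN
        strand = "+" if i % 2 == 0 else "-"
        tss = start if strand == "+" else end
        tss_of[g] = tss
        records.append(
            {"gene_id": g, "chrom": _CHROM, "strand": strand, "tss": tss,
             "span_start": start, "span_end": end}
        )
    annot = pd.DataFrame(records)

    tf_names = sorted(truth.tf_targets) + [f"TF_BG{i + 1}" for i in range(N_DECOY_TFS)]
    bed_rows = []
    gene_arr = np.asarray(genes)
    for tf in tf_names:
        planted = truth.tf_targets.get(tf, set())
        bg_mask = rng.random(len(genes)) < config.tfbs_target_rate_bg
        targets = sorted(planted | (set(gene_arr[bg_mask]) - planted))
        for g in targets:
            tss = tss_of[g]
            bed_rows.append(
                {"chrom": _CHROM, "start": max(0, tss - _TFBS_HALF_WIDTH),
                 "end": tss + _TFBS_HALF_WIDTH, "name": tf, "score": 1000, "strand": "+"}
            )
    tfbs = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    module_idx = np.array(
        [
            -1 if truth.module_assignment[g] is None
            else int(truth.module_assignment[g][1:]) - 1
            for g in genes
        ]
    )
    ia, ib = np.triu_indices(len(genes), k=1)
    same_module = (module_idx[ia] >= 0) & (module_idx[ia] == module_idx[ib])
    u = rng.random(ia.size)
    edge = np.where(same_module, u < config.ppi_p_in, u < config.ppi_p_out)
    scores = np.where(
        same_module, rng.integers(400, 1000, size=ia.size), rng.integers(150, 400, size=ia.size)
    )
    ppi = pd.DataFrame(
        {
            "gene_a": gene_arr[ia[edge]],
            "gene_b": gene_arr[ib[edge]],
            "score": scores[edge],
        }
    )
    return annot, tfbs, ppi
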