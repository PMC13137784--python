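# stingsig

Discovery, scoring and diagnostics of a stimulus-driven gene-module
signature from time-course RNA-seq counts.

Innate-immune pathways such as cytosolic dsDNA sensing (cGAS–STING) leave
a transcriptional fingerprint: after stimulation, waves of co-regulated
genes switch on (or off) with distinct kinetics. A compact *core
signature* — module genes that are both targets of the module's dominant
promoter-binding transcription factor and significantly induced — can then
quantify pathway activity in any sample as a single number, the median
expression of the signature genes. That score supports case/control
diagnosis (AUROC), dose–response readouts, per-sample activation calls,
and stratifying which patients respond to a pathway antagonist.

`stingsig` is for computational biologists who want this derivation as a
reusable, tested pipeline rather than a one-off analysis: it consumes
gene × sample count matrices with sample metadata, a TSS annotation table,
a TF binding-site BED track and a protein-interaction edge list, and it
ships a synthetic-data generator that plants every structure the pipeline
assumes, so each stage is verifiable against ground truth.

## The method

1. **Screen** — per gene, OLS polynomials of degree 1–3 in hours
   post-stimulation; the degree with the best adjusted R² is kept and its
   F-test p-value gated at Benjamini–Hochberg FDR < 10%.
2. **Cluster** — Markov clustering (inflation 2.0) of the graph linking
   genes whose z-scored temporal profiles correlate at Pearson r ≥ 0.7.
3. **Refine** — keep clusters of ≥ 50 genes, then drop genes without a
   within-module protein-interaction edge (score ≥ 400).
4. **Enrich** — per TF, one-sided Fisher test of binding-site targets in
   core (±500 nt) and proximal (±1000 nt) promoter windows of module genes
   against the expressed-gene background, BH-adjusted.
5. **Derive** — core signature = focal-module genes ∩ top-TF targets ∩
   genes induced by the stimulus (negative-binomial exact test after TMM
   normalization, FDR < 0.05, LFC > 0).
6. **Score & evaluate** — per-sample median expression of the core genes;
   AUROC, dose correlation, activation calls (r > 0.6) and antagonist
   responder tests (rank-sum vs background genes, q < 0.05).

TMM normalization, the NB exact test, and all shared statistics (Fisher
2×2, BH, rank-sum, Pearson, AUROC) are implemented from first principles
and pinned to independent oracles in the test suite. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import stingsig as ss

cfg = ss.SimConfig(seed=7)                      # 2,000 genes, 5 planted modules
cm, truth = ss.simulate_timecourse(cfg)         # paired treated/control course
annot, tfbs, ppi = ss.simulate_annotations(cfg, truth)

disc = ss.discover_modules(cm, ppi)
print(f"selected genes: {len(disc.selected)}")
print(f"final modules: {[(m.module_id, len(m.genes)) for m in disc.final_modules]}")

deriv = ss.derive_signature(cm, disc, annot, tfbs)
top = deriv.enrichment["core"][0]
print(f"focal module: {deriv.focal_module.module_id}, top TF: {deriv.top_tf} "
      f"(OR={top.odds_ratio:.2f}, q={top.q:.3g})")
print(f"core signature: {len(deriv.core)} genes")

cohort, _ = ss.simulate_cohort(cfg, n_case=20, n_control=20, effect=2.0)
expr = ss.log2_cpm(cohort, ss.tmm_factors(cohort))
scores = ss.signature_score(expr, deriv.core)
labels = {s: int(cohort.metadata.loc[s, "label"] == "case") for s in cohort.samples}
print(f"cohort AUROC: {ss.cohort_auroc(scores, labels):.3f}")
```

prints

```
selected genes: 547
final modules: [('C1', 100), ('C2', 100), ('C3', 100), ('C4', 100), ('C5', 97)]
focal module: C5, top TF: TF_M1 (OR=7.58, q=4.95e-13)
core signature: 31 genes
cohort AUROC: 1.000
```

The screen keeps 547 of 2,000 genes (the 500 planted module genes plus a
handful of false positives that the size filter later discards); the five
final modules recover the planted partition exactly. The focal (strongest
induced) module's top-enriched TF is the planted one, with a promoter
odds ratio of 7.6, and the derived 31-gene core overlaps the planted
30-gene core at Jaccard ≈ 0.9. On an independent case/control cohort the
signature score separates the groups perfectly.

The same flow is available from the shell —
`stingsig simulate | discover | enrich | derive | score | evaluate` —
each stage reading TSV/BED/GMT files, taking `--seed` and an optional YAML
config (thresholds: `fdr_timecourse`, `fdr_de`, `r_min`, `inflation`,
`min_size`, `activation_r`, `responder_q`), and writing deterministic
outputs: re-running a stage with the same inputs and seed reproduces its
files byte for byte.

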