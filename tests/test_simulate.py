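"""Synthetic-data generator: determinism, planted-truth consistency, and the
statistical structure downstream stages assume."""

import dataclasses

import numpy as np
import pytest

import stingsig as ss
from stingsig.stats import pearson_r


class TestValidation:
    def test_invalid_fields_named(self):
        with pytest.raises(ValueError, match="core_fraction"):
            ss.SimConfig(core_fraction=1.5)
        with pytest.raises(ValueError, match="module_size"):
            ss.SimConfig(n_genes=100, n_modules=3, module_size=50)
        with pytest.raises(ValueError, match="noise_sd"):
            ss.SimConfig(noise_sd=-0.1)

    def test_cohort_preconditions(self):
        cfg = ss.SimConfig(n_genes=200, n_modules=1, module_size=50, seed=0)
        with pytest.raises(ValueError, match="effect"):
            ss.simulate_cohort(cfg, 4, 4, -1.0)
        with pytest.raises(ValueError, match="n_case"):
            ss.simulate_cohort(cfg, 1, 4, 1.0)

    def test_paired_preconditions(self):
        cfg = ss.SimConfig(n_genes=200, n_modules=1, module_size=50, seed=0)
        with pytest.raises(ValueError, match="responder_fraction"):
            ss.simulate_paired_inhibition(cfg, 4, 1.5)


class TestDeterminism:
    @pytest.mark.parametrize("op", ["timecourse", "cohort", "paired", "dose"])
    def test_same_seed_identical_counts(self, op):
        cfg = ss.SimConfig(n_genes=300, n_modules=2, module_size=50, seed=42)
        make = {
            "timecourse": lambda: ss.simulate_timecourse(cfg),
            "cohort": lambda: ss.simulate_cohort(cfg, 4, 4, 1.0),
            "paired": lambda: ss.simulate_paired_inhibition(cfg, 5, 0.5),
            "dose": lambda: ss.simulate_dose_ladder(cfg),
        }[op]
        cm1, t1 = make()
        cm2, t2 = make()
        assert np.array_equal(cm1.counts, cm2.counts)
        assert cm1.samples == cm2.samples
        assert t1.core_genes == t2.core_genes

    def test_same_seed_identical_annotation_payloads(self, small_config, small_timecourse):
        _, truth = small_timecourse
        a1, b1, p1 = ss.simulate_annotations(small_config, truth)
        a2, b2, p2 = ss.simulate_annotations(small_config, truth)
        assert a1.equals(a2) and b1.equals(b2) and p1.equals(p2)


class TestTruthConsistency:
    def test_core_subset_of_module_target_induced(self, small_timecourse):
        _, truth = small_timecourse
        module_genes = {g for g, m in truth.module_assignment.items() if m is not None}
        all_targets = set().union(*truth.tf_targets.values())
        assert truth.core_genes <= module_genes
        assert truth.core_genes <= all_targets & truth.induced_genes

    def test_module_sizes_and_assignment(self, small_config, small_timecourse):
        _, truth = small_timecourse
        counts = {}
        for m in truth.module_assignment.values():
            if m is not None:
                counts[m] = counts.get(m, 0) + 1
        assert all(v == small_config.module_size for v in counts.values())
        assert len(counts) == small_config.n_modules


class TestCountModel:
    def test_marginal_means_match_lognormal_baselines(self):
        """Control-arm count means track the configured abundance model."""
        cfg = ss.SimConfig(seed=3)
        cm, _ = ss.simulate_timecourse(cfg)
        import stingsig.simulate as sim

        pool = sim._gene_pool(cfg)
        controls = [s for s in cm.samples if cm.metadata.loc[s, "condition"] == "control"]
        idx = [cm.samples.index(s) for s in controls]
        counts = cm.counts[:, idx].astype(float)
        lib = cm.metadata.loc[controls, "lib_size"].to_numpy(dtype=float)
        # E[count] = lib/1e6 * baseline * E[2^noise]
        noise_factor = np.exp(0.5 * (cfg.noise_sd * np.log(2.0)) ** 2)
        expected = np.outer(pool.baseline_cpm, lib / 1e6) * noise_factor
        rel_err = abs(counts.mean() - expected.mean()) / expected.mean()
        assert rel_err < 0.05

    def test_module_mean_profiles_follow_planted_curves(self):
        cfg = ss.SimConfig(seed=7, noise_sd=0.05, effect_size=2.0)
        cm, truth = ss.simulate_timecourse(cfg)
        expr = ss.log2_cpm(cm, ss.tmm_factors(cm))
        md = cm.metadata
        treated = [s for s in cm.samples if md.loc[s, "condition"] == "treated"]
        times = md.loc[treated, "time_h"].to_numpy()
        uniq = np.unique(times)
        import stingsig.simulate as sim

        pool = sim._gene_pool(cfg)
        garr = np.asarray(pool.genes)
        for k, mid in enumerate(pool.module_ids):
            members = garr[pool.module_of == k].tolist()
            prof = np.array([
                expr.loc[members, [s for s, t in zip(treated, times) if t == u]]
                .mean(axis=1).mean()
                for u in uniq
            ])
            curve = float(pool.module_signs[k]) * truth.activation_curve[mid]
            r, _ = pearson_r(prof, curve)
            assert r >= 0.9, f"module {mid}: r={r:.3f}"


class TestCohort:
    def test_case_core_genes_shifted(self):
        cfg = ss.SimConfig(n_genes=500, n_modules=2, module_size=80, seed=5)
        cm, truth = ss.simulate_cohort(cfg, 10, 10, 2.0)
        expr = ss.log2_cpm(cm, ss.tmm_factors(cm))
        cases = [s for s in cm.samples if cm.metadata.loc[s, "label"] == "case"]
        controls = [s for s in cm.samples if cm.metadata.loc[s, "label"] == "control"]
        lfc = ss.group_lfc(expr, cases, controls)
        core = sorted(truth.core_genes)
        other = sorted(set(cm.genes) - truth.core_genes)
        assert lfc[core].mean() > 1.0
        assert abs(lfc[other].mean()) < 0.2


class TestPairedInhibition:
    def test_suppression_anticorrelates_with_baseline_activity(self):
        cfg = ss.SimConfig(n_genes=800, n_modules=2, module_size=80,
                           noise_sd=0.1, seed=9)
        cm, truth = ss.simulate_paired_inhibition(cfg, 12, 1.0)
        expr = ss.log2_cpm(cm, ss.tmm_factors(cm))
        md = cm.metadata
        core = sorted(truth.core_genes)
        base_scores, mean_lfcs = [], []
        for pid, grp in md.groupby("pair_id"):
            arms = grp.reset_index().set_index("condition")["sample_id"]
            base_scores.append(expr.loc[core, arms["vehicle"]].median())
            lfc = ss.group_lfc(expr, [arms["treated"]], [arms["vehicle"]])
            mean_lfcs.append(lfc[core].mean())
        r, _ = pearson_r(base_scores, mean_lfcs)
        assert r <= -0.7

    def test_truth_records_planted_responders(self):
        cfg = ss.SimConfig(n_genes=300, n_modules=1, module_size=60, seed=2)
        _, truth = ss.simulate_paired_inhibition(cfg, 8, 0.5)
        assert truth.responders is not None
        assert len(truth.responders) == 4


class TestAnnotations:
    def test_full_within_zero_across_gives_module_cliques(self):
        cfg = ss.SimConfig(n_genes=120, n_modules=2, module_size=30,
                           ppi_p_in=1.0, ppi_p_out=0.0, seed=6)
        cm, truth = ss.simulate_timecourse(cfg)
        _, _, ppi = ss.simulate_annotations(cfg, truth)
        by_module = {}
        for g, m in truth.module_assignment.items():
            if m is not None:
                by_module.setdefault(m, set()).add(g)
        edges = {frozenset((a, b)) for a, b in zip(ppi["gene_a"], ppi["gene_b"])}
        for genes in by_module.values():
            genes = sorted(genes)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    assert frozenset((a, b)) in edges
        n_expected = 2 * (30 * 29 // 2)
        assert len(edges) == n_expected  # no cross edges

    def test_background_target_rate_binomial(self, small_config, small_timecourse,
                                             small_annotations):
        _, truth = small_timecourse
        _, tfbs, _ = small_annotations
        tf = sorted(truth.tf_targets)[0]
        planted = truth.tf_targets[tf]
        n_sites = (tfbs["name"] == tf).sum()
        n_bg = n_sites - len(planted)
        n_candidates = small_config.n_genes - len(planted)
        expect = n_candidates * small_config.tfbs_target_rate_bg
        sd = np.sqrt(expect * (1 - small_config.tfbs_target_rate_bg))
        assert abs(n_bg - expect) <= 3 * sd

    def test_minus_strand_tss_is_three_prime_end(self, small_annotations):
        annot, _, _ = small_annotations
        minus = annot[annot["strand"] == "-"]
        assert (minus["tss"] == minus["span_end"]).all()
        plus = annot[annot["strand"] == "+"]
        assert (plus["tss"] == plus["span_start"]).all()


class TestDoseLadder:
    def test_score_increases_linearly_with_dose(self):
        cfg = dataclasses.replace(ss.SimConfig(seed=4), noise_sd=0.1)
        cm, truth = ss.simulate_dose_ladder(cfg)
        expr = ss.log2_cpm(cm, ss.tmm_factors(cm))
        scores = ss.signature_score(expr, truth.core_genes)
        by_dose = {}
        for s in scores:
            d = float(cm.metadata.loc[s.sample, "dose"])
            by_dose.setdefault(d, []).append(s.score)
        means = [np.mean(by_dose[d]) for d in sorted(by_dose)]
        assert np.all(np.diff(means) > 0)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="dose_levels"):
            ss.simulate_dose_ladder(ss.SimConfig(dose_levels=(0.0, 1.0)))
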