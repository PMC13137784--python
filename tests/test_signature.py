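"""NB differential expression, core derivation, and signature scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import stingsig as ss
from stingsig.discovery import GeneModule
from stingsig.norm import CountMatrix, NormFactors
from stingsig.signature import (
    derive_core_signature,
    estimate_common_dispersion,
    nb_exact_test,
    signature_score,
)


def _cm(counts, samples=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes=[f"g{i}" for i in range(counts.shape[0])],
                       samples=samples, counts=counts)


def _unit_nf(cm):
    return NormFactors(samples=tuple(cm.samples), factors=np.ones(len(cm.samples)))


class TestDispersion:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.poisson(60, size=(200, 8)))
        groups = {"a": cm.samples[:4], "b": cm.samples[4:]}
        assert estimate_common_dispersion(cm, groups) == estimate_common_dispersion(cm, groups)

    def test_poisson_counts_give_near_zero(self):
        ests = []
        for seed in range(5):
            cfg = ss.SimConfig(seed=seed, n_genes=300, n_modules=0, noise_sd=0.0,
                               dispersion_log_mean_sd=(np.log(1e-8), 0.0))
            cm, _ = ss.simulate_cohort(cfg, 4, 4, 0.0)
            groups = {"case": [s for s in cm.samples if s.startswith("CASE")],
                      "control": [s for s in cm.samples if s.startswith("HC")]}
            ests.append(estimate_common_dispersion(cm, groups))
        assert np.median(ests) <= 0.01

    def test_error_shrinks_with_gene_count(self):
        errs = []
        for n_genes in (100, 500, 2000):
            per_seed = []
            for seed in range(3):
                cfg = ss.SimConfig(seed=seed, n_genes=n_genes, n_modules=0,
                                   noise_sd=0.0,
                                   dispersion_log_mean_sd=(np.log(0.2), 0.0))
                cm, _ = ss.simulate_cohort(cfg, 4, 4, 0.0)
                groups = {"case": [s for s in cm.samples if s.startswith("CASE")],
                          "control": [s for s in cm.samples if s.startswith("HC")]}
                per_seed.append(abs(estimate_common_dispersion(cm, groups) - 0.2))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[2]

    def test_small_group_rejected(self):
        cm = _cm(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_common_dispersion(cm, {"a": cm.samples[:1], "b": cm.samples[1:]})


class TestNbExact:
    def test_most_probable_split_has_unit_p(self):
        counts = np.array([[10, 10, 10, 10], [100, 100, 100, 100]])
        cm = _cm(counts)
        res = nb_exact_test(cm, cm.samples[:2], cm.samples[2:], 0.1, nf=_unit_nf(cm))
        assert res[0].p == 1.0
        assert res[0].lfc == pytest.approx(0.0)

    def test_binomial_oracle_at_zero_dispersion(self):
        counts = np.array([[0, 20], [100, 80]])
        cm = _cm(counts)
        res = nb_exact_test(cm, [cm.samples[0]], [cm.samples[1]], 0.0, nf=_unit_nf(cm))
        # libraries are equalized to the geometric mean (100 vs 100), so the
        # split (0, 20) under Binomial(20, 1/2) has two equally extreme outcomes
        assert res[0].p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(2)
        cm = _cm(rng.poisson(40, size=(30, 6)))
        a, b = cm.samples[:3], cm.samples[3:]
        res_ab = nb_exact_test(cm, a, b, 0.1)
        res_ba = nb_exact_test(cm, b, a, 0.1)
        for r1, r2 in zip(res_ab, res_ba):
            assert r1.p == pytest.approx(r2.p, rel=1e-12)
            assert r1.lfc == pytest.approx(-r2.lfc, rel=1e-9, abs=1e-12)

    def test_matches_edger_exact_test(self):
        # Expected p-values from edgeR::exactTest(..., dispersion=0.1,
        # rejection.region="smallp") on this matrix with equal library sizes
        # (filler gene equalizes column sums; norm factors forced to 1).
        y = np.array([[10, 12, 30, 35], [50, 45, 48, 52], [100, 90, 200, 210],
                      [5, 6, 5, 4], [0, 1, 10, 9]])
        filler = y.sum(axis=0).max() + 50 - y.sum(axis=0)
        cm = _cm(np.vstack([y, filler]))
        res = nb_exact_test(cm, cm.samples[2:], cm.samples[:2], 0.1, nf=_unit_nf(cm))
        expected = [0.00860931597097, 0.906508754586, 0.0216770934029,
                    0.856435049042, 0.000555241402205, 0.000341736913193]
        assert [r.p for r in res] == pytest.approx(expected, rel=1e-9)

    def test_betabinom_oracle_on_conditional_law(self):
        """Conditional split law equals a beta-binomial for phi > 0."""
        from stingsig.signature import _split_logpmf

        for total, na, nb, phi in [(50, 2, 2, 0.2), (120, 3, 1, 0.05), (7, 2, 3, 1.0)]:
            mine = np.exp(_split_logpmf(total, na, nb, phi))
            ref = sps.betabinom.pmf(np.arange(total + 1), total, na / phi, nb / phi)
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-15)

    def test_zero_total_genes_excluded(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        cm = _cm(counts)
        res = nb_exact_test(cm, cm.samples[:2], cm.samples[2:], 0.1, nf=_unit_nf(cm))
        assert [r.gene for r in res] == ["g1"]

    def test_null_p_values_roughly_uniform(self):
        """Equal-group NB counts: p-value KS distance from uniform <= 0.05."""
        cfg = ss.SimConfig(seed=8, n_genes=2000, n_modules=0, noise_sd=0.0,
                           dispersion_log_mean_sd=(np.log(0.1), 0.0))
        cm, _ = ss.simulate_cohort(cfg, 4, 4, 0.0)
        cases = [s for s in cm.samples if s.startswith("CASE")]
        controls = [s for s in cm.samples if s.startswith("HC")]
        res = nb_exact_test(cm, cases, controls, 0.1)
        p = np.array([r.p for r in res])
        grid = np.linspace(0, 1, 201)
        ecdf = np.searchsorted(np.sort(p), grid, side="right") / p.size
        ks = np.max(ecdf - grid)  # exceedance only: super-uniform is fine
        assert ks <= 0.05


class TestDeriveCore:
    def _de(self, induced, others):
        from stingsig.signature import DeResult

        res = [DeResult(g, 2.0, 1e-6, 1e-5, 100.0, 25.0) for g in induced]
        res += [DeResult(g, 0.0, 0.9, 0.95, 50.0, 50.0) for g in others]
        return res

    def test_three_way_intersection(self):
        module = GeneModule("M", frozenset({"A", "B", "C"}))
        de = self._de(induced={"B", "C"}, others={"A"})
        core, prov = derive_core_signature(module, {"A", "B"}, de)
        assert core == {"B"}
        assert prov == {"A": "not_induced", "B": "core", "C": "not_tf_target"}

    def test_disjoint_sets_empty_core(self):
        module = GeneModule("M", frozenset({"A", "B"}))
        de = self._de(induced={"B"}, others={"A"})
        core, _ = derive_core_signature(module, {"A"}, de)
        assert core == set()

    def test_fdr_threshold_respected(self):
        from stingsig.signature import DeResult

        module = GeneModule("M", frozenset({"A"}))
        de = [DeResult("A", 1.0, 0.01, 0.06, 10.0, 5.0)]
        core, _ = derive_core_signature(module, {"A"}, de, fdr=0.05)
        assert core == set()


class TestSignatureScore:
    def _expr(self, values, genes=None):
        values = np.atleast_2d(values)
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        return pd.DataFrame(values, index=genes,
                            columns=[f"s{j}" for j in range(values.shape[1])])

    def test_median_of_gene_values(self):
        expr = self._expr(np.array([[2.0], [4.0], [6.0]]))
        scores = signature_score(expr, {"g0", "g1", "g2"})
        assert scores[0].score == 4.0
        assert scores[0].n_genes_used == 3

    def test_even_cardinality_takes_central_mean(self):
        expr = self._expr(np.array([[1.0], [2.0], [5.0], [10.0]]))
        assert signature_score(expr, {"g0", "g1", "g2", "g3"})[0].score == 3.5

    def test_constant_shift_equivariance(self):
        rng = np.random.default_rng(1)
        expr = self._expr(rng.normal(5, 2, size=(9, 4)))
        base = signature_score(expr, set(expr.index))
        shifted = signature_score(expr + 1.25, set(expr.index))
        for s0, s1 in zip(base, shifted):
            assert s1.score == pytest.approx(s0.score + 1.25)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng.normal(size=(11, 3)))
        perm = expr.iloc[rng.permutation(len(expr))]
        for s0, s1 in zip(signature_score(expr, set(expr.index)),
                          signature_score(perm, set(expr.index))):
            assert s0.score == s1.score

    def test_z_mode_drops_zero_variance_genes(self):
        expr = self._expr(np.array([[1.0, 1.0], [0.0, 4.0]]))
        scores = signature_score(expr, {"g0", "g1"}, mode="median_z")
        assert scores[0].n_genes_used == 1
        assert scores[0].score == pytest.approx(-1.0)

    def test_missing_all_genes_rejected(self):
        expr = self._expr(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no signature gene"):
            signature_score(expr, {"absent"})

    def test_cohort_separation_under_planted_effect(self):
        wins = 0
        for seed in range(5):
            cfg = ss.SimConfig(seed=seed, n_genes=500, n_modules=2, module_size=60)
            cm, truth = ss.simulate_cohort(cfg, 8, 8, 2.0)
            expr = ss.log2_cpm(cm, ss.tmm_factors(cm))
            scores = {s.sample: s.score
                      for s in signature_score(expr, truth.core_genes)}
            cases = [scores[s] for s in cm.samples
                     if cm.metadata.loc[s, "label"] == "case"]
            ctrls = [scores[s] for s in cm.samples
                     if cm.metadata.loc[s, "label"] == "control"]
            wins += np.mean(cases) > np.mean(ctrls)
        assert wins == 5


class TestEndToEndDerivation:
    def test_core_recovery_on_default_pipeline(self, default_discovery):
        cfg, cm, truth, annot, tfbs, ppi, disc = default_discovery
        deriv = ss.derive_signature(cm, disc, annot, tfbs)
        best = max(truth.module_core,
                   key=lambda m: len(truth.module_core[m] & deriv.core))
        planted = truth.module_core[best]
        jac = len(deriv.core & planted) / len(deriv.core | planted)
        assert deriv.top_tf == f"TF_{best}"
        assert jac >= 0.8
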