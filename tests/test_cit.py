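"""Causal inference test: component tests, IUT composite, attenuation."""

import numpy as np
import pytest

from methmediate import association, cit
from methmediate import synthetic as syn
from methmediate.synthetic import Effects, PlantedTriad, StudyConfig
from conftest import make_genotypes, make_methylation, make_phenotype


def triad_study(model, seed, strong=False, effects=None):
    eff = effects or syn.default_effects(model, strong=strong)
    cfg = StudyConfig(
        n_snps=1, n_probes=1, planted_triads=[PlantedTriad(0, 0, model, eff)], seed=seed
    )
    g, m, y, _ = syn.generate_study(cfg)
    return g.dosages[:, 0], m.betas[:, 0], y


class TestComposite:
    def test_component_quadruple_upper_bound(self):
        # four component p-values of a representative mediation pair
        p = cit.composite_cit(6.36e-3, 2.34e-3, 4.87e-3, 8.00e-3)
        assert p == pytest.approx(8.00e-3)

    def test_any_one_dominates(self):
        assert cit.composite_cit(1e-8, 1.0, 1e-8, 1e-8) == 1.0

    def test_permutation_invariant(self):
        ps = (0.01, 0.2, 0.03, 0.004)
        ref = cit.composite_cit(*ps)
        for perm in [(1, 0, 3, 2), (3, 2, 1, 0), (2, 3, 0, 1)]:
            assert cit.composite_cit(*(ps[i] for i in perm)) == ref

    def test_missing_component_propagates(self):
        assert np.isnan(cit.composite_cit(0.01, np.nan, 0.02, 0.03))

    def test_upper_bound_property(self, rng):
        for _ in range(50):
            ps = rng.random(4)
            assert cit.composite_cit(*ps) >= ps.max() - 1e-15


class TestComponents:
    def test_constant_g_gives_one(self):
        y = make_phenotype([1] * 10 + [0] * 10)
        m = np.linspace(0.3, 0.6, 20)
        assert cit.test_geno_pheno(np.ones(20), y) == 1.0
        assert cit.test_geno_meth_given_pheno(np.ones(20), m, y) == 1.0
        cfg = cit.CITConfig(n_permutations=100, seed=1)
        assert cit.test_conditional_independence(np.ones(20), y, m, cfg) == 1.0

    def test_constant_m_gives_one(self):
        y = make_phenotype([1] * 10 + [0] * 10)
        g = np.tile([0.0, 1.0], 10)
        assert cit.test_meth_pheno_given_geno(np.full(20, 0.5), y, g) == 1.0
        cfg = cit.CITConfig(n_permutations=100, seed=1)
        assert cit.test_conditional_independence(g, y, np.full(20, 0.5), cfg) == 1.0

    def test_geno_pheno_matches_association_module(self, rng):
        g, _, y = triad_study("independent", 3, strong=False)
        stat, p_assoc, _ = association.additive_logistic_test(g, y)
        assert cit.test_geno_pheno(g, y) == pytest.approx(p_assoc, abs=1e-12)

    def test_m_deterministic_in_y_underflows(self):
        y = make_phenotype([1] * 20 + [0] * 20)
        g = np.tile([0.0, 1.0, 2.0, 1.0], 10)
        m = 0.3 + 0.2 * y.status  # perfect M|Y split
        assert cit.test_meth_pheno_given_geno(m, y, g) < 1e-10

    def test_meth_pheno_reduces_to_marginal_when_g_constant(self, rng):
        y = make_phenotype(rng.integers(0, 2, 40))
        m = np.clip(rng.normal(0.5, 0.05, 40), 0, 1)
        p_const = cit.test_meth_pheno_given_geno(m, y, np.ones(40))
        p_marg = cit.test_meth_pheno_given_geno(m, y, np.zeros(40))
        assert p_const == pytest.approx(p_marg, abs=1e-12)

    def test_geno_meth_given_pheno_power(self):
        hits = 0
        for rep in range(50):
            g, m, y = triad_study(
                "mediation", 1000 + rep, effects=Effects(a=0.05, b=30.0)
            )
            hits += cit.test_geno_meth_given_pheno(g, m, y) < 0.05
        assert hits >= 49  # planted slope 0.05/allele, sd 0.02: near-certain

    def test_geno_meth_given_pheno_rss_matches_oracle(self):
        # 10-row fixture, partial F via explicit normal equations
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1], float)
        yv = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float)
        m = np.array([0.40, 0.45, 0.50, 0.41, 0.46, 0.52, 0.43, 0.47, 0.55, 0.48])
        X_full = np.column_stack([np.ones(10), yv, g])
        X_red = np.column_stack([np.ones(10), yv])
        bf = np.linalg.solve(X_full.T @ X_full, X_full.T @ m)
        br = np.linalg.solve(X_red.T @ X_red, X_red.T @ m)
        rss_f = ((m - X_full @ bf) ** 2).sum()
        rss_r = ((m - X_red @ br) ** 2).sum()
        from scipy.stats import f as f_dist

        F = (rss_r - rss_f) / (rss_f / 7)
        p_oracle = f_dist.sf(F, 1, 7)
        assert cit.test_geno_meth_given_pheno(g, m, yv) == pytest.approx(
            p_oracle, abs=1e-10
        )

    def test_conditional_independence_calibration(self):
        """Mediation: small p4 often; direct path: p4 rarely small."""
        small_under_mediation = 0
        small_under_direct = 0
        reps = 60
        for rep in range(reps):
            g, m, y = triad_study("mediation", 2000 + rep, strong=False)
            cfg = cit.CITConfig(n_permutations=300, seed=rep)
            p4 = cit.test_conditional_independence(g, y, m, cfg)
            small_under_mediation += p4 < 0.05
            g, m, y = triad_study("independent", 3000 + rep, strong=False)
            p4 = cit.test_conditional_independence(g, y, m, cfg)
            small_under_direct += p4 < 0.05
        assert small_under_mediation / reps > 0.5
        assert small_under_direct / reps <= 0.10

    def test_permutation_p_valid_and_reproducible(self):
        g, m, y = triad_study("mediation", 77)
        cfg = cit.CITConfig(n_permutations=200, seed=5)
        p_a = cit.test_conditional_independence(g, y, m, cfg)
        p_b = cit.test_conditional_independence(g, y, m, cfg)
        assert p_a == p_b
        assert p_a >= 1 / 201  # add-one smoothing: never zero


class TestAttenuation:
    def test_constant_m_noop(self):
        y = make_phenotype([1] * 15 + [0] * 15)
        g = np.tile([0.0, 1.0, 2.0], 10)
        bu, ba = cit.attenuation(g, y, np.full(30, 0.5))
        assert bu == pytest.approx(ba, abs=1e-10)

    def test_mediation_attenuates(self):
        shrunk = 0
        for rep in range(60):
            g, m, y = triad_study("mediation", 4000 + rep)
            bu, ba = cit.attenuation(g, y, m)
            shrunk += abs(ba) < abs(bu)
        assert shrunk >= 54  # >= 90% under strong mediation

    def test_unrelated_m_centred_difference(self):
        diffs = []
        for rep in range(60):
            g, m, y = triad_study("independent", 5000 + rep)
            gen = np.random.default_rng(rep)
            m_noise = np.clip(gen.normal(0.5, 0.05, len(y.sample_ids)), 0, 1)
            bu, ba = cit.attenuation(g, y, m_noise)
            diffs.append(ba - bu)
        assert abs(np.mean(diffs)) < 0.05

    def test_linear_scale(self):
        g, m, y = triad_study("mediation", 6000)
        bu, ba = cit.attenuation(g, y, m, outcome_model="linear")
        assert np.isfinite(bu) and np.isfinite(ba)


class TestRunCIT:
    def _study(self, seed):
        cfg = syn.planted_study_config(
            n_mediation=3, n_consequential=3, n_independent=3,
            snps_per_probe=3, seed=seed, n_extra_snps=2, n_extra_probes=1,
        )
        return syn.generate_study(cfg)

    def test_deterministic_given_seed(self):
        g, m, y, truth = self._study(11)
        pairs = list(zip(truth.snp_id, truth.probe_id))[:4]
        cfg = cit.CITConfig(n_permutations=150, seed=42)
        r1 = cit.run_cit(pairs, g, m, y, cfg)
        r2 = cit.run_cit(pairs, g, m, y, cfg)
        assert [(a.p_cit, a.p_independence) for a in r1] == [
            (b.p_cit, b.p_independence) for b in r2
        ]

    def test_verdict_consistent_with_composite(self):
        g, m, y, truth = self._study(13)
        pairs = list(zip(truth.snp_id, truth.probe_id))
        res = cit.run_cit(pairs, g, m, y, cit.CITConfig(n_permutations=150, seed=1))
        for r in res:
            expected = (not np.isnan(r.p_cit)) and r.p_cit < 0.05
            assert (r.verdict == "mediation") == expected
            if not np.isnan(r.p_cit):
                assert r.p_cit == pytest.approx(
                    max(
                        r.p_geno_pheno,
                        r.p_meth_pheno_given_geno,
                        r.p_geno_meth_given_pheno,
                        r.p_independence,
                    )
                )

    def test_planted_mediation_dominates_verdicts(self):
        g, m, y, truth = self._study(17)
        pairs = list(zip(truth.snp_id, truth.probe_id))
        res = cit.run_cit(pairs, g, m, y, cit.CITConfig(n_permutations=400, seed=2))
        med_truth = set(
            zip(truth[truth.model == "mediation"].snp_id,
                truth[truth.model == "mediation"].probe_id)
        )
        verdicts = {(r.snp_id, r.probe_id) for r in res if r.verdict == "mediation"}
        assert len(verdicts & med_truth) >= 2
        assert len(verdicts - med_truth) <= 1

    def test_empty_pairs(self):
        g, m, y, _ = self._study(19)
        assert cit.run_cit([], g, m, y) == []
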