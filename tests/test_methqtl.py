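"""methQTL mapping: additive linear fits, cis/trans windows, global BH."""

import numpy as np
import pytest
from scipy.stats import kstest

from methmediate import methqtl
from methmediate.datasets import ProbeRecord, SNPRecord
from conftest import make_genotypes, make_methylation
from _oracles import ols_simple_oracle


class TestLinearFit:
    def test_matches_normal_equations_on_12_pairs(self):
        dos = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 0, 1], float)
        bet = np.array(
            [0.41, 0.44, 0.39, 0.47, 0.50, 0.46, 0.49, 0.55, 0.52, 0.56, 0.42, 0.48]
        )
        slope, t, p, n = methqtl.linear_additive_fit(dos, bet)
        o_slope, o_se, o_t, o_p = ols_simple_oracle(dos, bet)
        assert n == 12
        assert slope == pytest.approx(o_slope, abs=1e-10)
        assert t == pytest.approx(o_t, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_matches_oracle_random_fixtures(self, rng):
        for _ in range(20):
            n = rng.integers(5, 30)
            dos = rng.binomial(2, 0.4, n).astype(float)
            if np.ptp(dos) == 0:
                continue
            bet = np.clip(0.5 + 0.05 * dos + rng.normal(0, 0.03, n), 0, 1)
            slope, t, p, _ = methqtl.linear_additive_fit(dos, bet)
            o_slope, _, o_t, o_p = ols_simple_oracle(dos, bet)
            assert slope == pytest.approx(o_slope, abs=1e-10)
            assert t == pytest.approx(o_t, abs=1e-9)
            assert p == pytest.approx(o_p, abs=1e-10)

    def test_perfect_fit_recovers_generating_slope(self):
        dos = np.array([0, 1, 2, 0, 1, 2], float)
        bet = 0.4 + 0.04 * dos
        slope, t, p, _ = methqtl.linear_additive_fit(dos, bet)
        assert slope == pytest.approx(0.04, abs=1e-12)
        assert p <= 1e-12  # underflows toward zero

    def test_constant_dosage_untestable(self):
        slope, t, p, n = methqtl.linear_additive_fit(np.ones(10), np.linspace(0.2, 0.4, 10))
        assert np.isnan(p) and np.isnan(slope)

    def test_constant_beta_slope_zero(self):
        dos = np.array([0, 1, 2, 1, 0], float)
        slope, t, p, _ = methqtl.linear_additive_fit(dos, np.full(5, 0.5))
        assert slope == 0.0 and np.isnan(p)

    def test_pairwise_complete_cases(self):
        dos = np.array([0, 1, 2, np.nan, 1, 2], float)
        bet = np.array([0.4, 0.45, 0.5, 0.6, np.nan, 0.49])
        *_, n = methqtl.linear_additive_fit(dos, bet)
        assert n == 4

    def test_null_p_uniformity(self):
        gen = np.random.default_rng(5150)
        ps = []
        for _ in range(5000):
            dos = gen.binomial(2, 0.3, 88).astype(float)
            bet = gen.normal(0.5, 0.05, 88)
            if np.ptp(dos) == 0:
                continue
            *_, p, _ = methqtl.linear_additive_fit(dos, np.clip(bet, 0, 1))
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestClassifyRelation:
    probe = ProbeRecord("cg1", "chr2", 1_000_000, "", "IGR")

    def test_inside_window_cis(self):
        snp = SNPRecord("rs1", "chr2", 1_000_000 + 499_999, "A", "G")
        assert methqtl.classify_relation(snp, self.probe) == ("cis", 499_999.0)

    def test_exact_window_is_trans(self):
        snp = SNPRecord("rs1", "chr2", 1_000_000 + 500_000, "A", "G")
        rel, d = methqtl.classify_relation(snp, self.probe)
        assert rel == "trans" and d == 500_000.0

    def test_cross_chromosome_trans_no_distance(self):
        snp = SNPRecord("rs1", "chr17", 1_000_000, "A", "G")
        rel, d = methqtl.classify_relation(snp, self.probe)
        assert rel == "trans" and np.isnan(d)

    def test_symmetric_in_position(self):
        up = SNPRecord("rs1", "chr2", 900_000, "A", "G")
        down = SNPRecord("rs2", "chr2", 1_100_000, "A", "G")
        assert methqtl.classify_relation(up, self.probe) == methqtl.classify_relation(
            down, self.probe
        )


class TestMapMethQTL:
    def _pair_study(self, rng, n=88, slope=0.04, noise=0.02):
        dos = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        bet = np.clip(0.5 + slope * dos + rng.normal(0, noise, size=(n, 1)), 0, 1)
        return make_genotypes(dos), make_methylation(bet)

    def test_planted_pair_recovered(self, rng):
        g, m = self._pair_study(rng)
        res = methqtl.map_methqtl(g, m, ["cg0"], ["rs0"])
        assert len(res) == 1
        assert res[0].fdr < 0.05
        assert res[0].slope == pytest.approx(0.04, abs=0.02)

    def test_vectorised_path_equals_scalar_fit(self, rng):
        dos = rng.binomial(2, 0.3, size=(50, 8)).astype(float)
        dos[rng.random(dos.shape) < 0.05] = np.nan
        bet = np.clip(rng.normal(0.5, 0.05, size=(50, 4)), 0, 1)
        bet[rng.random(bet.shape) < 0.05] = np.nan
        g, m = make_genotypes(dos), make_methylation(bet)
        res = methqtl.map_methqtl(
            g, m, [p.probe_id for p in m.probes], [s.snp_id for s in g.snps]
        )
        sidx, pidx = g.snp_index(), m.probe_index()
        for r in res:
            slope, t, p, n = methqtl.linear_additive_fit(
                g.dosages[:, sidx[r.snp_id]], m.betas[:, pidx[r.probe_id]]
            )
            assert n == r.n_used
            if np.isnan(p):
                assert np.isnan(r.p_value)
            else:
                assert r.p_value == pytest.approx(p, rel=1e-9)
                assert r.slope == pytest.approx(slope, rel=1e-9)

    def test_bh_excludes_untestable_pairs(self, rng):
        dos = rng.binomial(2, 0.3, size=(30, 2)).astype(float)
        dos[:, 1] = 1.0  # constant: untestable
        bet = np.clip(rng.normal(0.5, 0.05, size=(30, 1)), 0, 1)
        g, m = make_genotypes(dos), make_methylation(bet)
        res = methqtl.map_methqtl(g, m, ["cg0"], ["rs0", "rs1"])
        testable = [r for r in res if r.testable]
        assert len(testable) == 1
        # single testable pair: FDR equals its raw p
        assert testable[0].fdr == pytest.approx(testable[0].p_value)

    def test_unique_counts_bookkeeping(self):
        rows = [
            methqtl.MethQTLResult(f"rs{i}", f"cg{i % 3}", 0, 0, 0.01, 0.01, 88, "cis", 1.0)
            for i in range(24)
        ]
        n_cpg, n_snp = methqtl.unique_counts(rows)
        assert (n_cpg, n_snp) == (3, 24)

    def test_order_invariance(self, rng):
        dos = rng.binomial(2, 0.3, size=(40, 5)).astype(float)
        bet = np.clip(rng.normal(0.5, 0.05, size=(40, 3)), 0, 1)
        g, m = make_genotypes(dos), make_methylation(bet)
        probes = [p.probe_id for p in m.probes]
        snps = [s.snp_id for s in g.snps]
        r1 = methqtl.map_methqtl(g, m, probes, snps)
        r2 = methqtl.map_methqtl(g, m, probes[::-1], snps[::-1])
        key = lambda r: (r.snp_id, r.probe_id)
        for a, b in zip(sorted(r1, key=key), sorted(r2, key=key)):
            assert a.p_value == pytest.approx(b.p_value, rel=1e-12) or (
                np.isnan(a.p_value) and np.isnan(b.p_value)
            )
            assert a.fdr == pytest.approx(b.fdr, rel=1e-12) or np.isnan(a.fdr)

    def test_m_value_scale_runs(self, rng):
        g, m = self._pair_study(rng)
        cfg = methqtl.MethQTLConfig(value_scale="m_value")
        res = methqtl.map_methqtl(g, m, ["cg0"], ["rs0"], cfg)
        assert res[0].fdr < 0.05

    def test_empty_product_raises(self, rng):
        g, m = self._pair_study(rng)
        with pytest.raises(ValueError):
            methqtl.map_methqtl(g, m, [], ["rs0"])
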