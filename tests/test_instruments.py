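"""Instrument construction: clumping, exclusion, refinement, Steiger, strength."""

import numpy as np
import pytest

from epimr import (
    InstrumentError,
    LDInfo,
    apply_exclusion_list,
    dual_marker_refine,
    instrument_strength,
    select_and_clump,
    steiger_filter,
)
from epimr.gwas_io import harmonized_from_arrays
from epimr.instruments import steiger_z, variance_explained
from epimr.simulate import SimulationConfig, simulate_two_sample

from conftest import make_table


def snp(sid, chrom, pos, p, beta=0.1):
    return {"snp": sid, "chrom": str(chrom), "pos": pos, "ea": "A", "oa": "G",
            "beta": beta, "se": 0.01, "p": p, "eaf": 0.3}


class TestClumping:
    def test_correlated_nearby_pair_keeps_best_pvalue(self):
        t = make_table([snp("rs1", 1, 100_000, 1e-10), snp("rs2", 1, 200_000, 1e-9)])
        ld = LDInfo()
        ld.set_r2("rs1", "rs2", 0.5)
        kept = select_and_clump(t, ld)
        assert list(kept.snps) == ["rs1"]

    def test_distant_pair_both_kept_despite_high_ld(self):
        t = make_table([snp("rs1", 1, 100_000, 1e-10), snp("rs2", 1, 700_000, 1e-9)])
        ld = LDInfo()
        ld.set_r2("rs1", "rs2", 0.9)
        kept = select_and_clump(t, ld)  # 600 kb apart: outside the window
        assert sorted(kept.snps) == ["rs1", "rs2"]

    def test_nonsignificant_snps_never_enter(self):
        t = make_table([snp("rs1", 1, 100_000, 1e-10), snp("rs2", 1, 900_000, 1e-5)])
        kept = select_and_clump(t, LDInfo())
        assert list(kept.snps) == ["rs1"]

    def test_empty_instrument_when_nothing_significant(self):
        t = make_table([snp("rs1", 1, 100_000, 1e-3)])
        kept = select_and_clump(t, LDInfo())
        assert len(kept) == 0

    def test_five_snp_chain_matches_bruteforce_greedy(self):
        """Mixed distances and r2 values against an independent greedy
        re-implementation."""
        snps = [snp("rs1", 1, 100_000, 1e-12), snp("rs2", 1, 350_000, 1e-11),
                snp("rs3", 1, 550_000, 1e-10), snp("rs4", 1, 620_000, 1e-9),
                snp("rs5", 2, 100_000, 1e-8 / 2)]
        t = make_table(snps)
        ld = LDInfo()
        ld.set_r2("rs1", "rs2", 0.3)
        ld.set_r2("rs2", "rs3", 0.15)
        ld.set_r2("rs3", "rs4", 0.9)
        ld.set_r2("rs1", "rs3", 0.05)

        # oracle: plain-python greedy over (p-sorted) list
        items = sorted([(s["p"], s["snp"], s["chrom"], s["pos"]) for s in snps])
        expected, pool = [], items[:]
        while pool:
            p, sid, ch, pos = pool.pop(0)
            expected.append(sid)
            pool = [x for x in pool
                    if not (x[2] == ch and abs(x[3] - pos) <= 500_000
                            and ld.r2(x[1], sid) >= 0.1)]
        kept = select_and_clump(t, ld)
        assert sorted(kept.snps) == sorted(expected)

    def test_row_order_invariance(self, rng):
        snps = [snp(f"rs{i}", 1 + i % 2, 50_000 * i, 10.0 ** -rng.integers(9, 15),
                    beta=0.05 + 0.01 * i) for i in range(12)]
        ld = LDInfo()
        for i in range(11):
            ld.set_r2(f"rs{i}", f"rs{i + 1}", float(rng.uniform(0, 1)))
        t1 = make_table(snps)
        t2 = make_table(list(reversed(snps)))
        k1 = select_and_clump(t1, ld)
        k2 = select_and_clump(t2, ld)
        assert sorted(k1.snps) == sorted(k2.snps)


class TestExclusion:
    def test_listed_snp_removed(self):
        t = make_table([snp("rs1598856", 1, 100_000, 1e-10), snp("rs2", 2, 100_000, 1e-10)])
        out = apply_exclusion_list(t, {"rs1598856"})
        assert list(out.snps) == ["rs2"]

    def test_empty_list_noop(self):
        t = make_table([snp("rs1", 1, 100_000, 1e-10)])
        out = apply_exclusion_list(t, set())
        assert out.df.equals(t.df)

    def test_ld_proxy_threshold_semantics(self):
        t = make_table([snp("rs_a", 1, 100_000, 1e-10), snp("rs_b", 1, 200_000, 1e-10)])
        ld = LDInfo()
        ld.set_r2("rs_a", "rs_x", 0.85)
        ld.set_r2("rs_b", "rs_x", 0.75)
        out = apply_exclusion_list(t, {"rs_x"}, ld)
        assert list(out.snps) == ["rs_b"]  # 0.85 > 0.8 removed; 0.75 retained

    def test_commutes_with_clumping_for_disjoint_criteria(self):
        snps = [snp(f"rs{i}", 1, 200_000 * i, 1e-10 * (i + 1)) for i in range(6)]
        t = make_table(snps)
        ld = LDInfo()
        ld.set_r2("rs0", "rs1", 0.5)
        excl = {"rs4"}
        a = apply_exclusion_list(select_and_clump(t, ld), excl, ld)
        b = select_and_clump(apply_exclusion_list(t, excl, ld), ld)
        assert sorted(a.snps) == sorted(b.snps)


class TestDualMarkerRefine:
    def secondary(self, entries):
        return make_table([
            {"snp": s, "ea": "A", "oa": "G", "beta": b, "se": 0.01, "p": p}
            for s, b, p in entries], "secondary")

    def test_bonferroni_and_direction(self):
        prim = make_table([snp("rs1", 1, 1, 1e-10, beta=0.1),
                           snp("rs2", 1, 2, 1e-10, beta=0.1),
                           snp("rs3", 1, 3, 1e-10, beta=0.1)])
        sec = self.secondary([("rs1", 0.05, 1e-6),   # significant, concordant
                              ("rs2", 0.05, 0.01),   # not significant (0.01 > 0.05/256)
                              ("rs3", -0.05, 1e-6)])  # significant but discordant
        out = dual_marker_refine(prim, sec, n_index=256)
        assert list(out.snps) == ["rs1"]

    def test_inverse_marker_expects_discordance(self):
        prim = make_table([snp("rs1", 1, 1, 1e-10, beta=0.1)])
        sec = self.secondary([("rs1", -0.05, 1e-6)])
        out = dual_marker_refine(prim, sec, n_index=256, expected_sign="discordant")
        assert list(out.snps) == ["rs1"]

    def test_missing_secondary_data_removed(self):
        prim = make_table([snp("rs1", 1, 1, 1e-10), snp("rs2", 1, 2, 1e-10)])
        sec = self.secondary([("rs1", 0.05, 1e-6)])
        out = dual_marker_refine(prim, sec, n_index=10)
        assert list(out.snps) == ["rs1"]

    def test_ten_snp_hand_enumeration(self):
        """Retention over a 10-SNP table matches an explicit enumeration."""
        n_index = 100
        betas_p = [(0.1, 1e-6), (0.1, 1e-3), (-0.1, 1e-6), (0.1, 4e-4),
                   (0.1, 6e-4), (-0.1, 0.2), (0.1, 1e-8), (0.1, 0.04),
                   (-0.1, 1e-9), (0.1, 2e-4)]
        prim = make_table([snp(f"rs{i}", 1, i, 1e-10, beta=0.1) for i in range(10)])
        sec = self.secondary([(f"rs{i}", b, p) for i, (b, p) in enumerate(betas_p)])
        # by hand: p < 5e-4 and beta > 0 -> rs0, rs3, rs6, rs9
        out = dual_marker_refine(prim, sec, n_index=n_index)
        assert list(out.snps) == ["rs0", "rs3", "rs6", "rs9"]

    def test_nonpositive_n_index_rejected(self):
        prim = make_table([snp("rs1", 1, 1, 1e-10)])
        with pytest.raises(InstrumentError):
            dual_marker_refine(prim, prim, n_index=0)


class TestSteiger:
    def test_equal_r2_is_dropped_with_p_one(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.1], [0.01],
                                   n_exp=10_000, n_out=10_000)
        kept, res = steiger_filter(h)
        assert kept.n_retained == 0
        assert res.df.iloc[0]["steiger_z"] == pytest.approx(0.0)
        assert res.df.iloc[0]["steiger_p"] == pytest.approx(1.0)

    def test_zero_outcome_beta_keeps_direction(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.0], [0.01],
                                   n_exp=10_000, n_out=10_000)
        kept, res = steiger_filter(h)
        assert res.df.iloc[0]["r2_out"] == 0.0
        assert kept.n_retained == 1

    def test_z_matches_direct_fisher_formula(self):
        """3-SNP set: z values against a from-scratch evaluation."""
        g = np.array([0.10, 0.07, 0.05])
        seg = np.array([0.010, 0.012, 0.011])
        G = np.array([0.03, 0.02, 0.04])
        seG = np.array([0.015, 0.014, 0.013])
        n_exp, n_out = 25_000, 40_000
        h = harmonized_from_arrays(g, seg, G, seG, n_exp=n_exp, n_out=n_out)
        _, res = steiger_filter(h)
        for j in range(3):
            te, to = g[j] / seg[j], G[j] / seG[j]
            r2e = te**2 / (te**2 + n_exp - 2)
            r2o = to**2 / (to**2 + n_out - 2)
            z = (np.arctanh(np.sqrt(r2e)) - np.arctanh(np.sqrt(r2o))) / np.sqrt(
                1 / (n_exp - 3) + 1 / (n_out - 3))
            assert res.df.iloc[j]["steiger_z"] == pytest.approx(z, rel=1e-12)

    def test_small_sample_size_rejected(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.0], [0.01], n_exp=3, n_out=100)
        with pytest.raises(InstrumentError):
            steiger_filter(h)

    def test_retains_valid_snps_under_true_forward_model(self):
        """Exposure-generated data, instrument selected at genome-wide
        significance: > 95% of instrument SNPs keep the correct direction."""
        from epimr import harmonize

        total = kept = 0
        for seed in range(20):
            cfg = SimulationConfig(J=30, beta_true=0.1, n_exp=50_000, n_out=50_000)
            exp, out, _ = simulate_two_sample(cfg, seed=seed)
            instrument = select_and_clump(exp, LDInfo())
            if len(instrument) == 0:
                continue
            h = harmonize(instrument, out)
            filtered, _ = steiger_filter(h)
            total += h.n_retained
            kept += filtered.n_retained
        assert total > 100  # enough instrument SNPs to make the rate meaningful
        assert kept / total > 0.95


class TestStrength:
    def test_single_snp_f_statistic(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.02], [0.01],
                                   n_exp=10_000, n_out=10_000)
        s = instrument_strength(h)
        assert s.f_per_snp[0] == pytest.approx(100.0)
        assert s.i2_gx is None

    def test_identical_effects_zero_heterogeneity(self):
        h = harmonized_from_arrays([0.1] * 4, [0.01] * 4, [0.02] * 4, [0.01] * 4,
                                   n_exp=10_000, n_out=10_000)
        s = instrument_strength(h)
        assert s.q_gx == pytest.approx(0.0)
        assert s.i2_gx == 0.0

    def test_q_and_i2_match_direct_summation(self):
        g = np.array([0.10, 0.12, 0.05, 0.08])
        seg = np.array([0.01, 0.02, 0.01, 0.015])
        h = harmonized_from_arrays(g, seg, 0.3 * g, np.full(4, 0.01),
                                   n_exp=30_000, n_out=30_000)
        s = instrument_strength(h)
        v = 1 / seg**2
        gbar = np.sum(v * g) / np.sum(v)
        q = np.sum(v * (g - gbar) ** 2)
        assert s.q_gx == pytest.approx(q, rel=1e-12)
        assert s.i2_gx == pytest.approx(max(0, (q - 3) / q), rel=1e-12)
        r2 = variance_explained(g, seg, 30_000).sum()
        assert s.r2_instrument == pytest.approx(r2, rel=1e-12)


def test_steiger_z_antisymmetric():
    assert steiger_z(0.01, 0.003, 1000, 2000) == pytest.approx(
        -steiger_z(0.003, 0.01, 2000, 1000))
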