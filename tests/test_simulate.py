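import numpy as np
import pandas as pd
import pytest

from xtrait.exceptions import ConfigurationError, DomainError
from xtrait import simulate
from xtrait.simulate import (make_gene_map, make_panel,
                             simulate_mr_instruments, simulate_pair,
                             simulate_region_scenario)


class TestMakePanel:
    def test_zero_rho_gives_identity_blocks(self):
        panel = make_panel(n_blocks=3, block_size=10, ar1_rho=0.0, seed=0)
        for R in panel.ld:
            assert np.array_equal(R, np.eye(10))

    def test_adjacent_correlation_is_rho_exactly(self):
        panel = make_panel(n_blocks=2, block_size=10, ar1_rho=0.9, seed=0)
        assert panel.ld[0][0, 1] == pytest.approx(0.9)

    def test_same_seed_reproduces_panel(self):
        a = make_panel(n_blocks=4, block_size=20, seed=3)
        b = make_panel(n_blocks=4, block_size=20, seed=3)
        pd.testing.assert_frame_equal(a.snps, b.snps)
        for Ra, Rb in zip(a.ld, b.ld):
            assert np.array_equal(Ra, Rb)

    def test_invalid_eaf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            make_panel(eaf_range=(0.0, 0.5))

    def test_r2_lookup(self):
        panel = make_panel(n_blocks=2, block_size=5, ar1_rho=0.5, seed=0)
        s = panel.snps["snp_id"]
        assert panel.r2(s[0], s[1]) == pytest.approx(0.25)
        assert panel.r2(s[0], s[5]) == 0.0  # across blocks
        assert np.isnan(panel.r2(s[0], "missing"))


class TestSimulatePair:
    def test_null_mean_chi2_calibration(self, acc_panel):
        g1, g2, _ = simulate_pair(acc_panel, 0.0, 0.0, 0.0, n_s=0, seed=9)
        assert np.mean(g1.df["z"] ** 2) == pytest.approx(1.0, abs=0.03)
        assert np.mean(g2.df["z"] ** 2) == pytest.approx(1.0, abs=0.03)

    def test_full_overlap_correlates_noise(self, nold_panel):
        # h2=0, complete overlap: corr(z1, z2) equals the phenotypic
        # correlation at LD-independent SNPs
        g1, g2, _ = simulate_pair(nold_panel, 0.0, 0.0, 0.0,
                                  n1=10_000, n2=10_000, n_s=10_000,
                                  rho_pheno=0.5, seed=10)
        r = np.corrcoef(g1.df["z"], g2.df["z"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_perfect_rg_duplicates_effects(self, small_panel):
        _, _, truth = simulate_pair(small_panel, 0.3, 0.3, 1.0, seed=2)
        assert np.allclose(truth.gamma1, truth.gamma2)

    def test_invalid_rg_rejected(self, small_panel):
        with pytest.raises(DomainError):
            simulate_pair(small_panel, 0.3, 0.3, 1.5)

    def test_overlap_bounded_by_sample_sizes(self, small_panel):
        with pytest.raises(DomainError):
            simulate_pair(small_panel, 0.3, 0.3, 0.5, n1=100, n2=100, n_s=200)

    def test_seed_determinism(self, small_panel):
        a = simulate_pair(small_panel, 0.4, 0.2, 0.3, seed=7)[0]
        b = simulate_pair(small_panel, 0.4, 0.2, 0.3, seed=7)[0]
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_ld_score_regression_slope_connection(self, acc_panel):
        # cross products regressed on LD scores recover the genetic
        # covariance slope the estimator assumes
        from xtrait import ldsc
        g1, g2, _ = simulate_pair(acc_panel, 0.4, 0.4, 0.5, seed=21)
        ld = ldsc.compute_ld_scores(acc_panel)
        est = ldsc.estimate_rg(g1, g2, ld, n_blocks_jk=100,
                               constrain_gcov_int=True)
        rho_true = 0.5 * 0.4
        assert est.rho_g == pytest.approx(rho_true, abs=0.06)


class TestRegionScenario:
    def test_null_has_no_planted_variant(self, small_panel):
        z1, z2, info = simulate_region_scenario(small_panel, 0, "null", seed=0)
        assert info["causal1"] is None and info["causal2"] is None

    def test_shared_peaks_coincide_at_strong_effect(self, small_panel):
        hits = 0
        for s in range(20):
            z1, z2, info = simulate_region_scenario(
                small_panel, s % 10, "shared", effect_size=12.0, seed=s)
            hits += np.argmax(np.abs(z1)) == np.argmax(np.abs(z2))
        assert hits >= 18

    def test_distinct_peaks_differ_without_ld(self, nold_panel):
        z1, z2, info = simulate_region_scenario(
            nold_panel, 0, "distinct", effect_size=12.0, seed=1)
        assert np.argmax(np.abs(z1)) != np.argmax(np.abs(z2))
        assert info["causal1"] != info["causal2"]

    def test_unknown_scenario_rejected(self, small_panel):
        with pytest.raises(ConfigurationError):
            simulate_region_scenario(small_panel, 0, "bogus")


class TestGeneMapAndInstruments:
    def test_gene_count_and_no_overlap(self, small_panel):
        gm = make_gene_map(small_panel, genes_per_block=2, gene_length=20_000)
        assert len(gm) == 2 * small_panel.n_regions
        for _, sub in gm.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:]
                    > sub["end"].to_numpy()[:-1]).all()

    def test_gene_too_long_rejected(self, small_panel):
        with pytest.raises(ConfigurationError):
            make_gene_map(small_panel, genes_per_block=2, gene_length=10**9)

    def test_noise_free_instruments_have_exact_ratio(self):
        df = simulate_mr_instruments(10, 0.3, se_x=1e-15, se_y=1e-15, seed=0)
        # SEs stored as given; ratios exact up to float noise
        assert np.allclose(df["by"] / df["bx"], 0.3, atol=1e-9)

    def test_directional_pleiotropy_marked(self):
        df = simulate_mr_instruments(10, 0.0, pleiotropy_frac=0.3,
                                     pleiotropy_mean=0.1, seed=1)
        assert df["pleiotropic"].sum() == 3

    def test_instrument_determinism(self):
        a = simulate_mr_instruments(15, 0.2, seed=4)
        b = simulate_mr_instruments(15, 0.2, seed=4)
        pd.testing.assert_frame_equal(a, b)


def test_lcv_pair_architectures_differ():
    g1, g2 = simulate.simulate_lcv_pair(M=6000, mode="causal", seed=0)
    assert len(g1) == 6000 and len(g2) == 6000
    h1, h2 = simulate.simulate_lcv_pair(M=6000, mode="shared", seed=0)
    r_c = np.corrcoef(g1.df["z"], g2.df["z"])[0, 1]
    r_s = np.corrcoef(h1.df["z"], h2.df["z"])[0, 1]
    assert r_c > 0.1 and r_s > 0.1  # both genetically correlated
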