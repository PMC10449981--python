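import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xtrait import genes, simulate
from xtrait.exceptions import DomainError, EstimationError
from xtrait.sumstats import from_frame

from conftest import canonical_frame


class TestAssignment:
    def _setup(self):
        df = canonical_frame(3)
        df["pos"] = [95_000, 115_000, 140_000]
        g = from_frame("t", df)
        gene_map = pd.DataFrame({"gene_id": ["G1"], "chrom": [1],
                                 "start": [100_000], "end": [120_000]})
        return g, gene_map

    def test_within_pad_assigned(self):
        g, gm = self._setup()
        out = genes.assign_snps_to_genes(g, gm, pad=10_000)
        assert len(out["G1"]) == 2  # 5 kb upstream + inside

    def test_beyond_pad_not_assigned(self):
        g, gm = self._setup()
        gm2 = gm.assign(start=110_000)  # first SNP now 15 kb upstream
        out = genes.assign_snps_to_genes(g, gm2, pad=10_000)
        ids = g.df["snp_id"].to_numpy()[out["G1"]]
        assert g.df.set_index("snp_id").loc[ids, "pos"].min() == 115_000

    def test_overlapping_padded_genes_share_snp(self):
        g, gm = self._setup()
        gm2 = pd.concat([gm, pd.DataFrame({
            "gene_id": ["G2"], "chrom": [1], "start": [110_000],
            "end": [130_000]})], ignore_index=True)
        out = genes.assign_snps_to_genes(g, gm2, pad=10_000)
        shared = set(out["G1"]) & set(out["G2"])
        assert shared  # the 115 kb SNP sits in both padded intervals


class TestEffectiveNumberSnps:
    def test_identity(self):
        assert genes.effective_number_snps(np.eye(7)) == pytest.approx(7.0)

    def test_perfect_correlation(self):
        assert genes.effective_number_snps(np.ones((5, 5))) == pytest.approx(1.0)

    def test_two_by_two_half_correlation(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert genes.effective_number_snps(R) == pytest.approx(1.5)


class TestGates:
    def test_single_snp_passthrough(self):
        assert genes.gates([0.03], np.eye(1)) == pytest.approx(0.03)

    def test_independent_snps_equal_simes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.001, 1, size=6)
            simes = np.min(6 * np.sort(p) / np.arange(1, 7))
            assert genes.gates(p, np.eye(6)) == pytest.approx(min(simes, 1.0))

    def test_perfect_ld_equals_min_p(self):
        p = np.array([0.01, 0.01, 0.01])
        assert genes.gates(p, np.ones((3, 3))) == pytest.approx(0.01)

    def test_dominated_by_minsnp_from_above(self):
        rng = np.random.default_rng(1)
        k = 8
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        R = 0.6 ** d
        for _ in range(30):
            p = rng.uniform(1e-4, 1, size=k)
            assert genes.gates(p, R) <= genes.minsnp(p, R) + 1e-12
            assert genes.gates(p, R) >= p.min()

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            genes.gates([0.1, 0.2], np.eye(3))


class TestMinsnp:
    def test_single_snp(self):
        assert genes.minsnp([0.2], np.eye(1)) == pytest.approx(0.2)

    def test_independent_bonferroni_by_me(self):
        p = np.full(10, 0.5)
        p[3] = 0.004
        assert genes.minsnp(p, np.eye(10)) == pytest.approx(0.04)

    def test_perfect_ld_no_penalty(self):
        assert genes.minsnp([0.01, 0.01], np.ones((2, 2))) == pytest.approx(0.01)


class TestGecEffectiveGenes:
    def test_independent_best_snps_count_fully(self, nold_panel):
        sub = nold_panel.snps.groupby("region").head(1)
        df = pd.DataFrame({"best_snp_id": sub["snp_id"],
                           "chrom": sub["chrom"], "pos": sub["pos"]})
        assert genes.gec_effective_genes(df, nold_panel) == pytest.approx(
            len(df))

    def test_shared_best_snp_counts_once(self, nold_panel):
        row = nold_panel.snps.iloc[0]
        df = pd.DataFrame({"best_snp_id": [row["snp_id"]] * 2,
                           "chrom": [row["chrom"]] * 2,
                           "pos": [row["pos"], row["pos"] + 1]})
        assert genes.gec_effective_genes(df, nold_panel) == pytest.approx(1.0)

    def test_empty_input(self, nold_panel):
        df = pd.DataFrame({"best_snp_id": [], "chrom": [], "pos": []})
        assert genes.gec_effective_genes(df, nold_panel) == 0.0


class TestOverlapBinomial:
    def _results(self, panel, pvals):
        sub = panel.snps.groupby("region").head(2).reset_index(drop=True)
        n = len(pvals)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": sub["chrom"][:n], "start": sub["pos"][:n],
            "end": sub["pos"][:n] + 10, "n_snps": 1,
            "p_gates": pvals, "p_minsnp": pvals,
            "best_snp_id": sub["snp_id"][:n], "best_p": pvals})

    def test_exact_binomial_example(self, nold_panel):
        # 20 independent genes; 10 discovery hits, 9 overlapping,
        # target hits 10/20 -> expected proportion 0.5, P(X>=9 | 10, .5)
        p_disc = np.array([1e-4] * 10 + [0.9] * 10)
        p_targ = np.array([1e-4] * 9 + [0.9, 1e-4] + [0.9] * 9)
        d = self._results(nold_panel, p_disc)
        t = self._results(nold_panel, p_targ)
        r = genes.overlap_binomial(d, t, 0.05, nold_panel)
        assert r.p_binomial == pytest.approx(11 / 1024)
        assert r.prop_obs == pytest.approx(0.9)
        assert r.prop_exp == pytest.approx(0.5)

    def test_no_overlap_gives_unit_p(self, nold_panel):
        d = self._results(nold_panel, np.array([1e-4] * 5 + [0.9] * 15))
        t = self._results(nold_panel, np.array([0.9] * 5 + [1e-4] * 5 + [0.9] * 10))
        r = genes.overlap_binomial(d, t, 0.05, nold_panel)
        assert r.x_eff == 0.0
        assert r.p_binomial == pytest.approx(1.0)

    def test_no_discovery_hits_undefined(self, nold_panel):
        d = self._results(nold_panel, np.full(20, 0.9))
        with pytest.raises(EstimationError):
            genes.overlap_binomial(d, d, 0.05, nold_panel)

    def test_planted_overlap_detected(self, nold_panel):
        rng = np.random.default_rng(0)
        detected = 0
        for rep in range(50):
            p1 = rng.uniform(size=20)
            p2 = rng.uniform(size=20)
            p1[:5] = p2[:5] = 1e-3   # 25% shared associated genes
            d = self._results(nold_panel, p1)
            t = self._results(nold_panel, p2)
            try:
                r = genes.overlap_binomial(d, t, 0.05, nold_panel)
                detected += r.p_binomial < 0.05
            except EstimationError:
                pass
        assert detected >= 45


class TestFisherCombined:
    def test_unit_inputs(self):
        assert genes.fisher_combined(1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form(self):
        X = -4 * np.log(0.05)
        expected = np.exp(-X / 2) * (1 + X / 2)
        assert genes.fisher_combined(0.05, 0.05) == pytest.approx(expected)
        assert genes.fisher_combined(0.05, 0.05) == pytest.approx(
            stats.chi2.sf(X, 4))

    def test_commutes(self):
        assert genes.fisher_combined(0.01, 0.3) == pytest.approx(
            genes.fisher_combined(0.3, 0.01))

    def test_invalid_p_rejected(self):
        with pytest.raises(DomainError):
            genes.fisher_combined(0.0, 0.5)


class TestSharedGeneScreen:
    def _frame(self, p_fcp, p1, p2):
        return pd.DataFrame({"gene_id": ["g"], "p_fcp": [p_fcp],
                             "p1": [p1], "p2": [p2]})

    def test_flagged_when_all_conditions_met(self):
        out = genes.shared_gene_screen(self._frame(1e-7, 0.01, 0.03), 13_700)
        assert bool(out["shared_significant"][0])

    def test_weak_single_trait_blocks_flag(self):
        out = genes.shared_gene_screen(self._frame(1e-7, 0.2, 0.03), 13_700)
        assert not out["shared_significant"][0]

    def test_boundary_is_strict(self):
        me = 100.0
        out = genes.shared_gene_screen(self._frame(0.05 / me, 0.01, 0.01), me)
        assert not out["shared_significant"][0]


def test_gene_analysis_pipeline(small_panel):
    g1, _, _ = simulate.simulate_pair(small_panel, 0.3, 0.3, 0.5, seed=2)
    gm = simulate.make_gene_map(small_panel, genes_per_block=2,
                                gene_length=30_000)
    res = genes.gene_analysis(g1, gm, small_panel)
    assert len(res) > 0
    assert (res["p_gates"] >= res["best_p"]).all()
    assert ((res["p_gates"] > 0) & (res["p_gates"] <= 1)).all()
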