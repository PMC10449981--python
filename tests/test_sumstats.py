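import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xtrait.exceptions import ConfigurationError, DomainError, InputError
from xtrait.sumstats import (from_frame, harmonize_pair, munge, read_sumstats,
                             zscore_to_beta_se)

from conftest import canonical_frame


def _write(tmp_path, df, name="ss.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSumstats:
    def test_well_formed_rows_sorted_by_position(self, tmp_path):
        df = canonical_frame(3)
        df = df.iloc[[2, 0, 1]]  # shuffled on disk
        g = read_sumstats(_write(tmp_path, df))
        assert len(g) == 3
        assert list(g.df["pos"]) == sorted(g.df["pos"])
        assert g.meta["n_dropped"] == 0

    def test_invalid_p_row_dropped_and_counted(self, tmp_path):
        df = canonical_frame(3)
        df.loc[1, "p"] = 1.5
        g = read_sumstats(_write(tmp_path, df))
        assert len(g) == 2
        assert g.meta["n_dropped"] == 1

    def test_missing_se_and_n_is_configuration_error(self, tmp_path):
        df = canonical_frame(3).drop(columns=["se", "n", "z"])
        with pytest.raises(ConfigurationError):
            read_sumstats(_write(tmp_path, df))

    def test_zero_parseable_rows_is_input_error(self, tmp_path):
        df = canonical_frame(2)
        df["p"] = -1.0
        with pytest.raises(InputError):
            read_sumstats(_write(tmp_path, df))

    def test_header_synonyms_recognized(self, tmp_path):
        df = canonical_frame(3).rename(columns={
            "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "EA",
            "a2": "NEA", "eaf": "FRQ", "beta": "BETA", "se": "SE",
            "p": "PVAL", "n": "N"})
        df = df.drop(columns=["z"])
        g = read_sumstats(_write(tmp_path, df))
        assert len(g) == 3
        assert np.allclose(g.df["z"], g.df["beta"] / g.df["se"])

    def test_inconsistent_p_recomputed_from_z(self, tmp_path):
        df = canonical_frame(3, seed=5)
        df.loc[0, "p"] = 1e-30  # wildly inconsistent with its z
        g = read_sumstats(_write(tmp_path, df))
        assert g.meta["n_p_recomputed"] == 1
        row = g.df[g.df["snp_id"] == df.loc[0, "snp_id"]].iloc[0]
        from scipy import stats
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(row["z"])))


class TestZscoreConversion:
    def test_zero_z(self):
        beta, se = zscore_to_beta_se(0.0, 0.5, 10_000)
        assert beta == 0.0
        assert se == pytest.approx(1 / np.sqrt(5000))

    def test_direct_formula_evaluation(self):
        beta, se = zscore_to_beta_se(5.0, 0.5, 10_000)
        assert se == pytest.approx(1 / np.sqrt(0.5 * 10_025), rel=1e-9)
        assert beta == pytest.approx(5 / np.sqrt(0.5 * 10_025), rel=1e-9)

    def test_degenerate_eaf_rejected(self):
        with pytest.raises(DomainError):
            zscore_to_beta_se(1.0, 0.0, 100)
        with pytest.raises(DomainError):
            zscore_to_beta_se(1.0, 1.0, 100)

    @settings(derandomize=True, max_examples=200)
    @given(z=st.floats(-50, 50), eaf=st.floats(0.01, 0.99),
           n=st.floats(10, 1e7))
    def test_round_trip_reproduces_z(self, z, eaf, n):
        beta, se = zscore_to_beta_se(z, eaf, n)
        assert beta / se == pytest.approx(z, abs=1e-9)
        assert se > 0


class TestMunge:
    def test_low_maf_dropped(self):
        g = from_frame("t", canonical_frame(5, eaf=[0.01, 0.2, 0.3, 0.4, 0.5]))
        out = munge(g, maf_min=0.05)
        assert len(out) == 4

    def test_mhc_excluded(self):
        df = canonical_frame(3, chrom=6)
        df["pos"] = [24_000_000, 30_000_000, 36_000_000]
        out = munge(from_frame("t", df), exclude_mhc=True)
        assert len(out) == 2
        assert 30_000_000 not in list(out.df["pos"])

    def test_no_filters_is_identity(self):
        g = from_frame("t", canonical_frame(5))
        out = munge(g, maf_min=0.0)
        pd.testing.assert_frame_equal(out.df, g.df)

    def test_never_increases_and_filters_commute(self):
        df = canonical_frame(30, seed=3)
        df.loc[::3, "chrom"] = 6
        df.loc[::3, "pos"] = 30_000_000 + np.arange(10) * 100
        g = from_frame("t", df)
        a = munge(munge(g, maf_min=0.2), exclude_mhc=True)
        b = munge(munge(g, exclude_mhc=True), maf_min=0.2)
        assert len(a) <= len(g)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_empty_result_is_input_error(self):
        g = from_frame("t", canonical_frame(3))
        with pytest.raises(InputError):
            munge(g, keep_snps=set())


class TestHarmonizePair:
    def test_same_alleles_unchanged(self, trait_pair):
        g1, g2 = trait_pair
        h1, h2 = harmonize_pair(g1, g2)
        assert np.allclose(h2.df["beta"], g2.df["beta"])

    def test_swapped_alleles_flip_sign_and_frequency(self):
        g1 = from_frame("a", canonical_frame(3, seed=1))
        df2 = canonical_frame(3, seed=1)
        df2["a1"], df2["a2"] = "G", "A"
        g2 = from_frame("b", df2)
        h1, h2 = harmonize_pair(g1, g2)
        assert np.allclose(h2.df["beta"], -g2.df["beta"])
        assert np.allclose(h2.df["eaf"], 1 - g2.df["eaf"])

    def test_palindromic_dropped_when_ambiguous(self):
        df1 = canonical_frame(3, seed=1)
        df1.loc[0, "a1"], df1.loc[0, "a2"] = "A", "T"
        g1 = from_frame("a", df1)
        g2 = from_frame("b", df1.copy())
        h1, h2 = harmonize_pair(g1, g2, drop_ambiguous=True)
        assert len(h1) == 2 and len(h2) == 2

    def test_irreconcilable_alleles_dropped_with_count(self):
        df1 = canonical_frame(3, seed=1)
        df2 = df1.copy()
        df2.loc[0, "a2"] = "C"  # A/G vs A/C
        h1, h2 = harmonize_pair(from_frame("a", df1), from_frame("b", df2))
        assert len(h1) == 2
        assert h1.meta["harmonize_dropped"] == 1

    def test_idempotent(self):
        df2 = canonical_frame(4, seed=2)
        df2["a1"], df2["a2"] = "G", "A"
        g1 = from_frame("a", canonical_frame(4, seed=2))
        g2 = from_frame("b", df2)
        h1, h2 = harmonize_pair(g1, g2)
        i1, i2 = harmonize_pair(h1, h2)
        pd.testing.assert_frame_equal(h1.df, i1.df)
        pd.testing.assert_frame_equal(h2.df, i2.df)
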