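import numpy as np
import pandas as pd
import pytest

from xtrait import mr, simulate
from xtrait.exceptions import EstimationError, InstrumentError
from xtrait.mr import IVSet
from xtrait.sumstats import from_frame

from conftest import canonical_frame


def _ivset(ratios, se=0.1, bx=1.0):
    ratios = np.asarray(ratios, dtype=float)
    df = pd.DataFrame({
        "snp_id": [f"iv{i}" for i in range(ratios.size)],
        "bx": bx, "sex": 0.01, "by": ratios * bx, "sey": se * bx})
    return IVSet(df)


class TestSelectInstruments:
    def _pair_with_pvalues(self, panel, p_gws_hits, p_weak_hits):
        """Exposure with chosen numbers of GWS and suggestive lead SNPs."""
        rng = np.random.default_rng(0)
        # one candidate per block: guaranteed LD independence
        firsts = panel.snps.groupby("region").head(1).reset_index(drop=True)
        n = len(firsts)
        p = np.full(n, 0.5)
        p[:p_gws_hits] = 1e-9
        p[p_gws_hits:p_gws_hits + p_weak_hits] = 5e-6
        z = np.abs(rng.standard_normal(n)) + 1
        df = pd.DataFrame({
            "snp_id": firsts["snp_id"], "chrom": firsts["chrom"],
            "pos": firsts["pos"], "a1": "A", "a2": "G",
            "eaf": firsts["eaf"], "beta": 0.1, "se": 0.01, "z": z, "p": p,
            "n": 50_000.0})
        exposure = from_frame("exp", df)
        out = df.copy()
        out["beta"] = 0.03
        outcome = from_frame("out", out)
        return exposure, outcome

    def test_enough_gws_instruments_keep_default_threshold(self):
        panel = simulate.make_panel(n_blocks=40, block_size=5, seed=2)
        e, o = self._pair_with_pvalues(panel, 12, 10)
        iv = mr.select_instruments(e, o, panel)
        assert iv.p_threshold_used == 5e-8
        assert len(iv) == 12

    def test_fallback_threshold_below_min_iv(self):
        panel = simulate.make_panel(n_blocks=40, block_size=5, seed=2)
        e, o = self._pair_with_pvalues(panel, 8, 22)
        iv = mr.select_instruments(e, o, panel)
        assert iv.p_threshold_used == 1e-5
        assert len(iv) == 30

    def test_no_instruments_raises(self):
        panel = simulate.make_panel(n_blocks=40, block_size=5, seed=2)
        e, o = self._pair_with_pvalues(panel, 0, 0)
        with pytest.raises(InstrumentError):
            mr.select_instruments(e, o, panel)


class TestIvw:
    def test_identical_ratios(self):
        r = mr.ivw(_ivset([0.2, 0.2, 0.2]))
        assert r.beta_xy == pytest.approx(0.2)
        assert r.extras["q_stat"] == pytest.approx(0.0, abs=1e-20)

    def test_hand_arithmetic(self):
        r = mr.ivw(_ivset([0.1, 0.2, 0.3]))
        assert r.beta_xy == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1 / np.sqrt(3))

    def test_multiplicative_re_inflates_se_under_heterogeneity(self):
        iv = _ivset([0.0, 0.5, 1.0])
        fixed = mr.ivw(iv, model="fixed")
        re = mr.ivw(iv, model="multiplicative_re")
        assert re.se > fixed.se

    def test_or_and_ci_consistent(self):
        r = mr.ivw(_ivset([0.1, 0.2, 0.3]))
        lo, hi = r.ci95
        assert lo == pytest.approx(np.exp(r.beta_xy - 1.96 * r.se))
        assert hi == pytest.approx(np.exp(r.beta_xy + 1.96 * r.se))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        df = pd.DataFrame({"snp_id": list("abcd"), "bx": bx, "sex": 0.01,
                           "by": 0.05 + 0.3 * bx, "sey": 0.01})
        r = mr.mr_egger(IVSet(df))
        assert r.beta_xy == pytest.approx(0.3, abs=1e-9)
        assert r.extras["egger_intercept"] == pytest.approx(0.05, abs=1e-9)

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            mr.mr_egger(_ivset([0.1, 0.2]))

    def test_balanced_pleiotropy_intercept_near_zero(self):
        icpts = []
        for s in range(100):
            df = simulate.simulate_mr_instruments(
                30, 0.3, pleiotropy_frac=1.0, pleiotropy_mean=0.0,
                pleiotropy_sd=0.02, seed=s)
            icpts.append(mr.mr_egger(IVSet(df)).extras["egger_intercept"])
        assert np.mean(icpts) == pytest.approx(0.0, abs=0.01)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        r = mr.weighted_median(_ivset([1.0, 2.0, 3.0]))
        assert r.beta_xy == pytest.approx(2.0)

    def test_seeded_bootstrap_reproducible(self):
        iv = _ivset([0.1, 0.3, 0.2, 0.25])
        a = mr.weighted_median(iv, seed=7)
        b = mr.weighted_median(iv, seed=7)
        assert a.se == b.se


class TestPresso:
    def test_minimum_p_is_add_one_bound(self):
        df = simulate.simulate_mr_instruments(20, 0.3, seed=1)
        df.loc[3, "by"] += 0.5  # gross outlier
        r = mr.mr_presso(IVSet(df), n_sim=1000, seed=0)
        assert r.extras["global_p"] >= 1 / 1001
        assert "iv3" in r.extras["outlier_ids"]

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            mr.mr_presso(_ivset([0.1, 0.2, 0.3]))

    def test_outlier_removal_restores_estimate(self):
        df = simulate.simulate_mr_instruments(20, 0.3, seed=2)
        df.loc[5, "by"] += 0.3
        r = mr.mr_presso(IVSet(df), seed=0)
        assert abs(r.beta_xy - 0.3) < abs(r.extras["beta_raw"] - 0.3)


class TestGsmr:
    def test_identity_ld_equals_fixed_ivw(self):
        df = simulate.simulate_mr_instruments(30, 0.3, seed=1)
        g = mr.gsmr(IVSet(df), heidi_p=0.0, seed=0)
        i = mr.ivw(IVSet(df), model="fixed")
        assert g.beta_xy == pytest.approx(i.beta_xy, abs=1e-8)
        assert g.se == pytest.approx(i.se, abs=1e-8)

    def test_planted_pleiotropic_instrument_removed(self):
        removed = 0
        for s in range(50):
            df = simulate.simulate_mr_instruments(20, 0.3, seed=s)
            df.loc[4, "by"] += 0.1
            g = mr.gsmr(IVSet(df), seed=s)
            removed += "iv4" in g.extras["heidi_removed"]
        assert removed >= 45

    def test_all_removed_raises(self):
        df = simulate.simulate_mr_instruments(5, 0.3, seed=1)
        with pytest.raises(EstimationError):
            mr.gsmr(IVSet(df), heidi_p=1.1, seed=0)


class TestCochranQ:
    def test_identical_ratios_no_heterogeneity(self):
        q, p = mr.cochran_q(_ivset([0.2, 0.2, 0.2]), 0.2)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        iv = _ivset([0.0, 0.2], se=0.1)
        q, p = mr.cochran_q(iv, 0.1)
        assert q == pytest.approx(2.0)
        assert p == pytest.approx(0.15729, rel=1e-3)

    def test_order_invariance(self):
        a = mr.cochran_q(_ivset([0.1, 0.4, 0.2]), 0.2)[0]
        b = mr.cochran_q(_ivset([0.4, 0.2, 0.1]), 0.2)[0]
        assert a == pytest.approx(b)


def test_estimators_agree_with_strong_valid_instruments():
    # no pleiotropy: the five estimators agree within combined uncertainty
    for s in range(10):
        df = simulate.simulate_mr_instruments(40, 0.3, seed=300 + s)
        iv = IVSet(df)
        res = mr.mr_all(iv, seed=s)
        ests = {k: v.beta_xy for k, v in res.items()}
        ses = {k: v.se for k, v in res.items()}
        for k, v in ests.items():
            if k == "ivw":
                continue
            tol = 2 * np.hypot(ses["ivw"], ses[k])
            assert abs(v - ests["ivw"]) < max(tol, 0.02), (s, k)
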