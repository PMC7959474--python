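"""Bland-Altman statistics, trend interpretation and summary tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handkin import (AgreementResult, BlandAltman, PairedMeasurements,
                     bland_altman, rom_table, summarize_segment_lengths,
                     trend_interpretation)
from handkin.exceptions import InsufficientDataError, ValidationError


def oracle_bland_altman(x, y):
    """Textbook formulas coded independently of the implementation."""
    n = len(x)
    d = [xi - yi for xi, yi in zip(x, y)]
    m = [(xi + yi) / 2.0 for xi, yi in zip(x, y)]
    bias = sum(d) / n
    sd = math.sqrt(sum((di - bias) ** 2 for di in d) / (n - 1))
    out = {"bias": bias, "sd": sd,
           "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}
    from scipy.stats import t as tdist
    half = tdist.ppf(0.975, n - 1) * sd / math.sqrt(n)
    out["ci"] = (bias - half, bias + half)
    md = sum(m) / n
    sxx = sum((mi - md) ** 2 for mi in m)
    syy = sum((di - bias) ** 2 for di in d)
    sxy = sum((mi - md) * (di - bias) for mi, di in zip(m, d))
    if sxx > 0 and syy > 0 and n >= 3:
        r = sxy / math.sqrt(sxx * syy)
        tstat = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        out["r"] = r
        out["p"] = 2.0 * tdist.sf(abs(tstat), n - 2)
    return out


class TestBlandAltman:
    def test_perfect_agreement(self):
        values = np.array([10.0, 25.0, 40.0, 55.0])
        res = bland_altman(PairedMeasurements(values, values.copy()))
        assert res.bias == 0.0
        assert res.loa_high - res.loa_low == 0.0
        assert not res.r_defined and math.isnan(res.r)

    def test_five_pair_worked_example_matches_oracle(self):
        ref = [10.0, 20.0, 30.0, 40.0, 50.0]
        test = [12.0, 19.0, 33.0, 36.0, 55.0]
        res = bland_altman(PairedMeasurements(np.array(ref), np.array(test)))
        exp = oracle_bland_altman(ref, test)
        assert res.bias == pytest.approx(exp["bias"], abs=1e-12)
        assert res.sd_diff == pytest.approx(exp["sd"], abs=1e-12)
        assert res.loa_low == pytest.approx(exp["loa_low"], abs=1e-12)
        assert res.loa_high == pytest.approx(exp["loa_high"], abs=1e-12)
        assert res.ci95_bias[0] == pytest.approx(exp["ci"][0], abs=1e-12)
        assert res.ci95_bias[1] == pytest.approx(exp["ci"][1], abs=1e-12)
        assert res.r == pytest.approx(exp["r"], abs=1e-12)
        assert res.p == pytest.approx(exp["p"], abs=1e-12)

    def test_matches_oracle_on_many_random_paired_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            ref = rng.uniform(0, 120, n)
            test = ref + rng.normal(-5, 8, n)
            res = bland_altman(PairedMeasurements(ref, test))
            exp = oracle_bland_altman(list(ref), list(test))
            for field, key in (("bias", "bias"), ("sd_diff", "sd"),
                               ("loa_low", "loa_low"), ("loa_high", "loa_high")):
                assert abs(getattr(res, field) - exp[key]) < 1e-10
            assert abs(res.ci95_bias[0] - exp["ci"][0]) < 1e-10
            assert abs(res.ci95_bias[1] - exp["ci"][1]) < 1e-10
            if "r" in exp:
                assert abs(res.r - exp["r"]) < 1e-10
                assert abs(res.p - exp["p"]) < 1e-10

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        ref = rng.uniform(0, 90, n)
        test = rng.uniform(0, 90, n)
        perm = rng.permutation(n)
        a = bland_altman(PairedMeasurements(ref, test))
        b = bland_altman(PairedMeasurements(ref[perm], test[perm]))
        for field in ("bias", "sd_diff", "loa_low", "loa_high", "r", "p"):
            va, vb = getattr(a, field), getattr(b, field)
            assert va == pytest.approx(vb, abs=1e-10, nan_ok=True)

    def test_swapping_systems_negates_bias_and_r_and_mirrors_loa(self):
        rng = np.random.default_rng(8)
        ref = rng.uniform(0, 90, 15)
        test = ref + rng.normal(4, 6, 15)
        fwd = BlandAltman.from_arrays(ref, test).fit()
        rev = BlandAltman.from_arrays(ref, test, sign="test_minus_reference").fit()
        assert rev.bias == pytest.approx(-fwd.bias, abs=1e-12)
        assert rev.loa_low == pytest.approx(-fwd.loa_high, abs=1e-12)
        assert rev.loa_high == pytest.approx(-fwd.loa_low, abs=1e-12)
        assert rev.r == pytest.approx(-fwd.r, abs=1e-12)
        assert rev.p == pytest.approx(fwd.p, abs=1e-12)

    def test_r_omitted_below_three_pairs(self):
        res = bland_altman(PairedMeasurements(np.array([1.0, 2.0]),
                                              np.array([2.0, 1.0])))
        assert not res.r_defined and math.isnan(res.r) and math.isnan(res.p)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            PairedMeasurements(np.array([1.0]), np.array([1.0]))

    def test_summary_mentions_undefined_trend(self):
        values = np.array([5.0, 5.0, 5.0, 5.0])
        res = bland_altman(PairedMeasurements(values + 2.0, values))
        assert "undefined" in res.summary()
        assert res.bias == pytest.approx(2.0)


class TestTrendInterpretation:
    def make(self, r, p):
        return AgreementResult(n=18, bias=0.0, sd_diff=1.0, loa_low=-2.0, loa_high=2.0,
                               ci95_bias=(-0.5, 0.5), r=r, p=p,
                               r_defined=not math.isnan(r))

    def test_strong_significant_correlation_is_proportional_bias(self):
        assert trend_interpretation(self.make(0.9062, 0.0005)) == "proportional_bias"

    def test_negligible_correlation_is_no_trend(self):
        assert trend_interpretation(self.make(0.0084, 0.9735)) == "no_trend"

    def test_boundary_p_equal_alpha_is_no_trend(self):
        assert trend_interpretation(self.make(0.5, 0.05), alpha=0.05) == "no_trend"

    def test_undefined_r_is_no_trend(self):
        assert trend_interpretation(self.make(float("nan"), float("nan"))) == "no_trend"


class TestSummaries:
    def test_single_subject_sd_is_zero(self):
        df = pd.DataFrame([{"subject": 1, "system": "reference", "finger": "index",
                            "segment": "proximal", "mean_mm": 44.0}])
        out = summarize_segment_lengths(df)
        assert out.loc[0, "reference_sd_mm"] == 0.0
        assert out.loc[0, "reference_mean_mm"] == 44.0

    def test_two_identical_subjects_sd_exactly_zero(self):
        df = pd.DataFrame([
            {"subject": s, "system": "test", "finger": "ring",
             "segment": "distal", "mean_mm": 17.4} for s in (1, 2)])
        out = summarize_segment_lengths(df)
        assert out.loc[0, "test_sd_mm"] == 0.0

    def test_rom_table_difference_column(self):
        rows = []
        for system, rom in (("test", 43.59), ("reference", 105.10)):
            rows.append({"task": "middle_flexion", "joint": "middle_pip",
                         "system": system, "rom": rom})
        for system, rom in (("test", 47.49), ("reference", 19.86)):
            rows.append({"task": "ring_flexion", "joint": "ring_dip",
                         "system": system, "rom": rom})
        out = rom_table(pd.DataFrame(rows)).set_index("joint")
        assert out.loc["middle_pip", "difference"] == pytest.approx(61.51, abs=1e-9)
        assert out.loc["ring_dip", "difference"] == pytest.approx(-27.63, abs=1e-9)

    def test_rom_table_identical_systems_all_zero(self):
        rows = [{"task": "t", "joint": j, "system": s, "rom": 30.0}
                for j in ("a", "b") for s in ("reference", "test")]
        out = rom_table(pd.DataFrame(rows))
        assert np.allclose(out["difference"], 0.0)

    def test_rom_table_unmatched_joint_omitted(self):
        rows = [{"task": "t", "joint": "a", "system": "reference", "rom": 10.0}]
        assert len(rom_table(pd.DataFrame(rows))) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            summarize_segment_lengths(pd.DataFrame({"subject": [1]}))
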