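"""Binned correlations, regression fits, Wilcoxon machinery, length pairing."""

import numpy as np
import pytest

from oracles import exact_rank_sum_p
from structage import stats as st
from structage.stats import BinSeries, DegenerateDataError, StatsError


def series(dn, age=None, mids=None):
    dn = np.asarray(dn, dtype=float)
    mids = np.linspace(0.025, 0.975, len(dn)) if mids is None else np.asarray(mids)
    return BinSeries(mids, dn, np.zeros(len(dn)), np.full(len(dn), 1000), age=age)


class TestPearsonBinned:
    def test_perfectly_linear_series(self):
        s = series(0.001 + 0.005 * np.linspace(0.025, 0.975, 20))
        r, p = st.pearson_binned_correlation(s)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            st.pearson_binned_correlation(series(np.full(20, 0.01)))

    def test_too_few_bins_rejected(self):
        with pytest.raises(StatsError):
            st.pearson_binned_correlation(series([0.1, 0.2]))


class TestRsaAgeModel:
    def test_two_point_series_interpolated_exactly(self):
        s = series([0.001, 0.004], mids=[0.1, 0.9])
        fit = st.fit_rsa_age_model(s)["all"]
        assert fit.slope == pytest.approx((0.004 - 0.001) / 0.8)

    def test_planted_slopes_recovered_within_20_percent(self):
        """Low-noise series planted at the observed per-age slopes."""
        rng = np.random.default_rng(0)
        mids = np.linspace(0.025, 0.975, 20)
        planted = {"eukarya": 0.0025, "vertebrata": 0.006}
        by_age = {
            age: series(0.005 + b * mids + rng.normal(0, 1e-5, 20), age=age)
            for age, b in planted.items()
        }
        fits = st.fit_rsa_age_model(by_age)
        for age, b in planted.items():
            assert abs(fits[age].slope - b) / b < 0.2
        inter = st.fit_rsa_age_model(by_age, formula="dN~RSA+RSA*age+age")
        assert inter[("eukarya", "vertebrata")].interaction_p < 0.01

    def test_identical_slopes_give_null_interaction(self):
        rng = np.random.default_rng(1)
        mids = np.linspace(0.025, 0.975, 20)
        by_age = {
            age: series(0.005 + 0.003 * mids + rng.normal(0, 2e-4, 20), age=age)
            for age in ("a", "b")
        }
        fit = st.fit_rsa_age_model(by_age, formula="dN~RSA+RSA*age+age")[("a", "b")]
        assert fit.interaction_p > 0.05
        assert abs(fit.params["rsa:age"]) < 1e-3


class TestWilcoxon:
    def test_identical_samples_unpaired(self):
        a = np.arange(10.0)
        _, p = st.wilcoxon_test(a, a)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_small_samples_match_enumeration_oracle(self):
        """Exact p equals brute-force enumeration for all-tie-free n <= 8."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            n, m = rng.integers(3, 9), rng.integers(3, 9)
            pooled = rng.permutation(rng.normal(size=n + m))
            a, b = pooled[:n], pooled[n:]
            _, p = st.wilcoxon_test(a, b)
            assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_power_against_planted_shift(self):
        """A one-sd shift at n = 200 per group is detected at p < 0.01."""
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = st.wilcoxon_test(a, b)
        assert p < 0.01

    def test_paired_all_zero_differences_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            st.wilcoxon_test(a, a, paired=True)

    def test_paired_detects_shift(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 150)
        b = a + rng.normal(0.5, 0.3, 150)
        _, p = st.wilcoxon_test(a, b, paired=True)
        assert p < 0.01


class TestLengthBinPairing:
    def test_identical_length_multisets_fully_retained(self):
        lengths = [60, 70, 80, 90, 100]
        groups = {
            "old": [(l, 0.0) for l in lengths],
            "young": [(l, 1.0) for l in lengths],
        }
        table, excluded = st.length_bin_pairing(groups, bin_width=25, seed=0)
        assert excluded == []
        assert len(table) == 2 * len(lengths)

    def test_disjoint_ranges_flagged(self):
        groups = {
            "old": [(60, 0.0), (70, 0.0)],
            "young": [(300, 1.0), (310, 1.0)],
        }
        table, excluded = st.length_bin_pairing(groups, bin_width=25, seed=0)
        assert len(table) == 0
        assert set(excluded) == {"old", "young"}

    def test_partial_overlap_drops_one_group(self):
        groups = {
            "old": [(60, 0.0), (100, 0.0), (140, 0.0)],
            "mid": [(65, 0.5), (105, 0.5), (145, 0.5)],
            "young": [(400, 1.0)],
        }
        table, excluded = st.length_bin_pairing(groups, bin_width=25, seed=0)
        assert excluded == ["young"]
        assert set(table.group) == {"old", "mid"}

    def test_equal_counts_within_bins(self):
        rng = np.random.default_rng(5)
        groups = {
            g: [(int(rng.integers(60, 160)), float(rng.normal())) for _ in range(40)]
            for g in ("a", "b")
        }
        table, _ = st.length_bin_pairing(groups, bin_width=25, seed=1)
        counts = table.groupby(["length_bin", "group"]).size().unstack()
        assert (counts["a"] == counts["b"]).all()

    def test_planted_offset_detected_by_paired_wilcoxon(self):
        """A planted delta-G offset between length-matched groups is found."""
        rng = np.random.default_rng(6)
        lengths = rng.integers(60, 200, size=150)
        base = rng.normal(-90, 8, size=150)
        groups = {
            "old": list(zip(lengths, base)),
            "young": list(zip(lengths, base + 5.0 + rng.normal(0, 1, 150))),
        }
        table, _ = st.length_bin_pairing(groups, bin_width=25, seed=2)
        a = table[table.group == "old"].value.to_numpy()
        b = table[table.group == "young"].value.to_numpy()
        _, p = st.wilcoxon_test(a, b, paired=True)
        assert p < 0.01
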