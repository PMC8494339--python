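"""Unit and property tests for discretization and information measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from mgs import mi_core as mc
from oracles import cmi_bruteforce, mi_bruteforce

LN2 = np.log(2.0)


class TestDiscretize:
    def test_constant_vector_occupies_one_bin(self):
        dg = mc.discretize([5, 5, 5, 5], 2)
        assert dg.bins.tolist() == [0, 0, 0, 0]
        assert dg.occupied == 1

    def test_hand_case_equal_width(self):
        # width (3-0)/2 = 1.5, edges 0 / 1.5 / 3; max goes to the top bin
        dg = mc.discretize([0, 1, 2, 3], 2)
        assert dg.bins.tolist() == [0, 0, 1, 1]
        np.testing.assert_allclose(dg.edges, [0, 1.5, 3])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_binary_split_equals_midpoint_threshold(self, values):
        v = np.asarray(values)
        dg = mc.discretize(v, 2)
        if v.min() == v.max():
            assert set(dg.bins) == {0}
            return
        mid = (v.min() + v.max()) / 2.0
        expected = (v >= mid).astype(int)
        # floating-point placement of the midpoint itself may differ by
        # one ulp; everything strictly away from the edge must agree
        off_edge = v != mid
        assert np.array_equal(dg.bins[off_edge], expected[off_edge])

    def test_edges_strictly_increasing_and_cover_data(self, rng):
        v = rng.normal(size=25)
        for d in (2, 3, 7):
            dg = mc.discretize(v, d)
            assert np.all(np.diff(dg.edges) > 0)
            assert dg.edges[0] <= v.min() and v.max() <= dg.edges[-1]
            assert dg.bins.min() >= 0 and dg.bins.max() <= d - 1

    def test_equal_frequency_scheme_balances_occupancy(self, rng):
        v = rng.normal(size=200)
        dg = mc.discretize(v, 4, scheme="equal-frequency")
        counts = np.bincount(dg.bins)
        assert counts.min() >= 40  # quartiles of continuous data

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            mc.discretize([1.0, 2.0], 1)
        with pytest.raises(ValueError):
            mc.discretize([], 2)
        with pytest.raises(ValueError):
            mc.discretize([1.0, np.nan], 2)


class TestMutualInformation:
    def test_identical_fair_binary_is_one_bit(self):
        x = np.tile([0, 1], 50)
        assert mc.mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_variable_gives_zero(self, rng):
        y = rng.integers(0, 2, size=40)
        assert mc.mutual_information(np.zeros(40, dtype=int), y) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mc.mutual_information([0, 1], [0, 1, 0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        x = rng.integers(0, rng.integers(2, 6), size=n)
        y = rng.integers(0, rng.integers(2, 6), size=n)
        mi = mc.mutual_information(x, y)
        assert mi == pytest.approx(mi_bruteforce(x, y), abs=1e-12)
        assert mi == pytest.approx(mc.mutual_information(y, x), abs=1e-12)
        assert -1e-12 <= mi <= min(mc.entropy_bits(x), mc.entropy_bits(y)) + 1e-12


class TestConditionalMutualInformation:
    def test_xor_identity(self):
        # exhaustive balanced population of the XOR truth table
        x = np.array([0, 0, 1, 1] * 25)
        y = np.array([0, 1, 0, 1] * 25)
        c = x ^ y
        assert mc.mutual_information(x, c) == pytest.approx(0.0, abs=1e-12)
        assert mc.conditional_mutual_information(x, y, c) == pytest.approx(1.0)

    def test_constant_argument_gives_zero(self, rng):
        y = rng.integers(0, 3, size=30)
        z = rng.integers(0, 2, size=30)
        assert mc.conditional_mutual_information(np.ones(30, int), y, z) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        x = rng.integers(0, 4, size=n)
        y = rng.integers(0, 3, size=n)
        z = rng.integers(0, 2, size=n)
        cmi = mc.conditional_mutual_information(x, y, z)
        assert cmi == pytest.approx(cmi_bruteforce(x, y, z), abs=1e-12)
        assert cmi == pytest.approx(
            mc.conditional_mutual_information(y, x, z), abs=1e-12)
        assert cmi >= -1e-12


class TestBiasTerms:
    @pytest.mark.parametrize(
        "i, k, n, expected",
        [(1, 2, 100, 0.0), (2, 1, 100, 0.0), (2, 2, 100, 1 / (200 * LN2))],
    )
    def test_relevance_bias_values(self, i, k, n, expected):
        assert mc.relevance_bias(i, k, n) == pytest.approx(expected)

    def test_relevance_bias_halves_when_n_doubles(self):
        assert mc.relevance_bias(3, 2, 200) == pytest.approx(
            mc.relevance_bias(3, 2, 100) / 2)

    def test_complementary_bias_value_and_identity(self):
        assert mc.complementary_bias(2, 2, 2, 100) == pytest.approx(2 / (200 * LN2))
        assert mc.complementary_bias(1, 5, 3, 50) == 0.0
        # (I-1)(J-1)K/(2N ln2) == relevance-form with J as the class count, times K
        assert mc.complementary_bias(3, 4, 2, 77) == pytest.approx(
            mc.relevance_bias(3, 4, 77) * 2)


class TestChi2Critical:
    def test_df1_reference_value(self):
        expected = (chi2.ppf(0.95, 1) - 1) / (200 * LN2)
        assert mc.chi2_critical_mi(1, 0.05, 100) == pytest.approx(expected)
        assert expected == pytest.approx(0.020495, abs=1e-5)

    def test_corrected_scale_equals_raw_scale_test(self, rng):
        # j_rel > crit  <=>  2 N ln2 * MI > chi2 quantile
        n = 60
        y = rng.integers(0, 2, size=n)
        for _ in range(20):
            g = rng.normal(size=n)
            dg = mc.discretize(g, 3)
            df = (dg.occupied - 1) * 1
            if df == 0:
                continue
            mi = mc.mutual_information(dg, y)
            corrected_decision = mc.j_rel(g, y, 3) > mc.chi2_critical_mi(df, 0.05, n)
            raw_decision = 2 * n * LN2 * mi > chi2.ppf(0.95, df)
            assert corrected_decision == raw_decision

    def test_monotone_in_df_and_n(self):
        assert mc.chi2_critical_mi(4, 0.05, 100) > mc.chi2_critical_mi(1, 0.05, 100)
        assert mc.chi2_critical_mi(2, 0.05, 200) < mc.chi2_critical_mi(2, 0.05, 100)

    def test_alpha_to_one_limit(self):
        assert mc.chi2_critical_mi(3, 0.999999, 100) == pytest.approx(
            -3 / (200 * LN2), abs=1e-4)

    def test_literal_scale_omits_df_subtraction(self):
        lit = mc.chi2_critical_mi(2, 0.05, 50, scale="literal")
        cor = mc.chi2_critical_mi(2, 0.05, 50, scale="corrected")
        assert lit - cor == pytest.approx(2 / (100 * LN2))

    def test_nonpositive_df_raises(self):
        with pytest.raises(ValueError):
            mc.chi2_critical_mi(0, 0.05, 100)


class TestJRel:
    def test_label_copy_gene(self):
        y = np.tile([0, 1], 50)
        assert mc.j_rel(y.astype(float), y, 2) == pytest.approx(
            1.0 - 1 / (200 * LN2))

    def test_constant_gene_is_zero(self):
        y = np.tile([0, 1], 10)
        assert mc.j_rel(np.full(20, 3.3), y, 4) == 0.0

    def test_never_exceeds_uncorrected_mi(self, rng):
        y = rng.integers(0, 2, size=40)
        for _ in range(10):
            g = rng.normal(size=40)
            dg = mc.discretize(g, 4)
            assert mc.j_rel(g, y, 4) <= mc.mutual_information(dg, y) + 1e-12


class TestJMgs:
    def test_constant_partner_reduces_to_j_rel(self, rng):
        y = rng.integers(0, 2, size=40)
        g = rng.normal(size=40)
        partner = mc.discretize(np.full(40, 1.0), 3)
        assert mc.j_mgs(g, y, 3, [partner]) == pytest.approx(
            mc.j_rel(g, y, 3), abs=1e-12)

    def test_xor_partner_contributes_one_bit(self):
        rng = np.random.default_rng(5)
        n = 4000
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        c = a ^ b
        partner = mc.discretize(b.astype(float), 2)
        score = mc.j_mgs(a.astype(float), c, 2, [partner])
        assert score == pytest.approx(1.0, abs=0.05)
        assert abs(mc.j_rel(a.astype(float), c, 2)) < 0.05

    def test_empty_selected_set_raises(self, rng):
        with pytest.raises(ValueError):
            mc.j_mgs(rng.normal(size=10), rng.integers(0, 2, 10), 2, [])

    @given(st.integers(0, 5_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_naive_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        g = rng.normal(size=n)
        partners = [mc.discretize(rng.normal(size=n), int(rng.integers(2, 5)))
                    for _ in range(int(rng.integers(1, 4)))]
        d = int(rng.integers(2, 5))
        dg = mc.discretize(g, d)
        i, k = dg.occupied, len(np.unique(y))
        expected = mi_bruteforce(dg.bins, y) - mc.relevance_bias(i, k, n)
        comp = [
            cmi_bruteforce(dg.bins, p.bins, y)
            - mc.complementary_bias(i, p.occupied, k, n)
            for p in partners
        ]
        expected += sum(comp) / len(comp)
        assert mc.j_mgs(g, y, d, partners) == pytest.approx(expected, abs=1e-12)


class TestNullCalibration:
    def test_type_one_error_and_centering_at_binary_level(self):
        """2N ln2 * MI of independent pairs is chi-square to MC precision."""
        rng = np.random.default_rng(424242)
        n, reps = 100, 2000
        X = rng.normal(size=(reps, n))
        y = (rng.random(n) < 0.5).astype(int)
        bins = mc.discretize_matrix(X, 2)
        mi, occ = mc.mi_profile(bins, y, 2)
        df = (occ - 1) * 1
        score = mi - df / (2 * n * LN2)
        crit = np.array([mc.chi2_critical_mi(f, 0.05, n) for f in df])
        rate = float((score > crit).mean())
        band = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= band
        sem = score.std(ddof=1) / np.sqrt(reps)
        assert abs(score.mean()) <= 3 * sem
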