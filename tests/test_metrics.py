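import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mcrquant as mq


def vec(n_min=2, n_max=12):
    return st.lists(
        st.floats(0.1, 100.0, allow_nan=False), min_size=n_min, max_size=n_max)


class TestFiguresOfMerit:
    def test_perfect_prediction(self):
        fom = mq.figures_of_merit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fom.rmsep == 0 and fom.bias == 0 and fom.sep == 0
        assert fom.re_pct == 0
        assert fom.r2 == pytest.approx(1.0)
        assert fom.slope == pytest.approx(1.0)
        assert fom.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_has_zero_sep(self):
        fom = mq.figures_of_merit([1.0, 2.0, 3.0], [0.9, 1.9, 2.9])
        assert fom.bias == pytest.approx(0.1)
        assert fom.rmsep == pytest.approx(0.1)
        assert fom.sep == pytest.approx(0.0, abs=1e-12)

    def test_relative_error_formula_arithmetic(self):
        fom = mq.figures_of_merit([10.0, 10.0], [9.0, 11.0])
        assert fom.re_pct == pytest.approx(10.0)

    @settings(max_examples=100, deadline=None)
    @given(pairs=st.lists(
        st.tuples(st.floats(0.1, 50.0), st.floats(0.0, 50.0)),
        min_size=2, max_size=15))
    def test_rmsep_identity_holds_for_all_inputs(self, pairs):
        actual = [a for a, _ in pairs]
        predicted = [p for _, p in pairs]
        fom = mq.figures_of_merit(actual, predicted)
        n = fom.n
        lhs = fom.rmsep**2
        rhs = fom.bias**2 + fom.sep**2 * (n - 1) / n
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 10, 9)
        p = a + rng.normal(0, 0.1, 9)
        perm = rng.permutation(9)
        f1 = mq.figures_of_merit(a, p)
        f2 = mq.figures_of_merit(a[perm], p[perm])
        for attr in ("rmsep", "sep", "bias", "re_pct", "r2", "slope", "intercept"):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mq.figures_of_merit([1.0], [1.0])
        with pytest.raises(ValueError, match="relative error undefined"):
            mq.figures_of_merit([0.0, 0.0], [0.1, 0.2])


class TestRecovery:
    @pytest.mark.parametrize("X,Y,Z,expected", [
        (2.0, 1.0, 1.0, 100.0),
        (1.0, 1.0, 2.0, 0.0),
        (2.98, 1.0, 2.0, 99.0),
    ])
    def test_formula_arithmetic(self, X, Y, Z, expected):
        assert mq.recovery(X, Y, Z) == pytest.approx(expected)

    def test_nonpositive_addition_rejected(self):
        with pytest.raises(ValueError):
            mq.recovery(2.0, 1.0, 0.0)


class TestPrecisionRsd:
    def test_identical_replicates_have_zero_rsd(self):
        assert mq.precision_rsd([[5.0, 5.0, 5.0]]) == [pytest.approx(0.0)]

    def test_hand_arithmetic(self):
        assert mq.precision_rsd([[98.0, 100.0, 102.0]])[0] == pytest.approx(2.0)

    def test_three_level_layout_matches_direct_recomputation(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(level, 0.5, 3) for level in (1.0, 5.0, 10.0)]
        got = mq.precision_rsd(groups)
        expected = [100 * np.std(g, ddof=1) / np.mean(g) for g in groups]
        np.testing.assert_allclose(got, expected)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            mq.precision_rsd([[1.0, -1.0]])


class TestMethodComparison:
    def test_critical_values_match_published_tables_at_n5(self):
        mc = mq.compare_methods([99.0, 100.0, 101.0, 99.5, 100.5],
                                [99.2, 99.8, 100.9, 99.6, 100.4], alpha=0.05)
        assert round(mc.t_crit, 2) == 2.78
        assert round(mc.f_crit, 2) == 6.39

    @pytest.mark.parametrize("sd1,sd2,expected", [
        (1.50, 1.25, 1.44),
        (1.85, 1.58, 1.37),
    ])
    def test_f_from_published_standard_deviations(self, sd1, sd2, expected):
        assert round(mq.f_from_sds(sd1, sd2), 2) == expected

    def test_equal_spreads_give_unit_f(self):
        assert mq.f_from_sds(0.37, 0.37) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(sd1=st.floats(0.01, 10.0), sd2=st.floats(0.01, 10.0))
    def test_f_reciprocal_identity(self, sd1, sd2):
        assert mq.f_from_sds(sd1, sd2) * mq.f_from_sds(sd2, sd1) == \
            pytest.approx(1.0, rel=1e-9)

    def test_plain_ratio_convention_allows_f_below_one(self):
        rng = np.random.default_rng(4)
        a = rng.normal(100, 0.5, 5)
        b = rng.normal(100, 2.0, 5)
        mc = mq.compare_methods(a, b)
        assert mc.f_stat < 1.0

    def test_equivalent_methods_declare_no_difference(self):
        rng = np.random.default_rng(8)
        base = rng.normal(100, 1.0, 5)
        mc = mq.compare_methods(base + rng.normal(0, 0.2, 5),
                                base + rng.normal(0, 0.2, 5))
        assert mc.t_decision == "no-difference"
        assert mc.f_decision == "no-difference"

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            mq.compare_methods([1.0, 2.0], [3.0, 3.0])
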