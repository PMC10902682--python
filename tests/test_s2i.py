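"""Unit and property tests for the sequence-to-image transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ts2inet.s2i import (
    GAFImage,
    NormalizedSeries,
    gadf,
    gasf,
    invert_gasf_diagonal,
    minmax_normalize,
    mtf,
    paa_reduce,
    recurrence_plot,
    to_polar,
    transform_record,
)
from ts2inet.signal_io import RawRecord


def paa_brute_force(signal, l):
    """Independent PAA oracle: refine the step function onto a common grid
    of n*l equal slices, where every window boundary is exact, then group."""
    return np.repeat(np.asarray(signal, float), l).reshape(l, -1).mean(axis=1)


class TestPAA:
    @pytest.mark.parametrize(
        "signal,l,expected",
        [
            ([1, 2, 3, 4], 2, [1.5, 3.5]),
            ([7, 7, 7, 7, 7], 3, [7, 7, 7]),
            ([1, 2, 3, 4, 5], 2, [1.8, 4.2]),  # fractional-overlap windows
        ],
    )
    def test_examples(self, signal, l, expected):
        np.testing.assert_allclose(paa_reduce(np.array(signal, float), l), expected)

    def test_identity_when_same_length(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        np.testing.assert_array_equal(paa_reduce(x, 4), x)

    def test_upsampling_repeats_samples(self):
        # l = 2n: each sample covers exactly two windows
        np.testing.assert_allclose(paa_reduce(np.array([1.0, 5.0]), 4), [1, 1, 5, 5])

    def test_matches_brute_force_on_random_lengths(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 60))
            l = int(rng.integers(1, 50))
            sig = rng.normal(size=n)
            np.testing.assert_allclose(
                paa_reduce(sig, l), paa_brute_force(sig, l), atol=1e-10
            )

    def test_rejects_bad_target_length(self):
        with pytest.raises(ValueError):
            paa_reduce(np.array([1.0, 2.0]), 0)


class TestNormalize:
    def test_unit_endpoints(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([0.0, 5.0, 10.0]), "unit").values, [0, 0.5, 1]
        )

    def test_sym_endpoints(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([0.0, 5.0, 10.0]), "sym").values, [-1, 0, 1]
        )

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_normalize(np.array([3.0, 3.0, 3.0]), "unit")

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_bounds_hold(self, values):
        sig = np.asarray(values)
        if sig.max() == sig.min():
            return
        for range_, (lo, hi) in (("unit", (0, 1)), ("sym", (-1, 1))):
            ns = minmax_normalize(sig, range_)
            assert ns.values.min() >= lo - 1e-12 and ns.values.max() <= hi + 1e-12
            assert np.isclose(ns.values.min(), lo) and np.isclose(ns.values.max(), hi)


class TestPolar:
    def test_sym_angles(self):
        ps = to_polar(NormalizedSeries(np.array([1.0, 0.0, -1.0]), "sym"))
        np.testing.assert_allclose(ps.angles, [0, np.pi / 2, np.pi])

    def test_unit_angles(self):
        ps = to_polar(NormalizedSeries(np.array([0.0, 0.5, 1.0]), "unit"))
        np.testing.assert_allclose(ps.angles, [np.pi / 2, np.pi / 3, 0])

    def test_radii_strictly_increasing_in_unit_interval(self):
        ps = to_polar(NormalizedSeries(np.array([0.0, 0.5, 1.0]), "unit"))
        np.testing.assert_allclose(ps.radii, [1 / 3, 2 / 3, 1.0])

    def test_drift_within_tolerance_is_clipped(self):
        ps = to_polar(NormalizedSeries(np.array([0.0, 1.0 + 1e-15]), "unit"))
        assert ps.angles[1] == 0.0

    def test_out_of_range_raises(self):
        bad = object.__new__(NormalizedSeries)
        object.__setattr__(bad, "values", np.array([0.0, 1.1]))
        object.__setattr__(bad, "range", "unit")
        with pytest.raises(ValueError):
            to_polar(bad)


def _random_normalized(rng, n, range_="unit"):
    sig = rng.normal(size=n)
    while sig.max() == sig.min():
        sig = rng.normal(size=n)
    return minmax_normalize(sig, range_)


class TestGramian:
    def test_gasf_all_zero_angles(self):
        from ts2inet.s2i import PolarSeries

        img = gasf(PolarSeries(np.zeros(3), (np.arange(3) + 1) / 3))
        np.testing.assert_array_equal(img.matrix, np.ones((3, 3)))

    def test_gasf_derived_matrix(self):
        ps = to_polar(NormalizedSeries(np.array([0.0, 0.5, 1.0]), "unit"))
        expected = [
            [-1, -np.sqrt(3) / 2, 0],
            [-np.sqrt(3) / 2, -0.5, 0.5],
            [0, 0.5, 1],
        ]
        np.testing.assert_allclose(gasf(ps).matrix, expected, atol=1e-15)

    def test_gadf_derived_matrix(self):
        ps = to_polar(NormalizedSeries(np.array([0.0, 0.5, 1.0]), "unit"))
        expected = [
            [0, 0.5, 1],
            [-0.5, 0, np.sqrt(3) / 2],
            [-1, -np.sqrt(3) / 2, 0],
        ]
        np.testing.assert_allclose(gadf(ps).matrix, expected, atol=1e-15)

    def test_gadf_constant_angles_zero_matrix(self):
        from ts2inet.s2i import PolarSeries

        img = gadf(PolarSeries(np.full(4, 0.7), (np.arange(4) + 1) / 4))
        np.testing.assert_allclose(img.matrix, 0.0, atol=1e-16)

    def test_vectorized_forms_agree(self, rng):
        """The outer-product matrix forms equal the elementwise trig forms."""
        for _ in range(30):
            n = int(rng.integers(3, 80))
            for range_ in ("unit", "sym"):
                ns = _random_normalized(rng, n, range_)
                x = ns.values
                comp = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
                gasf_vec = np.outer(x, x) - np.outer(comp, comp)
                gadf_vec = np.outer(comp, x) - np.outer(x, comp)
                ps = to_polar(ns)
                assert np.max(np.abs(gasf(ps).matrix - gasf_vec)) <= 1e-10
                assert np.max(np.abs(gadf(ps).matrix - gadf_vec)) <= 1e-10

    def test_symmetry_properties(self, rng):
        for _ in range(20):
            ns = _random_normalized(rng, int(rng.integers(3, 50)), "sym")
            s = gasf(to_polar(ns)).matrix
            d = gadf(to_polar(ns)).matrix
            np.testing.assert_array_equal(s, s.T)
            np.testing.assert_allclose(d + d.T, 0.0, atol=1e-16)
            np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-16)
            assert s.min() >= -1 - 1e-12 and s.max() <= 1 + 1e-12


class TestGASFInversion:
    def test_derived_diagonal_example(self):
        img = GAFImage(np.diag([-1.0, -0.5, 1.0]), "GASF")
        np.testing.assert_allclose(invert_gasf_diagonal(img, "unit"), [0, 0.5, 1])

    def test_all_ones_diagonal_fixed_point(self):
        img = GAFImage(np.ones((3, 3)), "GASF")
        np.testing.assert_allclose(invert_gasf_diagonal(img, "unit"), [1, 1, 1])

    def test_diagonal_identity_and_roundtrip(self, rng):
        for _ in range(50):
            ns = _random_normalized(rng, int(rng.integers(3, 100)), "unit")
            img = gasf(to_polar(ns))
            np.testing.assert_allclose(np.diag(img.matrix), 2 * ns.values**2 - 1, atol=1e-12)
            np.testing.assert_allclose(invert_gasf_diagonal(img, "unit"), ns.values, atol=1e-9)

    def test_sym_range_refused(self):
        img = GAFImage(np.diag([-1.0, 1.0]), "GASF")
        with pytest.raises(ValueError, match="sign-ambiguous"):
            invert_gasf_diagonal(img, "sym")

    def test_non_gasf_refused(self):
        with pytest.raises(ValueError):
            invert_gasf_diagonal(GAFImage(np.zeros((2, 2)), "GADF"), "unit")


class TestMTF:
    def mtf_oracle(self, sig, n_bins):
        """Brute-force transition counting with stable-rank binning."""
        sig = np.asarray(sig, float)
        l = len(sig)
        ranks = np.empty(l, int)
        ranks[np.argsort(sig, kind="stable")] = np.arange(l)
        bins = (ranks * n_bins) // l
        W = np.zeros((n_bins, n_bins))
        for a, b in zip(bins[:-1], bins[1:]):
            W[a, b] += 1
        for a in range(n_bins):
            if W[a].sum():
                W[a] /= W[a].sum()
        return W, np.array([[W[bins[i], bins[j]] for j in range(l)] for i in range(l)])

    def test_two_level_example(self):
        img = mtf(np.array([0.0, 0.0, 1.0, 1.0]), 2)
        assert img.matrix[0, 3] == 0.5
        assert img.matrix[2, 3] == 1.0

    def test_strictly_increasing_gives_superdiagonal_shift(self):
        sig = np.array([1.0, 2.0, 3.0, 4.0])
        W, expected = self.mtf_oracle(sig, 4)
        np.testing.assert_array_equal(mtf(sig, 4).matrix, expected)
        # superdiagonal pattern: bin i transitions only to bin i+1
        np.testing.assert_array_equal(W[:3], np.eye(4)[1:])

    def test_matches_oracle_on_random_signals(self, rng):
        for _ in range(20):
            l = int(rng.integers(4, 40))
            n_bins = int(rng.integers(2, min(l, 9)))
            sig = rng.normal(size=l)
            _, expected = self.mtf_oracle(sig, n_bins)
            np.testing.assert_allclose(mtf(sig, n_bins).matrix, expected, atol=1e-14)

    def test_entries_in_unit_interval(self, rng):
        for _ in range(10):
            img = mtf(rng.normal(size=30), 5)
            assert img.matrix.min() >= 0 and img.matrix.max() <= 1

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            mtf(np.full(10, 2.0), 3)


class TestRecurrencePlot:
    def test_far_pair_gives_identity(self):
        np.testing.assert_array_equal(
            recurrence_plot(np.array([0.0, 1.0]), 0.5).matrix, np.eye(2)
        )

    def test_large_epsilon_all_ones(self, rng):
        sig = rng.normal(size=12)
        eps = sig.max() - sig.min()
        np.testing.assert_array_equal(recurrence_plot(sig, eps).matrix, np.ones((12, 12)))

    def test_derived_example(self):
        expected = [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        np.testing.assert_array_equal(
            recurrence_plot(np.array([0.0, 0.3, 1.0]), 0.5).matrix, expected
        )

    def test_binary_symmetric_unit_diagonal(self, rng):
        m = recurrence_plot(rng.normal(size=25), 0.3).matrix
        assert set(np.unique(m)) <= {0.0, 1.0}
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 1.0)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            recurrence_plot(np.array([0.0, 1.0]), -0.1)


class TestTransformRecord:
    def test_gadf_composition_is_antisymmetric(self):
        rec = RawRecord("ramp", np.linspace(0, 1, 10), "x")
        img = transform_record(rec, "GADF", l=4)
        assert img.matrix.shape == (4, 4)
        np.testing.assert_allclose(img.matrix + img.matrix.T, 0, atol=1e-15)

    def test_deterministic(self, rng):
        rec = RawRecord("r", rng.normal(size=300), "x")
        a = transform_record(rec, "GASF", l=16).matrix
        b = transform_record(rec, "GASF", l=16).matrix
        np.testing.assert_array_equal(a, b)

    def test_long_signal_gasf_invariants(self, rng):
        rec = RawRecord("bc", rng.normal(size=700), "x")
        img = transform_record(rec, "GASF", l=64)
        assert img.matrix.shape == (64, 64)
        np.testing.assert_array_equal(img.matrix, img.matrix.T)
        assert img.matrix.min() >= -1 - 1e-12 and img.matrix.max() <= 1 + 1e-12

    def test_length_invariance(self, rng):
        """Same shape at different raw lengths -> identical images."""
        base = rng.normal(size=16)
        rec_short = RawRecord("s", base, "x")
        rec_long = RawRecord("l", np.repeat(base, 5), "x")  # 5x oversampled
        for strat in ("GASF", "GADF", "MTF", "RP"):
            a = transform_record(rec_short, strat, l=16).matrix
            b = transform_record(rec_long, strat, l=16).matrix
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_unknown_strategy_rejected(self):
        rec = RawRecord("r", np.arange(10.0), "x")
        with pytest.raises(ValueError):
            transform_record(rec, "WAVELET", l=4)
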