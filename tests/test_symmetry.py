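import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitsf import (
    DegenerateRangeError,
    CurveParams,
    annotate_phases,
    classify_asymmetry,
    compute_sf,
    curve_range,
    parameterize,
    symmetry_function,
)
from gaitsf.errors import InputError
from gaitsf.symmetry import SFResult

from conftest import make_curve


def sf_oracle(x1, x2):
    """Direct loop transliteration of the SF definition."""
    r1 = max(x1) - min(x1)
    r2 = max(x2) - min(x2)
    return np.array(
        [(a - b) / (0.5 * (r1 + r2)) * 100.0 for a, b in zip(x1, x2)]
    )


def random_pair(rng):
    t = np.arange(101.0)
    def curve():
        vals = rng.normal(10, 3) + sum(
            rng.normal(0, 5) * np.cos(2 * np.pi * h * t / 100 + rng.uniform(0, 2 * np.pi))
            for h in range(1, 4)
        )
        return vals + rng.normal(0, 0.5, size=101)
    return make_curve(curve()), make_curve(curve())


class TestCurveRange:
    def test_constant_curve(self):
        assert curve_range(make_curve(np.full(101, 3.3))) == 0.0

    def test_span_matches_peaks(self):
        t = np.arange(101.0)
        vals = (34.6 + (-10.4)) / 2 + (34.6 - (-10.4)) / 2 * np.cos(2 * np.pi * t / 100)
        assert curve_range(make_curve(vals)) == pytest.approx(45.0)

    def test_sine_amplitude(self):
        t = np.arange(101.0)
        assert curve_range(make_curve(7 * np.sin(2 * np.pi * t / 100))) == pytest.approx(14.0, abs=1e-9)


class TestSymmetryFunction:
    @pytest.mark.parametrize("half_range, expected", [(2.5, 20.0), (25.0, 2.0)])
    def test_constant_offset_worked_examples(self, half_range, expected):
        """1 deg side difference reads 20% at mean ROM 5 deg, 2% at 50 deg."""
        t = np.arange(101.0)
        base = 10.0 + half_range * np.cos(2 * np.pi * t / 100)
        first = make_curve(base)
        second = make_curve(base - 1.0)
        sf = symmetry_function(first, second)
        np.testing.assert_allclose(sf.values, expected, atol=1e-12)

    def test_extreme_antiphase_reaches_200(self):
        """Equal-range curves spanning [0,R] and [-R,0] with coinciding
        extremes hit +/-200% at that instant."""
        t = np.arange(101.0)
        R = 30.0
        first = make_curve(R / 2 + R / 2 * np.cos(2 * np.pi * t / 100))   # [0, R], max at 0
        second = make_curve(-R / 2 + R / 2 * np.cos(2 * np.pi * (t - 50) / 100))  # [-R, 0], min at 0
        sf = symmetry_function(first, second)
        assert sf.values[0] == pytest.approx(200.0)
        flipped = symmetry_function(second, first)
        assert flipped.values[0] == pytest.approx(-200.0)

    def test_identical_curves_zero(self, cosine_curve):
        sf = symmetry_function(cosine_curve, cosine_curve)
        np.testing.assert_array_equal(sf.values, 0.0)

    def test_degenerate_range_raises(self):
        a = make_curve(np.full(101, 5.0))
        b = make_curve(np.full(101, 4.0))
        with pytest.raises(DegenerateRangeError):
            symmetry_function(a, b)

    def test_incomparable_curves_raise(self):
        a = make_curve(np.zeros(101))
        b = make_curve(np.linspace(0, 1, 50))
        with pytest.raises(InputError):
            symmetry_function(a, b)

    def test_labels_default_to_sides(self, cosine_curve):
        other = make_curve(cosine_curve.values - 1.0, side="left")
        sf = symmetry_function(cosine_curve, other)
        assert (sf.first_label, sf.second_label) == ("right", "left")


class TestSymmetryProperties:
    def test_antisymmetry(self, rng):
        for _ in range(50):
            a, b = random_pair(rng)
            ab = symmetry_function(a, b).values
            ba = symmetry_function(b, a).values
            np.testing.assert_allclose(ab, -ba, rtol=1e-12, atol=1e-12)

    def test_common_shift_invariance(self, rng):
        a, b = random_pair(rng)
        base = symmetry_function(a, b).values
        for c in (-40.0, 3.7, 220.0):
            shifted = symmetry_function(
                a.with_values(a.values + c), b.with_values(b.values + c)
            ).values
            np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-9)

    def test_common_scale_invariance(self, rng):
        a, b = random_pair(rng)
        base = symmetry_function(a, b).values
        for k in (0.01, 3.0, 1e4):
            scaled = symmetry_function(
                a.with_values(a.values * k), b.with_values(b.values * k)
            ).values
            np.testing.assert_allclose(scaled, base, rtol=1e-9, atol=1e-9)

    def test_one_sided_offset_law(self, rng):
        """Adding delta to one side shifts SF by the closed-form constant."""
        a, b = random_pair(rng)
        r1, r2 = curve_range(a), curve_range(b)
        base = symmetry_function(a, b).values
        for delta in (-5.0, 0.3, 12.0):
            shifted = symmetry_function(a.with_values(a.values + delta), b).values
            expected = base + delta / (0.5 * (r1 + r2)) * 100.0
            np.testing.assert_allclose(shifted, expected, rtol=1e-9, atol=1e-9)

    def test_brute_force_oracle_agreement(self, rng):
        for _ in range(200):
            a, b = random_pair(rng)
            sf = symmetry_function(a, b).values
            np.testing.assert_allclose(sf, sf_oracle(a.values, b.values), rtol=1e-9)


class TestParameterize:
    @pytest.mark.parametrize(
        "lo, hi, rom",
        [(-64.6, 44.3, 108.9), (-17.4, 15.9, 33.3), (-7.3, 31.4, 38.7)],
    )
    def test_rom_identity_on_sf_peaks(self, lo, hi, rom):
        """ROM = Peak^max - Peak^min, checked on realistic SF peak pairs."""
        t = np.arange(101.0)
        vals = (hi + lo) / 2 + (hi - lo) / 2 * np.cos(2 * np.pi * t / 100)
        p = parameterize(make_curve(vals))
        assert p.peak_max == pytest.approx(hi)
        assert p.peak_min == pytest.approx(lo)
        assert p.rom == pytest.approx(rom)
        assert p.rom == p.peak_max - p.peak_min

    def test_constant_curve_first_occurrence(self):
        p = parameterize(make_curve(np.full(101, 2.0)))
        assert p.rom == 0.0
        assert p.t_min == 0.0 and p.t_max == 0.0

    def test_first_occurrence_tie_break(self):
        vals = np.zeros(101)
        vals[[10, 60]] = 5.0
        vals[[20, 80]] = -3.0
        p = parameterize(make_curve(vals))
        assert p.t_max == 10.0 and p.t_min == 20.0

    def test_monotone_curve_endpoints(self):
        p = parameterize(make_curve(np.linspace(-3, 9, 101)))
        assert p.t_min == 0.0 and p.t_max == 100.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_rom_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        p = parameterize(make_curve(rng.normal(size=101)))
        assert p.rom == pytest.approx(p.peak_max - p.peak_min, abs=1e-9)
        assert 0.0 <= p.t_min <= 100.0 and 0.0 <= p.t_max <= 100.0


class TestClassification:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (5.0, "symmetric"),
            (9.99, "symmetric"),
            (10.0, "borderline"),
            (12.0, "borderline"),
            (14.99, "borderline"),
            (15.0, "asymmetric"),
            (40.0, "asymmetric"),
        ],
    )
    def test_peak_abs_thresholds(self, s, expected):
        params = CurveParams(peak_min=-s, t_min=10.0, peak_max=s / 2, t_max=60.0, rom=1.5 * s)
        assert classify_asymmetry(params, "peak_abs") == expected

    def test_mean_abs_statistic(self):
        from gaitsf import SFCurve

        sf_curve = SFCurve(values=np.full(101, 12.0), first_label="a", second_label="b")
        params = parameterize(sf_curve)
        assert classify_asymmetry(params, "mean_abs", curve=sf_curve) == "borderline"


class TestAnnotatePhases:
    @pytest.mark.parametrize(
        "t_min, t_max, phase_min, phase_max",
        [(8.0, 54.0, "LR", "TDSt"), (95.0, 20.0, "TSw", "MSt")],
    )
    def test_peak_phase_localisation(self, t_min, t_max, phase_min, phase_max):
        from gaitsf import SFCurve

        vals = np.zeros(101)
        vals[int(t_min)] = -50.0
        vals[int(t_max)] = 40.0
        curve = SFCurve(values=vals, first_label="a", second_label="b")
        result = annotate_phases(SFResult(curve=curve, params=parameterize(curve)))
        assert result.peak_phases[0].name == phase_min
        assert result.peak_phases[1].name == phase_max


class TestComputeSF:
    def test_full_pipeline_consistency(self, cosine_curve):
        other = make_curve(cosine_curve.values - 1.0, side="left")
        result = compute_sf(cosine_curve, other)
        np.testing.assert_allclose(result.curve.values, 20.0)
        assert result.classification == "asymmetric"
        assert result.peak_phases is not None
        assert result.params.rom == pytest.approx(0.0, abs=1e-12)
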