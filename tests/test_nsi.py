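"""NSI statistic: difference curve, trapezoid integral, pairing, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isolocate import (
    DifferenceCurve,
    Mobilogram,
    NormalizedMobilogram,
    difference_curve,
    integrate_nsi,
    nsi_pair,
    running_average,
)


def riemann_nsi(f_ref, f_iso, t0, t1, n=100_000):
    """Independent fine-grid oracle: midpoint Riemann sum of the absolute
    difference of the two analytically peak-normalized curves."""
    t = np.linspace(t0, t1, n)
    mid = (t[:-1] + t[1:]) / 2
    dt = t[1] - t[0]
    ref = f_ref(mid)
    iso = f_iso(mid)
    ref = 100 * ref / f_ref(np.linspace(t0, t1, 10 * n)).max()
    iso = 100 * iso / f_iso(np.linspace(t0, t1, 10 * n)).max()
    return float(np.sum(np.abs(ref - iso)) * dt)


class TestDifferenceCurve:
    def test_identity_gives_zero(self):
        t = np.linspace(40, 50, 51)
        a = NormalizedMobilogram(t, 100 * np.exp(-((t - 45) ** 2)))
        c = difference_curve(a, a)
        assert np.all(c.abs_d == 0)

    def test_signed_arithmetic(self):
        t = np.array([0.0, 1.0])
        ref = NormalizedMobilogram(t, [100.0, 0.0])
        iso = NormalizedMobilogram(t, [100.0, 100.0])
        c = difference_curve(ref, iso)
        assert c.d.tolist() == [0.0, -100.0]
        assert c.abs_d.tolist() == [0.0, 100.0]

    def test_swap_negates_d_not_abs(self):
        t = np.linspace(0, 5, 20)
        a = NormalizedMobilogram(t, 100 * np.exp(-((t - 2) ** 2)))
        b = NormalizedMobilogram(t, 100 * np.exp(-((t - 3) ** 2)))
        c1, c2 = difference_curve(a, b), difference_curve(b, a)
        assert np.allclose(c1.d, -c2.d)
        assert np.allclose(c1.abs_d, c2.abs_d)

    def test_mismatched_grids_instruct_alignment(self):
        a = NormalizedMobilogram([0.0, 1.0, 2.0], [0.0, 100.0, 0.0])
        b = NormalizedMobilogram([0.0, 1.1, 2.0], [0.0, 100.0, 0.0])
        with pytest.raises(ValueError, match="align"):
            difference_curve(a, b)


class TestIntegrateNSI:
    @pytest.mark.parametrize(
        "times,abs_d,expected",
        [
            ([0.0, 1.0], [0.0, 100.0], 50.0),
            ([0.0, 1.0, 2.0], [100.0, 100.0, 0.0], 150.0),
            ([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], 0.0),
        ],
    )
    def test_hand_trapezoid(self, times, abs_d, expected):
        c = DifferenceCurve(np.array(times), np.array(abs_d))
        assert integrate_nsi(c) == expected

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 time points"):
            integrate_nsi(DifferenceCurve(np.array([1.0]), np.array([5.0])))


class TestNSIPair:
    def test_identical_traces_zero(self, gaussian_trace):
        a = gaussian_trace()
        assert nsi_pair(a, gaussian_trace()).nsi == 0.0

    def test_scale_invariance(self, gaussian_trace):
        a = gaussian_trace(scale=1000.0)
        b = gaussian_trace(scale=3000.0)
        assert nsi_pair(a, b).nsi == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, gaussian_trace):
        a, b = gaussian_trace(center=42.0), gaussian_trace(center=43.5)
        assert nsi_pair(a, b).nsi == pytest.approx(nsi_pair(b, a).nsi, rel=1e-12)

    def test_triangular_shift_matches_riemann_oracle(self):
        # unit-width triangular peaks at 42 and 43 ms on a dense grid
        t = np.arange(38.0, 48.0, 0.002)

        def tri(center):
            return np.clip(1.0 - np.abs(t - center), 0.0, None) * 500.0

        ref = Mobilogram(t, tri(42.0) + 1e-9)
        iso = Mobilogram(t, tri(43.0) + 1e-9)
        oracle = riemann_nsi(
            lambda x: np.clip(1.0 - np.abs(x - 42.0), 0.0, None),
            lambda x: np.clip(1.0 - np.abs(x - 43.0), 0.0, None),
            38.0, 48.0)
        assert nsi_pair(ref, iso).nsi == pytest.approx(oracle, rel=1e-3)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_random_gaussian_mixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(35.0, 55.0, 0.01)

        def mixture():
            k = rng.integers(1, 4)
            cs = rng.uniform(40, 50, k)
            ss = rng.uniform(0.5, 2.0, k)
            ws = rng.uniform(0.2, 1.0, k)
            return lambda x: sum(
                w * np.exp(-0.5 * ((x - c) / s) ** 2)
                for c, s, w in zip(cs, ss, ws))

        f, g = mixture(), mixture()
        ref = Mobilogram(t, 1000 * f(t))
        iso = Mobilogram(t, 700 * g(t))
        oracle = riemann_nsi(f, g, 35.0, 55.0 - 0.01)
        assert nsi_pair(ref, iso).nsi == pytest.approx(oracle, rel=1e-3)

    def test_monotone_in_peak_separation(self, gaussian_trace):
        seps = np.linspace(0.0, 5.0, 26)  # 0 to 5 sigma
        vals = [nsi_pair(gaussian_trace(center=42.0),
                         gaussian_trace(center=42.0 + s)).nsi for s in seps]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_bound(self, gaussian_trace):
        a = gaussian_trace(center=40.0, sigma=0.3)
        b = gaussian_trace(center=50.0, sigma=0.3)
        span = a.times[-1] - a.times[0]
        assert nsi_pair(a, b).nsi <= 200.0 * span

    def test_charge_mismatch_is_error(self, gaussian_trace):
        a = gaussian_trace(meta={"charge": 1})
        b = gaussian_trace(center=43.0, meta={"charge": 2})
        with pytest.raises(ValueError, match="charge mismatch"):
            nsi_pair(a, b)

    def test_isotope_flag_mismatch_warns(self, gaussian_trace):
        a = gaussian_trace(meta={"isotopes_summed": True})
        b = gaussian_trace(center=43.0, meta={"isotopes_summed": False})
        with pytest.warns(UserWarning, match="isotopes_summed"):
            res = nsi_pair(a, b)
        assert res.warnings


class TestRunningAverage:
    def test_constant_series_unchanged(self, series_factory):
        s = running_average(series_factory([10, 10, 10, 10], fill_ra=False))
        assert all(v == 10 for v in s.running_avg.values())

    def test_three_point_mean(self, series_factory):
        s = running_average(series_factory([0, 30, 60], fill_ra=False))
        assert s.running_avg[2] == 30.0
        assert s.running_avg[1] == 15.0  # window shrinks at the start
        assert s.running_avg[3] == 45.0

    def test_gap_shrinks_window(self, series_factory):
        s = series_factory([1.0, 2.0, 4.0, 8.0], start_n=2, fill_ra=False)
        # observed n = 2,3,4,5; drop n=5 and add n=6 to make a gap at 5
        s = series_factory([1.0, 2.0, 4.0, None, 8.0], start_n=2, fill_ra=False)
        out = running_average(s)
        # at n=4 the window {3,4,5} only has observed members {3,4}
        assert out.running_avg[4] == pytest.approx((2.0 + 4.0) / 2)
        # at n=6 only {6} itself is observed (5 missing, 7 absent)
        assert out.running_avg[6] == 8.0
        assert 5 not in out.running_avg
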