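import numpy as np
import pytest
from hypothesis import given, strategies as st

import phosphagen as pg
from oracles import mad_flags_oracle


def make_trace(time, num, den, bg=100.0, stim=(0.0, 10.0)):
    n = time.size
    return pg.RatiometricTrace(
        time=time, signal_num=num, signal_den=den,
        background_num=np.full((2, n), bg), background_den=np.full((2, n), bg),
        stim_start=stim[0], stim_end=stim[1])


@pytest.fixture
def flat_time():
    return np.linspace(-30, 40, 281)  # 4 Hz


class TestDeltaROverR:
    def test_constant_channels_give_zero(self, flat_time):
        tr = make_trace(flat_time, np.full_like(flat_time, 1100.0),
                        np.full_like(flat_time, 600.0))
        np.testing.assert_allclose(pg.delta_r_over_r(tr), 0.0, atol=1e-12)

    def test_numerator_doubling_steps_to_one(self, flat_time):
        num = np.where(flat_time < 0, 1100.0, 2100.0)  # signal-bg: 1000 -> 2000
        tr = make_trace(flat_time, num, np.full_like(flat_time, 600.0))
        dr = pg.delta_r_over_r(tr)
        np.testing.assert_allclose(dr[flat_time < 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(dr[flat_time >= 0], 1.0, atol=1e-12)

    @given(gain=st.floats(0.1, 10.0))
    def test_common_mode_gain_invariance(self, gain):
        t = np.linspace(-30, 40, 281)
        rng = np.random.default_rng(0)
        num = 1000 + 50 * rng.standard_normal(t.size) + 100
        den = 800 + 30 * rng.standard_normal(t.size) + 100
        tr = make_trace(t, num, den)
        scaled = pg.RatiometricTrace(
            time=t, signal_num=gain * num, signal_den=gain * den,
            background_num=gain * tr.background_num,
            background_den=gain * tr.background_den,
            stim_start=0.0, stim_end=10.0)
        np.testing.assert_allclose(pg.delta_r_over_r(scaled),
                                   pg.delta_r_over_r(tr), rtol=1e-9, atol=1e-12)

    def test_degenerate_denominator_raises(self, flat_time):
        tr = make_trace(flat_time, np.full_like(flat_time, 1100.0),
                        np.full_like(flat_time, 50.0))  # below background
        with pytest.raises(pg.DegenerateTraceError):
            pg.delta_r_over_r(tr)


class TestBleachCorrect:
    def test_flat_prestimulus_is_identity(self, flat_time):
        # a flat baseline must come back flat (normalized to pre-stim mean 1)
        ratio = np.full_like(flat_time, 1.8)
        out = pg.bleach_correct(flat_time, ratio, stim_start=0.0)
        assert out.converged
        np.testing.assert_allclose(out.corrected[out.window_mask], 1.0,
                                   rtol=1e-6)

    def test_pure_exponential_flattens_to_one(self, flat_time):
        ratio = 2.0 * np.exp(-(flat_time - flat_time[0]) / 60.0)
        out = pg.bleach_correct(flat_time, ratio, stim_start=0.0,
                                with_offset=False)
        assert out.converged
        assert out.tau == pytest.approx(60.0, rel=1e-6)
        corrected = out.corrected[out.window_mask]
        np.testing.assert_allclose(corrected, 1.0, atol=1e-3)

    def test_bleach_plus_dip_amplitude_recovered(self, flat_time):
        t = flat_time
        dip = np.where((t >= 0) & (t <= 10), -0.2, 0.0)
        ratio = 1.5 * np.exp(-(t - t[0]) / 45.0) * (1.0 + dip)
        out = pg.bleach_correct(t, ratio, stim_start=0.0, with_offset=False)
        assert out.converged
        corrected = out.corrected
        in_dip = (t >= 1.0) & (t <= 9.0)
        np.testing.assert_allclose(corrected[in_dip] - 1.0, -0.2, atol=2e-3)

    def test_too_few_prestimulus_samples(self):
        t = np.linspace(-0.2, 40, 100)
        with pytest.raises(pg.InvalidParameterError):
            pg.bleach_correct(t, np.ones_like(t), stim_start=0.0, pre_window=0.1)


class TestMadOutlierFlags:
    def test_hand_computed_example(self):
        # median 3, MAD 1, bounds [0, 6] -> only 100 flagged
        flags = pg.mad_outlier_flags([1, 2, 3, 4, 100])
        assert list(flags) == [False, False, False, False, True]

    def test_tight_symmetric_set(self):
        assert not pg.mad_outlier_flags([-1, 0, 1]).any()

    def test_all_equal_none_flagged(self):
        assert not pg.mad_outlier_flags([5.0, 5.0, 5.0, 5.0]).any()

    def test_zero_mad_flags_non_median_with_warning(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            flags = pg.mad_outlier_flags([1.0, 1.0, 1.0, 9.0])
        assert list(flags) == [False, False, False, True]

    def test_boundary_values_kept(self):
        # median 0, MAD 1 -> bounds [-3, 3] inclusive
        flags = pg.mad_outlier_flags([-3.0, -1.0, 0.0, 1.0, 3.0])
        assert not flags.any()

    @given(st.integers(0, 1000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_t(df=3, size=rng.integers(3, 40)) * 5
        np.testing.assert_array_equal(pg.mad_outlier_flags(x),
                                      mad_flags_oracle(x))

    def test_screen_then_rescreen_idempotent(self):
        x = np.array([1.0, 2, 3, 4, 100])
        kept = x[~pg.mad_outlier_flags(x)]
        assert not pg.mad_outlier_flags(kept).any()

    def test_minimum_sample_size(self):
        with pytest.raises(pg.InvalidParameterError):
            pg.mad_outlier_flags([1.0, 2.0])


class TestQuantalContent:
    def test_negligible_correction(self):
        s = pg.AmplitudeSamples(ejp=np.full(10, 0.09), mejp=np.full(30, 0.01),
                                driving=90.0)  # EJP/driving = 0.001
        assert pg.quantal_content(s) == pytest.approx(9.0, rel=2e-3)

    def test_half_driving_doubles_corrected_mean(self):
        s = pg.AmplitudeSamples(ejp=np.full(10, 45.0), mejp=np.full(30, 1.0),
                                driving=90.0)
        # corrected mean = 45/(1-0.5) = 90 -> QC = 90
        assert pg.quantal_content(s) == pytest.approx(90.0, rel=1e-12)

    def test_ratio_identity(self):
        # mEJPs all equal to the corrected mean EJP -> QC is exactly 1
        v, driving = 10.0, 80.0
        corrected = v / (1 - v / driving)
        s = pg.AmplitudeSamples(ejp=np.full(10, v), mejp=np.full(30, corrected),
                                driving=driving)
        assert pg.quantal_content(s) == pytest.approx(1.0, rel=1e-12)

    def test_mejps_never_corrected(self):
        v = 30.0
        s1 = pg.AmplitudeSamples(ejp=np.full(5, v), mejp=np.full(10, 1.0),
                                 driving=90.0)
        s2 = pg.AmplitudeSamples(ejp=np.full(5, v), mejp=np.full(10, 2.0),
                                 driving=90.0)
        # doubling mEJP mean exactly halves QC (no correction applied to it)
        assert pg.quantal_content(s1) == pytest.approx(2 * pg.quantal_content(s2),
                                                       rel=1e-12)

    def test_driving_force_must_exceed_ejps(self):
        with pytest.raises(pg.InvalidParameterError):
            pg.AmplitudeSamples(ejp=np.full(5, 95.0), mejp=np.full(10, 1.0),
                                driving=90.0)
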