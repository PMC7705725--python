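"""Theta signal chain: decimation, equiripple band-pass, zero-phase
filtering, Hilbert phase, run gating, circular statistics, and the
two-stage pairwise offset estimate."""

import numpy as np
import pytest
from scipy import signal as sps

from lesionscope import (
    DegenerateCircularMeanError,
    FilterSpec,
    circular_distance,
    circular_mean,
    decimate_lfp,
    design_theta_bandpass,
    detect_run_periods,
    filtfilt_zero_phase,
    instantaneous_phase,
    pairwise_theta_offsets,
)
from lesionscope.synthetic_cohort import (
    LFPRecord,
    PhaseOffsetSpec,
    SpeedTrace,
    generate_lfp_session,
)

DEG = np.pi / 180.0


@pytest.fixture(scope="module")
def spec() -> FilterSpec:
    return design_theta_bandpass(FilterSpec())


class TestDecimateLfp:
    def test_dc_preserved(self):
        out = decimate_lfp(np.full(30000, 2.5), fs_in=30000)
        assert out.sampling_rate == 1500.0
        interior = out.data[0][100:-100]
        assert np.allclose(interior, 2.5, atol=1e-6)

    def test_theta_amplitude_preserved_within_one_percent(self):
        fs_in = 30000
        t = np.arange(20 * fs_in) / fs_in
        out = decimate_lfp(np.sin(2 * np.pi * 8.0 * t), fs_in=fs_in)
        y = out.data[0]
        tt = np.arange(y.size) / 1500.0
        design = np.column_stack([np.sin(2 * np.pi * 8 * tt), np.cos(2 * np.pi * 8 * tt)])
        sel = slice(1500, -1500)
        coef, *_ = np.linalg.lstsq(design[sel], y[sel], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, abs=0.01)

    def test_output_rate_is_exactly_1500(self):
        out = decimate_lfp(np.zeros(6000), fs_in=3000)
        assert out.sampling_rate == 1500.0
        assert out.n_samples == 3000

    def test_low_input_rate_rejected(self):
        with pytest.raises(ValueError, match="1500"):
            decimate_lfp(np.zeros(100), fs_in=1000)


class TestDesignThetaBandpass:
    def test_combined_passband_gain(self, spec):
        _, h = sps.freqz(spec.coefficients, worN=[8.0], fs=spec.fs)
        assert np.abs(h[0]) ** 2 >= 0.99

    def test_combined_stopband_leakage(self, spec):
        _, h = sps.freqz(spec.coefficients, worN=[1.0, 20.0], fs=spec.fs)
        assert (np.abs(h) ** 2 <= 0.01).all()

    def test_coefficients_symmetric(self, spec):
        assert np.allclose(spec.coefficients, spec.coefficients[::-1], atol=1e-12)

    def test_band_edge_ordering_enforced(self):
        with pytest.raises(ValueError, match="edges"):
            FilterSpec(pass_band=(4.0, 12.0), stop_edges=(3.0, 11.0))


class TestFiltfiltZeroPhase:
    def test_pure_theta_peaks_do_not_shift(self, spec):
        fs = spec.fs
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 8.0 * t)
        y = filtfilt_zero_phase(x, spec)
        sel = slice(int(5 * fs), int(25 * fs))
        lags = sps.correlation_lags(sel.stop - sel.start, sel.stop - sel.start)
        xc = sps.correlate(y[sel], x[sel])
        assert abs(lags[np.argmax(xc)]) < 1

    def test_commutes_with_time_reversal(self, spec, rng):
        x = rng.normal(size=4 * spec.numtaps)
        a = filtfilt_zero_phase(x[::-1], spec)
        b = filtfilt_zero_phase(x, spec)[::-1]
        assert np.allclose(a, b, atol=1e-9)

    def test_magnitude_response_is_single_pass_squared(self, spec):
        """Cross-spectral gain of the operator equals |H|^2 at theta."""
        fs = spec.fs
        t = np.arange(int(40 * fs)) / fs
        for f in (6.0, 8.0):
            x = np.sin(2 * np.pi * f * t)
            y = filtfilt_zero_phase(x, spec)
            sel = slice(int(10 * fs), int(30 * fs))
            amp = np.sqrt(2 * np.mean(y[sel] ** 2))
            _, h = sps.freqz(spec.coefficients, worN=[f], fs=fs)
            assert amp == pytest.approx(np.abs(h[0]) ** 2, rel=1e-3)

    def test_too_short_signal_rejected(self, spec):
        with pytest.raises(ValueError, match="too short"):
            filtfilt_zero_phase(np.zeros(spec.numtaps), spec)


class TestInstantaneousPhase:
    def test_unwrapped_phase_slope_matches_frequency(self):
        fs = 1500.0
        t = np.arange(int(20 * fs)) / fs
        phase = instantaneous_phase(np.cos(2 * np.pi * 8.0 * t))
        n = phase.size
        sel = slice(int(0.1 * n), int(0.9 * n))
        unwrapped = np.unwrap(phase)[sel]
        slope = np.polyfit(t[sel], unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 8.0, rel=1e-3)

    def test_sin_lags_cos_by_half_pi(self):
        fs = 1500.0
        t = np.arange(int(10 * fs)) / fs
        p_cos = instantaneous_phase(np.cos(2 * np.pi * 8 * t))
        p_sin = instantaneous_phase(np.sin(2 * np.pi * 8 * t))
        sel = slice(2000, -2000)
        d = np.angle(np.exp(1j * (p_sin[sel] - p_cos[sel])))
        assert np.allclose(d, -np.pi / 2, atol=1e-3)

    def test_output_range(self, rng):
        phase = instantaneous_phase(rng.normal(size=4096))
        assert (phase > -np.pi).all() and (phase <= np.pi).all()


class TestDetectRunPeriods:
    def test_constant_fast_speed_spans_session(self):
        speed = SpeedTrace(speed=np.full(250, 20.0), sampling_rate=25.0)
        periods = detect_run_periods(speed, lfp_rate=1500.0)
        assert periods.intervals == [(0, 15000)]

    def test_constant_slow_speed_gives_no_periods(self):
        speed = SpeedTrace(speed=np.full(250, 5.0), sampling_rate=25.0)
        assert len(detect_run_periods(speed, lfp_rate=1500.0)) == 0

    def test_square_wave_boundaries_exact(self):
        """20 cm/s and 0 cm/s alternating every 10 s at 25 Hz."""
        block = np.r_[np.full(250, 20.0), np.zeros(250)]
        speed = SpeedTrace(speed=np.tile(block, 3), sampling_rate=25.0)
        periods = detect_run_periods(speed, lfp_rate=1500.0)
        expected = [(0, 15000), (30000, 45000), (60000, 75000)]
        assert periods.intervals == expected

    def test_short_bursts_dropped(self):
        speed = np.zeros(250)
        speed[100:110] = 20.0  # 0.4 s burst
        periods = detect_run_periods(
            SpeedTrace(speed=speed, sampling_rate=25.0), lfp_rate=1500.0, min_duration=1.0
        )
        assert len(periods) == 0

    def test_threshold_is_strict(self):
        speed = SpeedTrace(speed=np.full(250, 10.0), sampling_rate=25.0)
        assert len(detect_run_periods(speed, lfp_rate=1500.0, threshold=10.0)) == 0


class TestCircularMean:
    def test_equal_angles(self):
        assert circular_mean([0.0, 0.0]) == 0.0

    def test_symmetric_pair(self):
        assert circular_mean([0.0, np.pi / 2]) == pytest.approx(np.pi / 4)

    def test_wraps_across_pi(self):
        assert circular_mean([np.pi - 0.1, -np.pi + 0.1]) == pytest.approx(
            np.pi, abs=1e-9
        ) or abs(circular_mean([np.pi - 0.1, -np.pi + 0.1])) == pytest.approx(np.pi, abs=1e-9)

    def test_antipodal_angles_degenerate(self):
        with pytest.raises(DegenerateCircularMeanError) as exc:
            circular_mean([-np.pi / 2, np.pi / 2])
        assert exc.value.resultant < 1e-9


class TestPairwiseThetaOffsets:
    @pytest.fixture(scope="class")
    def session(self):
        spec = PhaseOffsetSpec(offsets=[0.0, 30 * DEG], snr=10.0, duration=600.0)
        return generate_lfp_session(spec, seed=3)

    def test_thirty_degree_offset_recovered_within_two_degrees(self, session):
        lfp, speed = session
        result = pairwise_theta_offsets(lfp, speed)
        assert circular_distance(result.offsets[1, 0], 30 * DEG) < 2 * DEG

    def test_self_offset_zero_and_antisymmetry(self, session):
        lfp, speed = session
        result = pairwise_theta_offsets(lfp, speed)
        assert np.allclose(np.diag(result.offsets), 0.0)
        wrap = lambda a: np.angle(np.exp(1j * a))
        assert np.allclose(
            wrap(result.offsets + result.offsets.T), 0.0, atol=1e-12
        )

    def test_no_run_periods_rejected(self, session):
        lfp, _ = session
        still = SpeedTrace(speed=np.zeros(int(lfp.duration * 25)), sampling_rate=25.0)
        with pytest.raises(ValueError, match="running"):
            pairwise_theta_offsets(lfp, still)

    def test_single_channel_rejected(self, session):
        lfp, speed = session
        mono = LFPRecord(data=lfp.data[:1], sampling_rate=lfp.sampling_rate)
        with pytest.raises(ValueError, match="2 channels"):
            pairwise_theta_offsets(mono, speed)

    def test_still_period_artifacts_do_not_move_estimates(self, session):
        """Gating: huge artifacts confined to still epochs are invisible."""
        lfp, speed = session
        base = pairwise_theta_offsets(lfp, speed)
        noisy = lfp.data.copy()
        fs = lfp.sampling_rate
        # the default schedule is 20 s run / 10 s still; hit still centers
        cycle, run_len = 30.0, 20.0
        t0 = 0.0
        while t0 + cycle <= lfp.duration:
            mid = int((t0 + run_len + 5.0) * fs)
            noisy[:, mid - 1500 : mid + 1500] += 50.0 * np.sin(
                2 * np.pi * 7.0 * np.arange(3000) / fs
            )
            t0 += cycle
        perturbed = pairwise_theta_offsets(
            LFPRecord(data=noisy, sampling_rate=fs), speed
        )
        assert circular_distance(base.offsets[1, 0], perturbed.offsets[1, 0]) < 0.5 * DEG

    def test_two_stage_average_differs_from_pooled_when_periods_unbalanced(self):
        """Periods of 10x different length with different true offsets: the
        per-period-then-across-period mean weighs them equally, the pooled
        mean does not, and the two disagree by > 5 degrees."""
        fs = 1500.0
        f = 8.0
        long_s, gap_s, short_s = 200.0, 10.0, 20.0
        n_long, n_gap, n_short = (int(s * fs) for s in (long_s, gap_s, short_s))
        n = n_long + n_gap + n_short
        t = np.arange(n) / fs
        ch0 = np.sin(2 * np.pi * f * t)
        delta = np.zeros(n)
        delta[n_long + n_gap :] = 40 * DEG  # offset switches during the gap
        ch1 = np.sin(2 * np.pi * f * t - delta)
        speed = np.zeros(int(np.ceil(n / fs * 25)))
        speed[: int(long_s * 25)] = 20.0
        speed[int((long_s + gap_s) * 25) :] = 20.0
        lfp = LFPRecord(data=np.vstack([ch0, ch1]), sampling_rate=fs)
        trace = SpeedTrace(speed=speed, sampling_rate=25.0)

        result = pairwise_theta_offsets(lfp, trace)
        assert result.per_period.shape[0] == 2
        two_stage = result.offsets[0, 1]
        durations = result.period_durations
        pooled = np.angle(
            np.sum(durations * np.exp(1j * result.per_period[:, 0, 1]))
        )
        assert circular_distance(two_stage, pooled) > 5 * DEG
        # the equal-weight definition sits near the midpoint of 0 and 40 deg
        assert circular_distance(two_stage, 20 * DEG) < 3 * DEG
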