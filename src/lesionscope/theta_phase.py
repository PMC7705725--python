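"""LFP theta phase-offset estimation.

The signal chain mirrors standard hippocampal practice: the LFP is
anti-alias low-pass filtered below 400 Hz and down-sampled to 1.5 kHz;
theta is extracted with a Parks-McClellan optimal equiripple FIR band-pass
(pass band 4-10 Hz, stop bands below 3 Hz and above 11 Hz) applied in the
forward and reverse directions so no phase distortion remains;
instantaneous phase is the angle of the Hilbert-transformed theta signal.
Analysis is restricted to running periods (body speed > 10 cm/s).  The
pairwise phase difference is the angle between the two channels' unit
phase vectors; it is averaged with a two-stage circular mean -- first over
time within each running period, then (unweighted) over the per-period
means -- to give the session phase-offset matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

from .synthetic_cohort import LFPRecord, SpeedTrace

__all__ = [
    "FilterSpec",
    "RunPeriods",
    "PhaseOffsetMatrix",
    "DegenerateCircularMeanError",
    "decimate_lfp",
    "design_theta_bandpass",
    "filtfilt_zero_phase",
    "instantaneous_phase",
    "detect_run_periods",
    "circular_mean",
    "pairwise_theta_offsets",
]

LFP_RATE = 1500.0
SPEED_THRESHOLD = 10.0  # cm/s


class DegenerateCircularMeanError(ValueError):
    """Circular mean undefined: near-zero resultant vector."""

    def __init__(self, resultant: float):
        self.resultant = resultant
        super().__init__(f"degenerate circular mean (resultant length {resultant:.3g})")


@dataclass(frozen=True)
class FilterSpec:
    """Equiripple theta band-pass design parameters and coefficients.

    ``pass_ripple`` / ``stop_ripple`` are single-pass linear deviations;
    the default stop ripple 0.01 gives a 40 dB single-pass (80 dB combined)
    stop band, and pass ripple 0.0025 keeps the combined (squared) pass
    band gain above 0.99.
    """

    fs: float = LFP_RATE
    pass_band: tuple[float, float] = (4.0, 10.0)
    stop_edges: tuple[float, float] = (3.0, 11.0)
    pass_ripple: float = 0.0025
    stop_ripple: float = 0.01
    numtaps: int | None = None
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.stop_edges[0] < self.pass_band[0] < self.pass_band[1] < self.stop_edges[1]):
            raise ValueError("band edges must satisfy stop_lo < pass_lo < pass_hi < stop_hi")
        if self.coefficients is not None:
            b = np.asarray(self.coefficients, dtype=float)
            if not np.allclose(b, b[::-1], atol=1e-12):
                raise ValueError("coefficients must be symmetric (linear phase)")
            object.__setattr__(self, "coefficients", b)


def _estimate_numtaps(spec: FilterSpec) -> int:
    """Kaiser-style equiripple order estimate for the narrower transition."""
    df = min(spec.pass_band[0] - spec.stop_edges[0], spec.stop_edges[1] - spec.pass_band[1])
    n = (-20 * np.log10(np.sqrt(spec.pass_ripple * spec.stop_ripple)) - 13) / (
        14.6 * df / spec.fs
    )
    n = int(np.ceil(n))
    return n + 1 if n % 2 == 0 else n  # odd => type-I symmetric


_DESIGN_CACHE: dict[tuple, FilterSpec] = {}


def design_theta_bandpass(spec: FilterSpec | None = None) -> FilterSpec:
    """Design the equiripple FIR and verify it meets the spec.

    The tap count comes from the standard order-estimation formula; the
    realized single-pass response is then checked (pass-band gain and
    stop-band leakage) and the order bumped up to twice the estimate if
    needed.  Raises if the spec is unattainable within that cap.
    """
    spec = spec or FilterSpec()
    key = (spec.fs, spec.pass_band, spec.stop_edges, spec.pass_ripple, spec.stop_ripple,
           spec.numtaps)
    if key in _DESIGN_CACHE:
        return _DESIGN_CACHE[key]
    n0 = spec.numtaps or _estimate_numtaps(spec)
    bands = [0.0, spec.stop_edges[0], spec.pass_band[0], spec.pass_band[1],
             spec.stop_edges[1], spec.fs / 2.0]
    weights = [1.0 / spec.stop_ripple, 1.0 / spec.pass_ripple, 1.0 / spec.stop_ripple]
    numtaps = n0
    while True:
        b = sps.remez(numtaps, bands, [0.0, 1.0, 0.0], weight=weights, fs=spec.fs)
        check = np.array([1.0, spec.stop_edges[0], *spec.pass_band,
                          np.mean(spec.pass_band), spec.stop_edges[1], 2 * spec.stop_edges[1]])
        _, h = sps.freqz(b, worN=check, fs=spec.fs)
        mag = np.abs(h)
        stop_ok = max(mag[0], mag[1], mag[5], mag[6]) <= 1.5 * spec.stop_ripple
        pass_ok = min(mag[2], mag[3], mag[4]) >= 1.0 - 1.5 * spec.pass_ripple
        if stop_ok and pass_ok:
            break
        if numtaps > 2 * n0:
            raise RuntimeError("equiripple spec unattainable at the order cap")
        numtaps = int(numtaps * 1.1) | 1
    out = replace(spec, numtaps=numtaps, coefficients=b)
    _DESIGN_CACHE[key] = out
    return out


def decimate_lfp(raw: np.ndarray | LFPRecord, fs_in: float | None = None) -> LFPRecord:
    """Anti-alias low-pass below 400 Hz, then resample to 1.5 kHz.

    ``fs_in`` must be an integer rate >= 1500 (rational resampling).  The
    anti-alias filter is a zero-phase symmetric FIR with 400 Hz cutoff;
    the polyphase resampler contributes its own guard filter.
    """
    if isinstance(raw, LFPRecord):
        data, fs_in = raw.data, raw.sampling_rate
    else:
        data = np.atleast_2d(np.asarray(raw, dtype=float))
    if fs_in is None:
        raise ValueError("fs_in required for bare arrays")
    if fs_in < LFP_RATE:
        raise ValueError("input rate below 1500 Hz cannot be decimated to 1500 Hz")
    if fs_in == LFP_RATE:
        return LFPRecord(data=data, sampling_rate=LFP_RATE)
    if abs(fs_in - round(fs_in)) > 1e-9:
        raise ValueError("fs_in must be an integer sampling rate")

    numtaps = (2 * int(fs_in / 150)) | 1
    b = sps.firwin(numtaps, 400.0, fs=fs_in)
    half = numtaps // 2
    filtered = np.empty_like(data)
    for c in range(data.shape[0]):
        filtered[c] = sps.oaconvolve(data[c], b, mode="full")[half : half + data.shape[1]]
    frac = Fraction(int(LFP_RATE), int(round(fs_in)))
    out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return LFPRecord(data=out, sampling_rate=LFP_RATE)


def filtfilt_zero_phase(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-reverse FIR filtering with no net phase shift.

    The signal is reflect-padded by 3x the tap count, filtered causally,
    reversed, filtered again and reversed back; the squared magnitude
    response is applied with zero phase.  Works on 1D signals or
    channels x samples arrays.  Requires the signal to be longer than 3x
    the tap count.
    """
    if spec.coefficients is None:
        spec = design_theta_bandpass(spec)
    b = spec.coefficients
    ntaps = len(b)
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    n = arr.shape[1]
    padlen = 3 * ntaps
    if n <= padlen:
        raise ValueError(f"signal too short for zero-phase filtering (need > {padlen} samples)")
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        xp = np.pad(arr[c], padlen, mode="reflect")
        y = sps.oaconvolve(xp, b, mode="full")[: xp.size]
        y = y[::-1]
        y = sps.oaconvolve(y, b, mode="full")[: xp.size]
        y = y[::-1]
        out[c] = y[padlen : padlen + n]
    return out[0] if single else out


def instantaneous_phase(theta_signal: np.ndarray) -> np.ndarray:
    """Phase of the analytic (Hilbert-transformed) signal, in (-pi, pi]."""
    arr = np.asarray(theta_signal, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    n = arr.shape[1]
    nfft = next_fast_len(n)
    analytic = sps.hilbert(arr, N=nfft, axis=1)[:, :n]
    phase = np.angle(analytic)
    phase[phase == -np.pi] = np.pi
    return phase[0] if single else phase


@dataclass
class RunPeriods:
    """Disjoint, sorted half-open [start, end) intervals in LFP samples."""

    intervals: list[tuple[int, int]]
    sampling_rate: float = LFP_RATE

    def __post_init__(self) -> None:
        for (s0, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("run periods must be disjoint and sorted")
        if any(e <= s for s, e in self.intervals):
            raise ValueError("run periods must be non-empty")

    @property
    def durations(self) -> np.ndarray:
        return np.array([(e - s) / self.sampling_rate for s, e in self.intervals])

    def __len__(self) -> int:
        return len(self.intervals)


def detect_run_periods(
    speed: SpeedTrace,
    lfp_rate: float = LFP_RATE,
    threshold: float = SPEED_THRESHOLD,
    min_duration: float = 1.0,
) -> RunPeriods:
    """Maximal intervals with body speed strictly above threshold.

    Boundaries are found at the speed trace's own rate, converted to LFP
    sample indices (half-open [start, end)), and intervals shorter than
    ``min_duration`` seconds are dropped.
    """
    above = speed.speed > threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        starts = np.r_[0, starts]
    if above.size and above[-1]:
        ends = np.r_[ends, above.size]
    ratio = lfp_rate / speed.sampling_rate
    intervals = []
    for s, e in zip(starts, ends):
        s_lfp, e_lfp = int(round(s * ratio)), int(round(e * ratio))
        if (e_lfp - s_lfp) / lfp_rate >= min_duration:
            intervals.append((s_lfp, e_lfp))
    return RunPeriods(intervals=intervals, sampling_rate=lfp_rate)


def circular_mean(angles: np.ndarray, tol: float = 1e-9) -> float:
    """Angle of the mean resultant vector, in (-pi, pi].

    Raises :class:`DegenerateCircularMeanError` when the resultant length
    falls below ``tol`` (e.g. antipodal angles), reporting the length.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("circular mean of an empty set")
    z = np.exp(1j * a).mean()
    r = float(np.abs(z))
    if r < tol:
        raise DegenerateCircularMeanError(r)
    ang = float(np.angle(z))
    return np.pi if ang == -np.pi else ang


@dataclass
class PhaseOffsetMatrix:
    """Pairwise session theta offsets (radians, (-pi, pi])."""

    offsets: np.ndarray          # (c, c)
    resultant: np.ndarray        # (c, c) across-period resultant length
    per_period: np.ndarray       # (n_periods, c, c)
    period_durations: np.ndarray
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)
    reference_channel: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(np.diag(self.offsets), 0.0):
            raise ValueError("self-offsets must be zero")

    @property
    def n_channels(self) -> int:
        return self.offsets.shape[0]

    def relative_to_reference(self) -> np.ndarray:
        return self.offsets[:, self.reference_channel]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        c = self.n_channels
        for i in range(c):
            for j in range(i + 1, c):
                rows.append(
                    {"ch_i": i, "ch_j": j, "offset_rad": self.offsets[i, j],
                     "resultant": self.resultant[i, j]}
                )
        return pd.DataFrame(rows)


def _wrap(a: np.ndarray | float):
    out = np.mod(np.asarray(a) + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out


def pairwise_theta_offsets(
    lfp: LFPRecord,
    speed: SpeedTrace,
    spec: FilterSpec | None = None,
    threshold: float = SPEED_THRESHOLD,
    min_duration: float = 1.0,
    amplitude_weighted: bool = False,
    reference_channel: int = 0,
) -> PhaseOffsetMatrix:
    """Session phase-offset matrix via the two-stage circular mean.

    Per pair, the instantaneous difference is the angle of
    ``exp(i phi_a) * exp(-i phi_b)``; its circular mean is taken over time
    within each running period, and the session offset is the unweighted
    circular mean of the per-period means.  ``amplitude_weighted=True``
    weights the instantaneous phasors by the product of the two channels'
    analytic amplitudes instead of using unit phasors.
    """
    if lfp.n_channels < 2:
        raise ValueError("need at least 2 channels")
    spec = spec or FilterSpec(fs=lfp.sampling_rate)
    if spec.fs != lfp.sampling_rate:
        raise ValueError("filter spec sampling rate does not match the LFP")
    spec = design_theta_bandpass(spec)

    theta = filtfilt_zero_phase(lfp.data, spec)
    nfft = next_fast_len(theta.shape[1])
    analytic = sps.hilbert(theta, N=nfft, axis=1)[:, : theta.shape[1]]
    if amplitude_weighted:
        phasors = analytic
    else:
        phasors = analytic / np.abs(analytic)

    periods = detect_run_periods(speed, lfp.sampling_rate, threshold, min_duration)
    if len(periods) == 0:
        raise ValueError("no running periods: phase offsets undefined")

    c = lfp.n_channels
    per_period = np.zeros((len(periods), c, c))
    # per-period circular means of the pairwise phase differences
    for p, (s, e) in enumerate(periods.intervals):
        seg = phasors[:, s:e]
        m = seg @ seg.conj().T / seg.shape[1]  # mean of z_i * conj(z_j)
        per_period[p] = _wrap(np.angle(m))
        np.fill_diagonal(per_period[p], 0.0)

    z = np.exp(1j * per_period).mean(axis=0)
    offsets = _wrap(np.angle(z))
    np.fill_diagonal(offsets, 0.0)
    resultant = np.abs(z)
    degenerate = [
        (i, j)
        for i in range(c)
        for j in range(i + 1, c)
        if resultant[i, j] < 1e-9
    ]
    return PhaseOffsetMatrix(
        offsets=offsets,
        resultant=resultant,
        per_period=per_period,
        period_durations=periods.durations,
        degenerate_pairs=degenerate,
        reference_channel=reference_channel,
    )


def circular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Absolute circular distance |a - b| wrapped into [0, pi]."""
    return np.abs(_wrap(np.asarray(a) - np.asarray(b)))
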