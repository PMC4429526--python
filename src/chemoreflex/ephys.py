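"""Quantification of integrated nerve recordings (phrenic C4 root).

Raw nerve signals are full-wave rectified and passed through a leaky
integrator (time constant 50 ms by default), emulating the analog integrator
of the acquisition chain.  On the integrated envelope the module detects
inspiratory bursts, measures their kinetics (amplitude, time to peak,
half-width, decay time), computes pH-challenge frequency changes, classifies
photostimulation trials as evoked or failed with their latencies, and
quantifies entrainment of the motor rhythm to periodic light pulses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NerveTrace",
    "Burst",
    "StimEvent",
    "StimResponse",
    "integrate_trace",
    "rolling_baseline",
    "detect_bursts",
    "burst_parameters",
    "frequency_change",
    "classify_evoked",
    "entrainment_analysis",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NerveTrace:
    """A sampled nerve signal; ``integrated`` marks a rectified envelope."""

    values: np.ndarray
    sample_rate: float
    integrated: bool = False
    tau_ms: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.integrated and (self.values < -1e-12).any():
            raise ValueError("an integrated trace must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


@dataclass
class Burst:
    """A detected burst with its kinetic parameters (times in s, kinetics ms)."""

    onset: float
    peak_time: float
    end: float
    amplitude: float | None = None
    time_to_peak_ms: float | None = None
    half_width_ms: float | None = None
    decay_time_ms: float | None = None
    censored: bool = False


@dataclass(frozen=True)
class StimEvent:
    """A light pulse: onset (s), duration (ms), and how it was triggered."""

    onset: float
    duration_ms: float = 70.0
    trigger_rule: Literal["fixed_delay_after_burst", "periodic", "random"] = (
        "fixed_delay_after_burst"
    )


@dataclass
class StimResponse:
    stim: StimEvent
    evoked: bool
    latency_ms: float | None = None
    matched_burst: Burst | None = None


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate_trace(raw: NerveTrace, tau_ms: float = 50.0) -> NerveTrace:
    """Full-wave rectify and leaky-integrate a raw nerve signal.

    Discrete first-order exponential smoothing with alpha = dt/tau emulates an
    analog RC integrator: a unit step reaches 1 - 1/e of its asymptote after
    one time constant.  The output is nonnegative and linear in the input
    magnitude.
    """
    if tau_ms <= 0:
        raise ValueError("tau must be positive")
    dt = 1.0 / raw.sample_rate
    alpha = dt / (tau_ms / 1000.0)
    if alpha >= 1:
        raise ValueError("sample rate too low for this time constant")
    x = np.abs(raw.values)
    y = np.empty_like(x)
    # y[n] = y[n-1] + alpha * (x[n] - y[n-1]); vectorized via lfilter
    from scipy.signal import lfilter

    y = lfilter([alpha], [1.0, -(1.0 - alpha)], x)
    return NerveTrace(values=y, sample_rate=raw.sample_rate, integrated=True, tau_ms=tau_ms)


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------


def rolling_baseline(values: np.ndarray, sample_rate: float, window_s: float = 10.0) -> np.ndarray:
    """Rolling-median baseline, computed on a decimated copy for speed."""
    n = len(values)
    step = max(1, n // 2000)
    coarse = pd.Series(values[::step])
    win = max(3, int(round(window_s * sample_rate / step)))
    med = coarse.rolling(win, min_periods=1, center=True).median().to_numpy()
    return np.interp(np.arange(n), np.arange(0, n, step), med)


def detect_bursts(
    trace: NerveTrace,
    k_threshold: float = 3.0,
    min_duration_ms: float = 50.0,
    refractory_ms: float = 300.0,
    baseline_window_s: float = 10.0,
) -> list[Burst]:
    """Detect bursts as maximal supra-threshold intervals of the envelope.

    The threshold is baseline + ``k_threshold`` robust SDs (1.4826 MAD of the
    baseline-subtracted trace); intervals shorter than ``min_duration_ms`` are
    dropped and intervals separated by less than ``refractory_ms`` are merged.
    Kinetic parameters are filled in by :func:`burst_parameters`.
    """
    if not trace.integrated:
        raise ValueError("burst detection expects an integrated trace")
    x = trace.values
    fs = trace.sample_rate
    baseline = rolling_baseline(x, fs, baseline_window_s)
    resid = x - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma == 0:
        sigma = 1e-3 * max(np.ptp(x), np.finfo(float).eps)
    thresh = baseline + k_threshold * sigma

    above = x > thresh
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]

    # drop sub-threshold-duration runs, then merge runs separated by less
    # than the refractory period
    min_len = int(round(min_duration_ms / 1000.0 * fs))
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]
    gap = int(round(refractory_ms / 1000.0 * fs))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    bursts = []
    for s, e in merged:
        peak = s + int(np.argmax(x[s:e]))
        b = Burst(onset=s / fs, peak_time=peak / fs, end=e / fs)
        burst_parameters(trace, b, baseline=baseline)
        bursts.append(b)
    return bursts


def _cross_time(x: np.ndarray, i0: int, i1: int, level: float, fs: float, forward: bool) -> float | None:
    """Sub-sample time where x crosses below ``level`` scanning from a peak."""
    idx = range(i0, i1) if forward else range(i0, i1, -1)
    prev = i0
    for i in idx:
        if x[i] <= level:
            # linear interpolation between the bracketing samples
            j = i - 1 if forward else i + 1
            if x[j] == x[i]:
                return i / fs
            frac = (x[j] - level) / (x[j] - x[i])
            return (j + frac * (i - j)) / fs
        prev = i
    return None


def burst_parameters(
    trace: NerveTrace,
    burst: Burst,
    baseline: np.ndarray | None = None,
    decay_criterion: Literal["1/e", "half"] = "1/e",
) -> Burst:
    """Measure amplitude, time to peak, half-width and decay time of a burst.

    amplitude = peak - baseline; time_to_peak = peak - onset; half_width is
    the width at 50% amplitude (sub-sample interpolated); decay_time is the
    time from the peak to 1/e of the amplitude (or 50% with
    ``decay_criterion="half"``).  The onset is refined by back-extrapolating
    the rising edge (20% and 50% crossings projected to baseline), which
    removes the late bias of a plain threshold crossing.  Bursts clipped by
    the trace edges are marked censored.
    """
    x = trace.values
    fs = trace.sample_rate
    if baseline is None:
        baseline = rolling_baseline(x, fs)
    ip = int(round(burst.peak_time * fs))
    b0 = baseline[ip]
    amp = x[ip] - b0
    burst.amplitude = float(amp)
    t20 = _cross_time(x, ip, -1, b0 + 0.2 * amp, fs, forward=False)
    t50_rise = _cross_time(x, ip, -1, b0 + 0.5 * amp, fs, forward=False)
    if t20 is not None and t50_rise is not None and t50_rise > t20:
        onset_ref = t20 - (t50_rise - t20) * (0.2 / 0.3)
        if 0.0 <= onset_ref <= burst.peak_time:
            burst.onset = onset_ref
    burst.time_to_peak_ms = 1000.0 * (burst.peak_time - burst.onset)

    half = b0 + 0.5 * amp
    decay_level = b0 + (amp / math.e if decay_criterion == "1/e" else 0.5 * amp)
    t_left = _cross_time(x, ip, -1, half, fs, forward=False)
    t_right = _cross_time(x, ip, len(x), half, fs, forward=True)
    t_decay = _cross_time(x, ip, len(x), decay_level, fs, forward=True)
    if t_left is None or t_right is None or t_decay is None:
        burst.censored = True
    if t_left is not None and t_right is not None:
        burst.half_width_ms = 1000.0 * (t_right - t_left)
    if t_decay is not None:
        burst.decay_time_ms = 1000.0 * (t_decay - burst.peak_time)
    return burst


# ---------------------------------------------------------------------------
# Frequency change and evoked-response classification
# ---------------------------------------------------------------------------


def frequency_change(
    bursts_a: Sequence,
    bursts_b: Sequence,
    interval_a: float,
    interval_b: float,
) -> float:
    """Percent change of burst frequency between two conditions.

    Delta = 100 * (f_b - f_a) / f_a with f = count / interval.  NaN when the
    reference frequency is zero (undefined).
    """
    if interval_a <= 0 or interval_b <= 0:
        raise ValueError("intervals must be positive")
    f_a = len(bursts_a) / interval_a
    f_b = len(bursts_b) / interval_b
    if f_a == 0:
        return math.nan
    return 100.0 * (f_b - f_a) / f_a


def classify_evoked(
    bursts: Sequence[Burst],
    stims: Sequence[StimEvent],
    response_window_s: float = 2.0,
) -> tuple[list[StimResponse], float]:
    """Label each stimulation as evoked or failed; report the success rate.

    A stimulus is evoked iff the first burst onset after the stimulus onset
    falls within ``response_window_s``.  (Under the fixed 4 s post-burst delay
    rule the trigger burst precedes the stimulus and cannot be matched.)
    Returns the responses and the success rate in percent.
    """
    if response_window_s <= 0:
        raise ValueError("response window must be positive")
    onsets = [s.onset for s in stims]
    if sorted(onsets) != onsets:
        raise ValueError("stimulations must be sorted by onset")
    for a, b in zip(stims[:-1], stims[1:]):
        if a.onset + response_window_s > b.onset:
            raise ValueError("overlapping stimulation windows (protocol violation)")
    burst_onsets = np.array([b.onset for b in bursts])
    order = np.argsort(burst_onsets)
    burst_onsets = burst_onsets[order]
    sorted_bursts = [bursts[i] for i in order]

    responses = []
    for stim in stims:
        i = int(np.searchsorted(burst_onsets, stim.onset, side="right"))
        if i < len(burst_onsets) and burst_onsets[i] <= stim.onset + response_window_s:
            lat = 1000.0 * (burst_onsets[i] - stim.onset)
            responses.append(
                StimResponse(stim=stim, evoked=True, latency_ms=lat, matched_burst=sorted_bursts[i])
            )
        else:
            responses.append(StimResponse(stim=stim, evoked=False))
    n_evoked = sum(r.evoked for r in responses)
    success_rate = 100.0 * n_evoked / len(stims) if stims else math.nan
    return responses, success_rate


def entrainment_analysis(
    bursts: Sequence[Burst],
    stims: Sequence[StimEvent],
    response_window_s: float | None = None,
    period_tolerance: float = 1e-3,
) -> dict:
    """Entrainment of the motor rhythm to periodic light pulses.

    Requires >= 5 periodic stimuli (inter-stimulus intervals equal to within
    ``period_tolerance`` fractional jitter).  A cycle is "followed" when
    exactly one burst onset falls within the response window after its
    stimulus (window defaults to the stimulation period).  Phases are
    (burst onset - stim onset) / period; the circular mean and the resultant
    length R (1 = perfectly locked) are reported.
    """
    onsets = np.array([s.onset for s in stims])
    if len(onsets) < 5:
        raise ValueError("need at least 5 stimulation cycles")
    intervals = np.diff(onsets)
    period = float(intervals.mean())
    if period <= 0 or (np.abs(intervals - period) / period).max() > period_tolerance:
        raise ValueError("stimulation train is not periodic")
    window = period if response_window_s is None else response_window_s
    burst_onsets = np.sort([b.onset for b in bursts])

    followed = 0
    phases = []
    for t in onsets:
        in_win = burst_onsets[(burst_onsets > t) & (burst_onsets <= t + window)]
        if len(in_win) == 1:
            followed += 1
            phases.append((in_win[0] - t) / period)
    followed_fraction = followed / len(onsets)
    if phases:
        ang = 2 * np.pi * np.asarray(phases)
        z = np.exp(1j * ang).mean()
        mean_phase = float(np.angle(z) / (2 * np.pi) % 1.0)
        resultant = float(np.abs(z))
    else:
        mean_phase, resultant = math.nan, math.nan
    return {
        "followed_fraction": followed_fraction,
        "period_s": period,
        "mean_phase": mean_phase,
        "resultant_length": resultant,
        "circular_dispersion": 1.0 - resultant if not math.isnan(resultant) else math.nan,
        "n_cycles": len(onsets),
    }
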