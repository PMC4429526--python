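"""Seeded synthetic data with complete ground truth.

Three generators emulate the raw data the analysis modules consume, so every
downstream stage has a recovery test against known ground truth:

* ``generate_calcium_movie`` — fluorescence movies of blob-shaped cells that
  burst rhythmically (fast rise, exponential decay) over a drifting, noisy
  baseline;
* ``generate_nerve_trace`` — integrated-style nerve envelopes with spontaneous
  and stimulus-locked bursts of specified kinetics and per-stimulus success
  probability;
* ``generate_breath_trace`` — plethysmograph pressure traces with per-breath
  durations and tidal volumes, apneas, a gas-epoch schedule applying
  multiplicative hypercapnic effects, and an embedded calibration injection.

Identical spec + seed gives bit-identical output.  All noise is additive
Gaussian; bleaching is monoexponential and multiplicative on the whole frame;
each breath is a single positive half-sine inspiratory lobe whose area maps
to tidal volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ephys import NerveTrace
from .imaging import FrameStack
from .pleth import EpochPlan

__all__ = [
    "CellSpec",
    "MovieSpec",
    "MovieGroundTruth",
    "NerveTraceSpec",
    "NerveGroundTruth",
    "BreathTraceSpec",
    "BreathGroundTruth",
    "generate_calcium_movie",
    "generate_nerve_trace",
    "generate_breath_trace",
]


# ---------------------------------------------------------------------------
# Calcium movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """One rhythmic cell: a 2-D Gaussian footprint bursting periodically.

    Bursts are instantaneous rises of ``burst_amplitude`` (dF/F fraction)
    followed by exponential decay with time constant ``burst_decay_tau`` (s);
    cycle-to-cycle timing noise is Gaussian with SD ``jitter_sd`` (s).
    """

    center: tuple[float, float]  # (row, col), pixels
    radius: float  # Gaussian sigma, pixels
    burst_frequency: float  # Hz
    burst_amplitude: float  # dF/F fraction
    burst_decay_tau: float = 1.0  # s
    jitter_sd: float = 0.0  # s
    phase: float = 0.0  # s, time of the first burst


@dataclass(frozen=True)
class MovieSpec:
    """Acquisition and scene parameters of a synthetic movie.

    Defaults follow the acquisition regime of the analysis: 10 frames/s
    (100 ms exposure) for 180 s records.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 1800
    frame_rate: float = 10.0
    cells: tuple[CellSpec, ...] = ()
    baseline_level: float = 100.0
    bleach_rate: float = 0.0  # fraction per frame, monoexponential
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in self.cells:
            if c.burst_frequency <= 0:
                raise ValueError("burst_frequency must be positive")
            if c.burst_amplitude < 0:
                raise ValueError("burst_amplitude must be >= 0")
            if self.frame_rate <= 2 * c.burst_frequency:
                raise ValueError(
                    "frame_rate must exceed twice the fastest burst frequency"
                )


@dataclass
class MovieGroundTruth:
    masks: list[np.ndarray]  # per-cell boolean H x W footprint masks
    event_times: list[np.ndarray]  # per-cell burst onset times, s
    cells: tuple[CellSpec, ...]


def _burst_times(
    rng: np.random.Generator, freq: float, phase: float, jitter_sd: float, duration: float
) -> np.ndarray:
    n = int(math.ceil(duration * freq)) + 2
    times = phase + np.arange(n) / freq
    if jitter_sd > 0:
        times = times + rng.normal(0.0, jitter_sd, size=n)
    times = np.sort(times)
    return times[(times >= 0) & (times < duration)]


def generate_calcium_movie(spec: MovieSpec) -> tuple[FrameStack, MovieGroundTruth]:
    """Render a movie of rhythmic cells with full ground truth.

    Frame model: F(t) = baseline * (1 + sum_cells footprint * activity(t))
    * exp(-bleach_rate * frame_index) + Gaussian noise.  A cell whose 2-sigma
    footprint leaves the frame is rejected by name.
    """
    rng = np.random.default_rng(spec.seed)
    H, W, T = spec.height, spec.width, spec.n_frames
    duration = T / spec.frame_rate
    t = np.arange(T) / spec.frame_rate

    activity = np.zeros((T, H, W))
    masks: list[np.ndarray] = []
    events: list[np.ndarray] = []
    for k, cell in enumerate(spec.cells):
        r0, c0 = cell.center
        if not (2 * cell.radius <= r0 <= H - 1 - 2 * cell.radius) or not (
            2 * cell.radius <= c0 <= W - 1 - 2 * cell.radius
        ):
            raise ValueError(f"cell {k} footprint extends outside the frame")
        # footprint support truncated at 4 sigma (below float noise elsewhere)
        ra, rb = max(0, int(r0 - 4 * cell.radius)), min(H, int(r0 + 4 * cell.radius) + 1)
        ca, cb = max(0, int(c0 - 4 * cell.radius)), min(W, int(c0 + 4 * cell.radius) + 1)
        rows, cols = np.mgrid[ra:rb, ca:cb]
        foot = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * cell.radius**2))
        mask = np.zeros((H, W), dtype=bool)
        mask[ra:rb, ca:cb] = foot >= math.exp(-2.0)  # within 2 sigma
        times = _burst_times(rng, cell.burst_frequency, cell.phase, cell.jitter_sd, duration)
        trace = np.zeros(T)
        for t0 in times:
            after = t >= t0
            trace[after] += cell.burst_amplitude * np.exp(-(t[after] - t0) / cell.burst_decay_tau)
        activity[:, ra:rb, ca:cb] += trace[:, None, None] * foot[None, :, :]
        masks.append(mask)
        events.append(times)

    frames = spec.baseline_level * (1.0 + activity)
    if spec.bleach_rate:
        frames *= np.exp(-spec.bleach_rate * np.arange(T))[:, None, None]
    if spec.noise_sd:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    stack = FrameStack(data=frames, frame_rate=spec.frame_rate, origin={"synthetic": True, "seed": spec.seed})
    return stack, MovieGroundTruth(masks=masks, event_times=events, cells=spec.cells)


# ---------------------------------------------------------------------------
# Nerve traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NerveTraceSpec:
    """Integrated-style nerve envelope with spontaneous and evoked bursts.

    ``burst_shape`` = (amplitude a.u., time_to_peak ms, half_width ms,
    decay_time ms).  The rendered burst rises linearly over ``time_to_peak``
    and decays exponentially with tau = ``decay_time``; that shape has three
    degrees of freedom, so the realized half-width is determined analytically
    (time_to_peak/2 + decay_time * ln 2) and reported in the ground truth
    rather than taken from the tuple's half_width entry.
    """

    duration: float = 60.0  # s
    sample_rate: float = 1000.0  # Hz
    spontaneous_rate: float = 0.1  # bursts/s
    burst_shape: tuple[float, float, float, float] = (201.0, 228.0, 450.0, 510.0)
    stim_times: tuple[float, ...] = ()
    stim_success_prob: float = 1.0
    evoked_latency: tuple[float, float] = (666.0, 20.0)  # mean, SD (ms)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        amp, ttp, hw, dec = self.burst_shape
        if min(amp, ttp, hw, dec) <= 0:
            raise ValueError("all burst-shape parameters must be positive")
        if not 0 <= self.stim_success_prob <= 1:
            raise ValueError("stim_success_prob must lie in [0, 1]")
        for s in self.stim_times:
            if not 0 <= s < self.duration:
                raise ValueError(f"stimulus at {s} s is outside the trace")

    @property
    def realized_kinetics(self) -> dict:
        """Closed-form kinetics of the rendered burst shape (ms except amp)."""
        amp, ttp, _, dec = self.burst_shape
        return {
            "amplitude": amp,
            "time_to_peak_ms": ttp,
            "half_width_ms": ttp / 2.0 + dec * math.log(2.0),
            "decay_time_ms": dec,
        }


@dataclass
class NerveGroundTruth:
    events: pd.DataFrame  # columns: onset_s, kind, stim_index
    spec: NerveTraceSpec


def _add_burst(
    x: np.ndarray, sample_rate: float, onset: float, amp: float, ttp_s: float, tau_s: float
) -> None:
    """Add a linear-rise / exponential-decay burst in place over its support
    (truncated where the decay falls below 1e-9 of the amplitude)."""
    i0 = max(0, int(math.floor(onset * sample_rate)))
    i1 = min(len(x), int(math.ceil((onset + ttp_s + tau_s * 21.0) * sample_rate)) + 1)
    if i1 <= i0:
        return
    dt = np.arange(i0, i1) / sample_rate - onset
    rise = np.clip(dt / ttp_s, 0.0, 1.0)
    decay = np.exp(-np.clip(dt - ttp_s, 0.0, None) / tau_s)
    x[i0:i1] += np.where(dt >= 0, amp * rise * decay, 0.0)


def generate_nerve_trace(spec: NerveTraceSpec) -> tuple[NerveTrace, NerveGroundTruth]:
    """Render an integrated-style envelope with labeled burst ground truth.

    Spontaneous bursts follow a homogeneous Poisson process; each stimulus
    independently evokes a burst with probability ``stim_success_prob`` at a
    Gaussian latency.  The trace is clipped at zero (integrated-signal
    convention).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    amp, ttp_ms, _, dec_ms = spec.burst_shape
    ttp_s, tau_s = ttp_ms / 1000.0, dec_ms / 1000.0

    rows = []
    n_spont = rng.poisson(spec.spontaneous_rate * spec.duration)
    for onset in np.sort(rng.uniform(0.0, spec.duration, size=n_spont)):
        rows.append({"onset_s": float(onset), "kind": "spontaneous", "stim_index": -1})
    lat_mean, lat_sd = spec.evoked_latency
    for k, s in enumerate(spec.stim_times):
        if rng.uniform() < spec.stim_success_prob:
            onset = s + max(0.0, rng.normal(lat_mean, lat_sd)) / 1000.0
            if onset < spec.duration:
                rows.append({"onset_s": float(onset), "kind": "evoked", "stim_index": k})
    events = pd.DataFrame(rows, columns=["onset_s", "kind", "stim_index"]).sort_values(
        "onset_s", ignore_index=True
    )

    x = np.zeros(n)
    for onset in events["onset_s"]:
        _add_burst(x, spec.sample_rate, onset, amp, ttp_s, tau_s)
    if spec.noise_sd:
        # noise enters before the analog integrator, so it arrives low-passed
        # (50 ms single pole) on an integrated-style envelope
        noise = rng.normal(0.0, spec.noise_sd, size=n)
        alpha = min(1.0, (1.0 / spec.sample_rate) / 0.05)
        from scipy.signal import lfilter

        smoothed = lfilter([alpha], [1.0, -(1.0 - alpha)], noise)
        x = x + smoothed / max(np.std(smoothed), 1e-12) * spec.noise_sd
    x = np.clip(x, 0.0, None)
    trace = NerveTrace(values=x, sample_rate=spec.sample_rate, integrated=True, tau_ms=50.0)
    return trace, NerveGroundTruth(events=events, spec=spec)


# ---------------------------------------------------------------------------
# Breath traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreathTraceSpec:
    """Plethysmograph pressure trace with gas epochs and a calibration pulse.

    Per-breath T_TOT and V_T are Gaussian with coefficients of variation
    ``ttot_cv`` and ``vt_cv``; inside hypercapnic epochs both are scaled by
    the multiplicative ``hypercapnic_effects`` = (ttot_factor, vt_factor).
    Each breath is a half-sine inspiratory lobe of duration 0.4 * T_TOT whose
    area encodes V_T through the chamber gain ``pressure_per_ul``.
    """

    duration: float = 800.0  # s
    sample_rate: float = 100.0  # Hz
    ttot_mean: float = 0.5  # s
    ttot_cv: float = 0.0
    vt_mean: float = 10.0  # ul
    vt_cv: float = 0.0
    body_mass: float = 1.5  # g
    apnea_times: tuple[tuple[float, float], ...] = ()  # (start s, duration s)
    epoch_plan: EpochPlan = field(default_factory=EpochPlan.neonatal_default)
    hypercapnic_effects: tuple[float, float] = (1.0, 1.0)  # (ttot, vt) factors
    calibration: tuple[float, float] | None = (5.0, 795.0)  # (volume ul, time s)
    pressure_per_ul: float = 0.1  # chamber gain, pressure units per ul
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        tf, vf = self.hypercapnic_effects
        if tf <= 0 or vf <= 0:
            raise ValueError("hypercapnic factors must be positive")
        if abs(self.epoch_plan.duration - self.duration) > 1e-9:
            raise ValueError("epoch plan does not match the trace duration")
        spans = sorted((s, s + d) for s, d in self.apnea_times)
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if b0 < a1:
                raise ValueError("apnea windows must not overlap")
        for a0, a1 in spans:
            if a0 < 0 or a1 > self.duration:
                raise ValueError("apnea window outside the recording")


@dataclass
class BreathGroundTruth:
    breaths: pd.DataFrame  # onset_s, t_tot_s, v_t_ul, epoch
    apneas: tuple[tuple[float, float], ...]
    scale: float  # true ul per pressure-unit-second
    spec: BreathTraceSpec


def _add_half_sine(x: np.ndarray, sample_rate: float, onset: float, dur: float, area: float) -> None:
    """Add a half-sine lobe in place, rendered as per-sample bin averages.

    Averaging the waveform over each sample interval makes the discrete sum
    times dt equal the requested area exactly, so lobe area encodes volume
    without sampling bias.  Only the lobe's own samples are touched.
    """
    dt = 1.0 / sample_rate
    i0 = max(0, int(math.floor(onset * sample_rate)) - 1)
    i1 = min(len(x), int(math.ceil((onset + dur) * sample_rate)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) * dt
    p0 = np.clip((t - onset) / dur, 0.0, 1.0)
    p1 = np.clip((t + dt - onset) / dur, 0.0, 1.0)
    # integral of (A * pi / (2 dur)) * sin(pi p) over the bin
    x[i0:i1] += (np.cos(np.pi * p0) - np.cos(np.pi * p1)) * (area / 2.0) / dt


def generate_breath_trace(spec: BreathTraceSpec) -> tuple[np.ndarray, BreathGroundTruth]:
    """Render a pressure trace and its per-breath ground truth.

    Breaths inside hypercapnic epochs have T_TOT and V_T scaled by the stated
    factors; apnea windows contain no breaths; a calibration lobe of known
    volume is embedded at the stated time (breaths within +/-1 s are
    suppressed so the lobe stays identifiable).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    g = spec.pressure_per_ul
    apneas = tuple(sorted((s, s + d) for s, d in spec.apnea_times))
    cal_blank = None
    if spec.calibration is not None:
        vol, t_cal = spec.calibration
        cal_blank = (t_cal - 1.0, t_cal + 1.0)

    tf, vf = spec.hypercapnic_effects
    x = np.zeros(n)
    rows = []
    t = 0.0
    while t < spec.duration:
        blocked = False
        for a0, a1 in apneas:
            if a0 <= t < a1:
                t = a1
                blocked = True
                break
        if blocked:
            continue
        if cal_blank and cal_blank[0] <= t < cal_blank[1]:
            t = cal_blank[1]
            continue
        label = spec.epoch_plan.label_at(t) or "normocapnic"
        hyper = label == "hypercapnic"
        mu_t = spec.ttot_mean * (tf if hyper else 1.0)
        mu_v = spec.vt_mean * (vf if hyper else 1.0)
        t_tot = max(0.05, rng.normal(mu_t, spec.ttot_cv * mu_t) if spec.ttot_cv else mu_t)
        v_t = max(0.0, rng.normal(mu_v, spec.vt_cv * mu_v) if spec.vt_cv else mu_v)
        if t + t_tot > spec.duration:
            break
        _add_half_sine(x, spec.sample_rate, t, 0.4 * t_tot, g * v_t)
        rows.append({"onset_s": t, "t_tot_s": t_tot, "v_t_ul": v_t, "epoch": label})
        t += t_tot

    if spec.calibration is not None:
        vol, t_cal = spec.calibration
        _add_half_sine(x, spec.sample_rate, t_cal, 0.2, g * vol)
    if spec.noise_sd:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    gt = BreathGroundTruth(
        breaths=pd.DataFrame(rows, columns=["onset_s", "t_tot_s", "v_t_ul", "epoch"]),
        apneas=apneas,
        scale=1.0 / g,
        spec=spec,
    )
    return x, gt
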