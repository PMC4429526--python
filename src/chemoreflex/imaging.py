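"""Calcium-imaging analysis of rhythmic brainstem neurons.

This module implements the movie-analysis chain used to find CO2/pH-sensitive
rhythmically bursting cells in fluorescence time series:

1. ``compute_dff`` — baseline-normalize the movie with a forward running-mean
   baseline model, F0(t) = mean of the next ``w`` frames, dropping the last
   ``w`` frames of the record.
2. ``detect_cycles`` + ``cycle_triggered_average`` — align the movie on the
   population rhythm to enhance rhythm-locked pixels.
3. ``sd_image`` + ``iterative_threshold_rois`` — localize candidate cells as
   compact bright blobs of the temporal-standard-deviation projection.
4. ``extract_traces`` + ``validate_rhythmic`` — keep only candidates whose
   power-spectral-density peak lies in the physiological rhythm band
   (0.1–0.4 Hz by default).

``detect_rtn_cells`` composes the chain end to end.  For preparations with no
coherent population rhythm (e.g. mutants) the SD image of the full dF/F0
series replaces the SD of the cycle-triggered average (``mode="full_series"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig
from skimage import measure as _measure

__all__ = [
    "FrameStack",
    "DFFSeries",
    "ROI",
    "CellTrace",
    "RhythmClassification",
    "CTAStack",
    "ImagingParams",
    "DetectionResult",
    "compute_dff",
    "detect_cycles",
    "cycle_triggered_average",
    "sd_image",
    "iterative_threshold_rois",
    "extract_traces",
    "validate_rhythmic",
    "detect_rtn_cells",
    "burst_frequency",
    "frequency_comparison",
    "photostim_response_map",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FrameStack:
    """A T x H x W fluorescence movie with its frame rate (Hz)."""

    data: np.ndarray
    frame_rate: float
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("FrameStack.data must be T x H x W")
        if self.data.shape[0] < 2:
            raise ValueError("FrameStack needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("FrameStack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class DFFSeries:
    """Baseline-normalized movie: (T - w) x H x W, dimensionless dF/F0."""

    data: np.ndarray
    w: int
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ROI:
    """A connected set of pixels representing one candidate cell."""

    label: int
    pixels: tuple[tuple[int, int], ...]  # (row, col) pairs
    centroid: tuple[float, float]
    area: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        m[list(rows), list(cols)] = True
        return m


@dataclass
class CellTrace:
    """Per-frame mean dF/F0 over one ROI."""

    roi_label: int
    values: np.ndarray
    frame_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


@dataclass
class RhythmClassification:
    """Spectral accept/reject verdict for one ROI trace."""

    roi_label: int
    peak_frequency: float
    peak_power: float
    band: tuple[float, float]
    accepted: bool


@dataclass
class CTAStack:
    """Cycle-triggered average: window-length L x H x W stack."""

    data: np.ndarray
    window: tuple[int, int]  # (frames before, frames after) the event
    n_events: int
    frame_rate: float


# ---------------------------------------------------------------------------
# dF/F0 baseline model
# ---------------------------------------------------------------------------


def compute_dff(
    stack: FrameStack,
    w: int = 100,
    nonpositive: Literal["mask", "raise"] = "mask",
) -> DFFSeries:
    """Baseline-normalize a movie with a forward running-mean baseline.

    For each retained frame t, F0(t) is the mean of frames t .. t+w-1 and the
    output is (F(t) - F0(t)) / F0(t).  The last ``w`` frames have no complete
    baseline window and are dropped, so the output has exactly T - w frames.

    Parameters
    ----------
    stack
        Input movie.
    w
        Baseline window length in frames (default 100; 10 s at 10 frames/s).
    nonpositive
        Policy for pixels whose baseline is <= 0: ``"mask"`` marks them NaN
        (default), ``"raise"`` raises ``ValueError``.
    """
    T = stack.n_frames
    if w < 1:
        raise ValueError("w must be >= 1")
    if T <= w:
        raise ValueError(f"need more than w={w} frames, got T={T}")
    F = stack.data
    csum = np.cumsum(F, axis=0, dtype=float)
    csum = np.concatenate([np.zeros((1,) + F.shape[1:]), csum], axis=0)
    # F0[t] = mean(F[t : t + w]) for t = 0 .. T - w - 1
    f0 = (csum[w : T + 1] - csum[0 : T - w + 1]) / w
    f0 = f0[: T - w]
    out = np.empty_like(f0)
    bad = f0 <= 0
    if bad.any():
        if nonpositive == "raise":
            raise ValueError("baseline F0 <= 0 encountered")
        out[:] = np.nan
        good = ~bad
        out[good] = (F[: T - w][good] - f0[good]) / f0[good]
    else:
        out = (F[: T - w] - f0) / f0
    return DFFSeries(data=out, w=w, frame_rate=stack.frame_rate)


# ---------------------------------------------------------------------------
# Cycle detection and cycle-triggered averaging
# ---------------------------------------------------------------------------


def detect_cycles(
    trace: CellTrace,
    min_separation: float,
    smooth_s: float = 0.5,
    prominence_k: float = 3.0,
) -> np.ndarray:
    """Find rhythm-cycle event times (s) as local maxima of the smoothed trace.

    The trace is smoothed with a ``smooth_s``-second moving mean; peaks must be
    separated by at least ``min_separation`` seconds and rise by at least
    ``prominence_k`` noise SDs above their surroundings.  The noise scale is
    the first-difference MAD estimator, sigma = 1.4826 * MAD(diff x) / sqrt 2,
    which is insensitive to the slow oscillation itself.  A flat or empty
    trace yields no events.
    """
    x = np.asarray(trace.values, dtype=float)
    if len(x) < 3:
        raise ValueError("trace too short for cycle detection")
    fr = trace.frame_rate
    x = np.where(np.isfinite(x), x, np.nanmedian(x))
    n_smooth = max(1, int(round(smooth_s * fr)))
    kernel = np.ones(n_smooth) / n_smooth
    xs = np.convolve(x, kernel, mode="same")
    d = np.diff(xs)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0)
    if sigma == 0:
        return np.empty(0)
    distance = max(1, int(round(min_separation * fr)))
    peaks, _ = _sig.find_peaks(xs, distance=distance, prominence=prominence_k * sigma)
    return peaks / fr


def cycle_triggered_average(
    dff: DFFSeries,
    events: Sequence[float],
    window: tuple[int, int],
) -> CTAStack:
    """Average movie segments aligned on rhythm-cycle events.

    ``window = (pre, post)`` frames around each event; output frame k is the
    mean over events of frame ``event_frame + k - pre``.  Events whose windows
    extend past the series are skipped; fewer than two usable events is an
    error.
    """
    pre, post = window
    if pre < 0 or post <= 0:
        raise ValueError("window must be (pre >= 0, post > 0) frames")
    T = dff.n_frames
    frames = np.round(np.asarray(events, dtype=float) * dff.frame_rate).astype(int)
    usable = [f for f in frames if f - pre >= 0 and f + post <= T]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 events with complete windows, got {len(usable)}"
        )
    segs = np.stack([dff.data[f - pre : f + post] for f in usable])
    return CTAStack(
        data=np.nanmean(segs, axis=0),
        window=window,
        n_events=len(usable),
        frame_rate=dff.frame_rate,
    )


# ---------------------------------------------------------------------------
# SD image and ROI discovery
# ---------------------------------------------------------------------------


def sd_image(stack, ddof: int = 0) -> np.ndarray:
    """Temporal standard deviation of a T x H x W series, per pixel.

    Accepts a raw array or any object with a T x H x W ``.data`` attribute
    (FrameStack, DFFSeries, CTAStack).  Population convention (ddof=0) by
    default, matching common Z-projection behavior; NaNs are ignored.
    """
    data = getattr(stack, "data", stack)
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need a T x H x W series with T >= 2")
    return np.nanstd(data, axis=0, ddof=ddof)


def iterative_threshold_rois(
    sd: np.ndarray,
    min_area: int = 5,
    max_area: int = 200,
    start_quantile: float = 0.995,
    step: float = 0.95,
    stop_mad_k: float = 2.0,
    connectivity: int = 2,
) -> list[ROI]:
    """Discover cell-like blobs by iterative thresholding of an SD image.

    Starting from the ``start_quantile`` intensity of the image, connected
    components above threshold whose area lies in ``[min_area, max_area]`` are
    accepted and their pixels zeroed out; the threshold is then lowered by the
    multiplicative factor ``step`` until it reaches the stopping level
    ``median + stop_mad_k * MAD`` of the original image.  A component that
    touches an already-accepted ROI (8-neighbourhood) is suppressed — it is
    the dimmer skirt of that cell, not a new one.  Accepted ROIs are disjoint
    and the procedure is deterministic.  A flat image yields no ROIs.
    """
    img = np.asarray(sd, dtype=float).copy()
    if img.ndim != 2:
        raise ValueError("SD image must be 2-D")
    if not (0 < step < 1):
        raise ValueError("step must be in (0, 1)")
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    finite = img[np.isfinite(img)]
    if finite.size == 0 or finite.max() == finite.min():
        return []
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    stop = med + stop_mad_k * mad
    thresh = float(np.quantile(finite, start_quantile))
    img[~np.isfinite(img)] = -np.inf

    rois: list[ROI] = []
    claimed = np.zeros(img.shape, dtype=bool)
    H, W = img.shape
    label = 0
    while thresh > stop:
        labels = _measure.label(img > thresh, connectivity=connectivity)
        for region in _measure.regionprops(labels):
            if not (min_area <= region.area <= max_area):
                continue
            rr, cc = region.coords.T
            touches = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if claimed[
                        np.clip(rr + dr, 0, H - 1), np.clip(cc + dc, 0, W - 1)
                    ].any():
                        touches = True
                        break
                if touches:
                    break
            if touches:
                continue
            label += 1
            rois.append(
                ROI(
                    label=label,
                    pixels=tuple(map(tuple, region.coords)),
                    centroid=tuple(region.centroid),
                    area=int(region.area),
                )
            )
            img[rr, cc] = -np.inf
            claimed[rr, cc] = True
        thresh *= step
    return rois


def extract_traces(dff: DFFSeries, rois: Sequence[ROI]) -> list[CellTrace]:
    """Per-frame mean dF/F0 over each ROI's pixels (NaN pixels excluded)."""
    H, W = dff.data.shape[1:]
    traces = []
    for roi in rois:
        rows, cols = zip(*roi.pixels)
        rows, cols = np.asarray(rows), np.asarray(cols)
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= H or cols.max() >= W:
            raise ValueError(f"ROI {roi.label} lies outside the image bounds")
        values = np.nanmean(dff.data[:, rows, cols], axis=1)
        traces.append(CellTrace(roi_label=roi.label, values=values, frame_rate=dff.frame_rate))
    return traces


# ---------------------------------------------------------------------------
# Spectral rhythmicity gate
# ---------------------------------------------------------------------------


def validate_rhythmic(
    trace: CellTrace,
    band: tuple[float, float] = (0.1, 0.4),
    min_frequency: float | None = None,
) -> RhythmClassification:
    """Accept a trace iff its PSD peak lies inside the rhythm band.

    The PSD is a mean-removed Welch periodogram (Hann window, 50% overlap,
    segment length >= 4 slow cycles).  The DC bin — and any frequency below
    ``min_frequency`` if given — is excluded from the peak search.  Equal-power
    peaks resolve to the lowest frequency.
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    fr = trace.frame_rate
    if fr <= 2 * hi:
        raise ValueError("frame rate must exceed twice the band's upper edge")
    x = np.asarray(trace.values, dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmedian(x))
    duration = len(x) / fr
    if duration < 2.0 / lo:
        raise ValueError(
            f"trace of {duration:.1f} s too short to resolve {lo} Hz (need {2.0 / lo:.1f} s)"
        )
    nperseg = min(len(x), int(round(4.0 / lo * fr)))
    freqs, power = _sig.welch(
        x - x.mean(),
        fs=fr,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    floor = 0.0 if min_frequency is None else min_frequency
    keep = freqs > floor
    freqs, power = freqs[keep], power[keep]
    i = int(np.argmax(power))  # argmax takes the first (lowest-frequency) tie
    peak_f, peak_p = float(freqs[i]), float(power[i])
    return RhythmClassification(
        roi_label=trace.roi_label,
        peak_frequency=peak_f,
        peak_power=peak_p,
        band=band,
        accepted=bool(lo <= peak_f <= hi),
    )


# ---------------------------------------------------------------------------
# End-to-end detection
# ---------------------------------------------------------------------------


@dataclass
class ImagingParams:
    """Tunable parameters of the end-to-end cell-detection chain."""

    w: int = 100
    band: tuple[float, float] = (0.1, 0.4)
    cta_window: tuple[int, int] = (25, 25)
    min_area: int = 5
    max_area: int = 200
    start_quantile: float = 0.995
    step: float = 0.95
    stop_mad_k: float = 2.0
    smooth_s: float = 0.5
    prominence_k: float = 3.0


@dataclass
class DetectionResult:
    rois: list[ROI]
    traces: list[CellTrace]
    classifications: list[RhythmClassification]
    activity_map: np.ndarray  # H x W labels of accepted ROIs only
    sd: np.ndarray
    mode: str

    @property
    def accepted(self) -> list[ROI]:
        ok = {c.roi_label for c in self.classifications if c.accepted}
        return [r for r in self.rois if r.label in ok]


def detect_rtn_cells(
    stack: FrameStack,
    mode: Literal["cta", "full_series"] = "cta",
    params: ImagingParams | None = None,
) -> DetectionResult:
    """Full detection chain: dF/F0 -> SD image -> ROIs -> traces -> PSD gate.

    ``mode="cta"`` takes the SD image of the cycle-triggered average computed
    on the whole-field population trace; ``mode="full_series"`` takes the SD
    image of the full dF/F0 series instead (the fallback for preparations with
    no coherent population rhythm).
    """
    p = params or ImagingParams()
    dff = compute_dff(stack, w=p.w)
    if mode == "cta":
        broad = CellTrace(
            roi_label=0,
            values=np.nanmean(dff.data, axis=(1, 2)),
            frame_rate=dff.frame_rate,
        )
        # a CTA needs a discernible in-band population rhythm to lock to
        broad_cls = validate_rhythmic(broad, band=p.band)
        events = detect_cycles(
            broad,
            min_separation=1.0 / p.band[1],
            smooth_s=p.smooth_s,
            prominence_k=p.prominence_k,
        )
        if not broad_cls.accepted or len(events) < 2:
            raise ValueError(
                "no detectable population cycles; retry with mode='full_series'"
            )
        cta = cycle_triggered_average(dff, events, p.cta_window)
        sd = sd_image(cta)
    elif mode == "full_series":
        sd = sd_image(dff)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rois = iterative_threshold_rois(
        sd,
        min_area=p.min_area,
        max_area=p.max_area,
        start_quantile=p.start_quantile,
        step=p.step,
        stop_mad_k=p.stop_mad_k,
    )
    traces = extract_traces(dff, rois)
    classifications = [validate_rhythmic(t, band=p.band) for t in traces]
    activity_map = np.zeros(sd.shape, dtype=int)
    accepted = {c.roi_label for c in classifications if c.accepted}
    for roi in rois:
        if roi.label in accepted:
            rows, cols = zip(*roi.pixels)
            activity_map[list(rows), list(cols)] = roi.label
    return DetectionResult(
        rois=rois,
        traces=traces,
        classifications=classifications,
        activity_map=activity_map,
        sd=sd,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Frequency and photostimulation measures
# ---------------------------------------------------------------------------


def burst_frequency(events: Sequence[float], interval: float) -> float:
    """Event rate in Hz: count / interval.  Empty event list gives 0 Hz."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    return len(events) / interval


def frequency_comparison(
    freqs_a: Sequence[float], freqs_b: Sequence[float]
) -> dict:
    """Per-cell frequency pairs across two conditions (e.g. pH 7.4 vs 7.2).

    Returns the paired frequencies and the relative change of the mean,
    100 * (mean_b - mean_a) / mean_a (NaN if mean_a is zero).
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must have the same number of cells")
    ma = a.mean() if a.size else math.nan
    change = math.nan if not ma else 100.0 * (b.mean() - ma) / ma
    return {"pairs": list(zip(a.tolist(), b.tolist())), "relative_change_pct": change}


def photostim_response_map(
    dff: DFFSeries, stim_offset_frame: int, n_frames: int = 10
) -> np.ndarray:
    """Mean dF/F0 image over ``n_frames`` frames starting at the light offset.

    With the default 10 frames at 10 frames/s this averages the 1 s of
    acquisition that follows the end of the light pulse.
    """
    if stim_offset_frame < 0 or n_frames < 1:
        raise ValueError("stim_offset_frame >= 0 and n_frames >= 1 required")
    if stim_offset_frame + n_frames > dff.n_frames:
        raise ValueError("not enough frames after the stimulus offset")
    return np.nanmean(dff.data[stim_offset_frame : stim_offset_frame + n_frames], axis=0)
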