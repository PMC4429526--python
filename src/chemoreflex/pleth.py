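"""Whole-body plethysmography analysis.

Breathing of unrestrained pups or adults is read out as chamber-pressure
fluctuations.  The chain implemented here is:

* ``calibrate`` — convert pressure-lobe area to volume using known air
  injections (2.5–5 ul) made at the end of a session;
* ``segment_breaths`` — delimit breaths at successive inspiratory onsets and
  compute, per breath, duration T_TOT (s), tidal volume V_T (ul) and
  ventilation V_E = V_T / T_TOT (ul/s);
* ``detect_apneas`` — flag breathing pauses so summaries use apnea-free
  periods only;
* ``bin_timecourse`` — 20 s-binned parameter timecourses across the gas
  protocol;
* ``hypercapnic_response`` — the ratio statistic: per animal, mean parameter
  over the last 100 s of the hypercapnic epoch divided by the mean over the
  last 100 s of the preceding normocapnic epoch, averaged across animals and
  expressed as a percent change (dV_E, dT_TOT, dV_T);
* ``baseline_ventilation`` — body-mass-normalized V_E (ul/s/g) in normal air.

The neonatal gas protocol is 200 s air, 200 s 8% CO2, 400 s air; the adult
variant records 100 s in air and 100 s after 3 min of CO2 equilibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import mean_sem, ttest_paired

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "EpochPlan",
    "BreathRecord",
    "HypercapnicResponse",
    "CalibrationError",
    "calibrate",
    "segment_breaths",
    "detect_apneas",
    "bin_timecourse",
    "animal_window_means",
    "hypercapnic_response",
    "baseline_ventilation",
    "percent_reduction",
    "breaths_to_frame",
]


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gas-epoch schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    label: str  # "normocapnic" | "hypercapnic"
    start: float
    end: float


@dataclass(frozen=True)
class EpochPlan:
    """Ordered, contiguous, non-overlapping gas epochs."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for e in self.epochs:
            if e.end <= e.start:
                raise ValueError(f"epoch {e.label} has end <= start")
            if prev_end is not None and not math.isclose(e.start, prev_end):
                raise ValueError("epochs must be contiguous and ordered")
            prev_end = e.end

    @property
    def duration(self) -> float:
        return self.epochs[-1].end

    def label_at(self, t: float) -> str | None:
        for e in self.epochs:
            if e.start <= t < e.end:
                return e.label
        return None

    @classmethod
    def neonatal_default(cls) -> "EpochPlan":
        """200 s air, 200 s 8% CO2, 400 s air (800 s total)."""
        return cls(
            (
                Epoch("normocapnic", 0.0, 200.0),
                Epoch("hypercapnic", 200.0, 400.0),
                Epoch("normocapnic", 400.0, 800.0),
            )
        )

    @classmethod
    def adult_default(cls) -> "EpochPlan":
        """100 s air, 3 min equilibration, 100 s hypercapnic recording."""
        return cls(
            (
                Epoch("normocapnic", 0.0, 100.0),
                Epoch("transition", 100.0, 280.0),
                Epoch("hypercapnic", 280.0, 380.0),
            )
        )


@dataclass
class BreathRecord:
    """One breath: onset (s), duration, tidal volume, ventilation."""

    onset: float
    t_tot: float  # s
    v_t: float  # ul
    epoch_label: str | None = None
    apnea_free: bool = True

    @property
    def v_e(self) -> float:
        """Ventilation, ul/s — identically V_T / T_TOT."""
        return self.v_t / self.t_tot


def breaths_to_frame(breaths: Sequence[BreathRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [b.onset for b in breaths],
            "t_tot_s": [b.t_tot for b in breaths],
            "v_t_ul": [b.v_t for b in breaths],
            "v_e_ul_per_s": [b.v_e for b in breaths],
            "epoch": [b.epoch_label for b in breaths],
            "apnea_free": [b.apnea_free for b in breaths],
        }
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibrate(
    trace: np.ndarray,
    sample_rate: float,
    injections: Sequence[tuple[float, float]],
    window_s: float = 0.5,
    max_disagreement: float = 0.2,
) -> float:
    """Volume-per-area scale (ul per pressure-unit-second) from air injections.

    Each injection ``(volume_ul, time_s)`` must produce an identifiable
    pressure deflection; its lobe area is integrated over ``window_s`` seconds
    after the injection, above the local pre-injection baseline.  Scales from
    multiple injections are averaged; mutual disagreement beyond
    ``max_disagreement`` (fractional) flags an inconsistent calibration.
    """
    x = np.asarray(trace, dtype=float)
    if not injections:
        raise CalibrationError("at least one injection event is required")
    dt = 1.0 / sample_rate
    scales = []
    for volume, t in injections:
        i0 = int(round(t * sample_rate))
        i1 = int(round((t + window_s) * sample_rate))
        if i0 < 0 or i1 > len(x):
            raise CalibrationError(f"injection at {t} s outside the trace")
        pre0 = max(0, i0 - int(round(window_s * sample_rate)))
        baseline = np.median(x[pre0:i0]) if i0 > pre0 else 0.0
        seg = x[i0:i1] - baseline
        area = float(np.clip(seg, 0.0, None).sum() * dt)
        if area <= 10 * np.finfo(float).eps:
            raise CalibrationError(f"no detectable deflection for injection at {t} s")
        scales.append(volume / area)
    scales = np.asarray(scales)
    if len(scales) > 1:
        spread = (scales.max() - scales.min()) / scales.mean()
        if spread > max_disagreement:
            raise CalibrationError(
                f"inconsistent calibration: scales disagree by {100 * spread:.0f}%"
            )
    return float(scales.mean())


# ---------------------------------------------------------------------------
# Breath segmentation
# ---------------------------------------------------------------------------


def segment_breaths(
    trace: np.ndarray,
    sample_rate: float,
    scale: float,
    epoch_plan: EpochPlan | None = None,
    smooth_s: float = 0.05,
    onset_fraction: float = 0.1,
    baseline_window_s: float = 2.0,
    amplitude_window_s: float = 5.0,
) -> list[BreathRecord]:
    """Delimit breaths at successive inspiratory onsets.

    The signal is smoothed (50 ms moving mean), a rolling lower-quartile
    baseline (which sits in the expiratory flat even when inspiration fills
    half the cycle) and a rolling peak-to-peak amplitude are computed, and
    inspiratory onsets are upward crossings of baseline + ``onset_fraction``
    x amplitude.  T_TOT is the inter-onset interval and V_T is ``scale``
    times the baseline-subtracted signal area over the breath.  A flat trace
    yields no breaths.
    """
    x = np.asarray(trace, dtype=float)
    dt = 1.0 / sample_rate
    n_smooth = max(1, int(round(smooth_s * sample_rate)))
    s = pd.Series(x).rolling(n_smooth, min_periods=1, center=True).mean().to_numpy()

    nb = max(3, int(round(baseline_window_s * sample_rate)))
    na = max(3, int(round(amplitude_window_s * sample_rate)))
    ser = pd.Series(s)
    baseline = ser.rolling(nb, min_periods=1, center=True).quantile(0.25).to_numpy()
    roll = ser.rolling(na, min_periods=1, center=True)
    p2p = (roll.max() - roll.min()).to_numpy()
    if np.nanmax(p2p) <= 1e-12:
        return []
    thresh = baseline + onset_fraction * p2p

    above = s > thresh
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(onsets) < 2:
        return []

    breaths: list[BreathRecord] = []
    for i, j in zip(onsets[:-1], onsets[1:]):
        t_on = i * dt
        t_tot = (j - i) * dt
        area = float((s[i:j] - baseline[i:j]).sum() * dt)
        v_t = max(0.0, scale * area)
        label = epoch_plan.label_at(t_on) if epoch_plan is not None else None
        breaths.append(BreathRecord(onset=t_on, t_tot=t_tot, v_t=v_t, epoch_label=label))
    return breaths


# ---------------------------------------------------------------------------
# Apnea detection
# ---------------------------------------------------------------------------


def detect_apneas(
    breaths: Sequence[BreathRecord],
    k_gap: float = 2.0,
    median_window: int = 11,
) -> tuple[list[BreathRecord], list[tuple[float, float]]]:
    """Flag apneic pauses: inter-onset gaps > ``k_gap`` x rolling-median T_TOT.

    Returns a new breath list with ``apnea_free`` cleared on the gap breath and
    its neighbours, plus the list of apnea intervals (start, end).
    """
    if len(breaths) < 5:
        return list(breaths), []
    ttot = pd.Series([b.t_tot for b in breaths])
    med = ttot.rolling(median_window, min_periods=1, center=True).median().to_numpy()
    flagged = [replace(b) for b in breaths]
    intervals: list[tuple[float, float]] = []
    for i, b in enumerate(breaths):
        if b.t_tot > k_gap * med[i]:
            intervals.append((b.onset, b.onset + b.t_tot))
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(flagged):
                    flagged[j].apnea_free = False
    return flagged, intervals


# ---------------------------------------------------------------------------
# Timecourses and the hypercapnic-response statistic
# ---------------------------------------------------------------------------


def bin_timecourse(
    breaths: Sequence[BreathRecord],
    bin_s: float = 20.0,
    duration: float | None = None,
) -> pd.DataFrame:
    """Per-bin means of V_E, T_TOT and V_T over apnea-free breaths.

    Bins of ``bin_s`` seconds tile the record; empty bins are NaN.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if not breaths:
        raise ValueError("no breaths to bin")
    if duration is None:
        last = breaths[-1]
        duration = last.onset + last.t_tot
    n_bins = int(math.ceil(duration / bin_s))
    rows = []
    free = [b for b in breaths if b.apnea_free]
    idx = np.array([int(b.onset // bin_s) for b in free])
    for k in range(n_bins):
        sel = [b for b, i in zip(free, idx) if i == k]
        rows.append(
            {
                "bin_start_s": k * bin_s,
                "n_breaths": len(sel),
                "v_e_ul_per_s": np.mean([b.v_e for b in sel]) if sel else np.nan,
                "t_tot_s": np.mean([b.t_tot for b in sel]) if sel else np.nan,
                "v_t_ul": np.mean([b.v_t for b in sel]) if sel else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _window_breaths(
    breaths: Sequence[BreathRecord], start: float, end: float
) -> list[BreathRecord]:
    return [b for b in breaths if b.apnea_free and start <= b.onset < end]


def animal_window_means(
    breaths: Sequence[BreathRecord],
    plan: EpochPlan,
    window_s: float = 100.0,
    min_breaths: int = 5,
) -> dict | None:
    """Mean V_E/T_TOT/V_T over the last ``window_s`` of the hypercapnic epoch
    and of the preceding normocapnic epoch, for one animal.

    Returns None (with a logged reason) when either window holds fewer than
    ``min_breaths`` apnea-free breaths.
    """
    hyper = next((e for e in plan.epochs if e.label == "hypercapnic"), None)
    if hyper is None:
        raise ValueError("epoch plan contains no hypercapnic epoch")
    prior = [e for e in plan.epochs if e.label == "normocapnic" and e.end <= hyper.start]
    if not prior:
        raise ValueError("no normocapnic epoch precedes the hypercapnic one")
    normo = prior[-1]
    wins = {
        "normocapnic": _window_breaths(breaths, normo.end - window_s, normo.end),
        "hypercapnic": _window_breaths(breaths, hyper.end - window_s, hyper.end),
    }
    for label, sel in wins.items():
        if len(sel) < min_breaths:
            logger.warning(
                "animal excluded: only %d apnea-free breaths in the %s window",
                len(sel),
                label,
            )
            return None
    out = {}
    for label, sel in wins.items():
        out[label] = {
            "v_e": float(np.mean([b.v_e for b in sel])),
            "t_tot": float(np.mean([b.t_tot for b in sel])),
            "v_t": float(np.mean([b.v_t for b in sel])),
        }
    return out


@dataclass
class HypercapnicResponse:
    """Group percent changes (mean over per-animal ratios) with SEM and n."""

    delta_v_e: float
    delta_t_tot: float
    delta_v_t: float
    sem_v_e: float | None
    sem_t_tot: float | None
    sem_v_t: float | None
    p_v_e: float | None
    p_t_tot: float | None
    p_v_t: float | None
    n: int
    per_animal: pd.DataFrame = field(repr=False, default=None)


def hypercapnic_response(
    animals: Sequence[Sequence[BreathRecord]],
    plan: EpochPlan,
    window_s: float = 100.0,
    min_breaths: int = 5,
) -> HypercapnicResponse:
    """Table-style hypercapnic-response statistic over a group of animals.

    Per animal, ratio = mean(parameter | last ``window_s`` of hypercapnia) /
    mean(parameter | last ``window_s`` of the preceding normocapnic epoch);
    the group value is the mean over animals of 100 * (ratio - 1), with SEM
    and a paired t-test p-value on the per-animal window means.
    """
    rows = []
    paired = {"v_e": ([], []), "t_tot": ([], []), "v_t": ([], [])}
    for k, breaths in enumerate(animals):
        means = animal_window_means(breaths, plan, window_s, min_breaths)
        if means is None:
            continue
        row = {"animal": k}
        for p in ("v_e", "t_tot", "v_t"):
            a, b = means["normocapnic"][p], means["hypercapnic"][p]
            row[f"ratio_{p}"] = b / a
            row[f"delta_{p}_pct"] = 100.0 * (b / a - 1.0)
            paired[p][0].append(a)
            paired[p][1].append(b)
        rows.append(row)
    if not rows:
        raise ValueError("no animal had enough breaths in both windows")
    table = pd.DataFrame(rows)
    n = len(table)

    def group(p: str) -> tuple[float, float | None, float | None]:
        vals = table[f"delta_{p}_pct"].to_numpy()
        gs = mean_sem(vals)
        pv = None
        if n >= 2:
            pv = ttest_paired(paired[p][0], paired[p][1]).p
        return gs.mean, gs.sem, pv

    dve, sve, pve = group("v_e")
    dtt, stt, ptt = group("t_tot")
    dvt, svt, pvt = group("v_t")
    return HypercapnicResponse(
        delta_v_e=dve,
        delta_t_tot=dtt,
        delta_v_t=dvt,
        sem_v_e=sve,
        sem_t_tot=stt,
        sem_v_t=svt,
        p_v_e=pve,
        p_t_tot=ptt,
        p_v_t=pvt,
        n=n,
        per_animal=table,
    )


# ---------------------------------------------------------------------------
# Baseline ventilation
# ---------------------------------------------------------------------------


def baseline_ventilation(
    breaths: Sequence[BreathRecord], body_mass: float
) -> float:
    """Animal-level V_E in ul/s/g over normocapnic, apnea-free breaths."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    sel = [
        b
        for b in breaths
        if b.apnea_free and (b.epoch_label in (None, "normocapnic"))
    ]
    if not sel:
        raise ValueError("no normocapnic apnea-free breaths")
    return float(np.mean([b.v_e for b in sel])) / body_mass


def percent_reduction(mean_ctrl: float, mean_mut: float) -> float:
    """Percent reduction of a mutant group mean vs control: 100*(c - m)/c."""
    if mean_ctrl == 0:
        raise ValueError("control mean must be nonzero")
    return 100.0 * (mean_ctrl - mean_mut) / mean_ctrl
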