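"""End-to-end pipeline: synthetic data -> imaging / ephys / pleth -> report.

``run_pipeline`` executes the requested stages in order, writes all tables
and figures under the configured output directory, and records a manifest
(parameters, seed, software version) from which the run is fully
reconstructible; deterministic stages reproduce bit-identically from the
same manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ephys, imaging, io, pleth, synthgen
from .config import RunConfig

logger = logging.getLogger(__name__)


def _default_movie_cells(rng: np.random.Generator, n_cells: int, h: int, w: int) -> tuple:
    cells = []
    for _ in range(n_cells):
        r = rng.uniform(8, h - 8)
        c = rng.uniform(8, w - 8)
        cells.append(
            synthgen.CellSpec(
                center=(r, c),
                radius=2.0,
                burst_frequency=rng.uniform(0.15, 0.35),
                burst_amplitude=rng.uniform(0.3, 0.6),
                burst_decay_tau=1.0,
                jitter_sd=0.1,
                phase=rng.uniform(0, 5),
            )
        )
    return tuple(cells)


def _stage_synthgen(cfg: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    movie_kwargs = dict(cfg.synthgen.movie)
    n_cells = movie_kwargs.pop("n_cells", 8)
    h = movie_kwargs.get("height", 64)
    w = movie_kwargs.get("width", 64)
    cells = _default_movie_cells(rng, n_cells, h, w)
    mspec = synthgen.MovieSpec(cells=cells, seed=cfg.seed, **movie_kwargs)
    stack, movie_gt = synthgen.generate_calcium_movie(mspec)
    io.save_stack(out / "movie.tif", stack)

    nerve_kwargs = dict(cfg.synthgen.nerve)
    stim_every = nerve_kwargs.pop("stim_every_s", None)
    if stim_every:
        dur = nerve_kwargs.get("duration", 60.0)
        nerve_kwargs["stim_times"] = tuple(np.arange(stim_every, dur - 2.0, stim_every))
    nspec = synthgen.NerveTraceSpec(seed=cfg.seed + 1, **nerve_kwargs)
    nerve_trace, nerve_gt = synthgen.generate_nerve_trace(nspec)
    io.save_trace(out / "nerve.csv", nerve_trace.values, nerve_trace.sample_rate, integrated=True, tau_ms=nerve_trace.tau_ms)
    io.save_stim_log(out / "stims.csv", list(nspec.stim_times), 150.0)

    animals = []
    breath_kwargs = dict(cfg.synthgen.breath)
    if "hypercapnic_effects" in breath_kwargs:
        breath_kwargs["hypercapnic_effects"] = tuple(breath_kwargs["hypercapnic_effects"])
    for k in range(cfg.synthgen.n_animals):
        bspec = synthgen.BreathTraceSpec(seed=cfg.seed + 10 + k, **breath_kwargs)
        trace, gt = synthgen.generate_breath_trace(bspec)
        io.save_trace(out / f"breath_{k}.csv", trace, bspec.sample_rate, body_mass_g=bspec.body_mass)
        animals.append((bspec, trace, gt))
    return {
        "movie": (mspec, stack, movie_gt),
        "nerve": (nspec, nerve_trace, nerve_gt),
        "animals": animals,
    }


def _stage_imaging(cfg: RunConfig, out: Path, stack: imaging.FrameStack) -> dict:
    p = imaging.ImagingParams(
        w=cfg.imaging.w,
        band=tuple(cfg.imaging.band),
        cta_window=tuple(cfg.imaging.cta_window),
        min_area=cfg.imaging.min_area,
        max_area=cfg.imaging.max_area,
        start_quantile=cfg.imaging.start_quantile,
        step=cfg.imaging.step,
    )
    result = imaging.detect_rtn_cells(stack, mode=cfg.imaging.mode, params=p)
    io.save_rois(out / "rois", result.rois, result.sd.shape)
    io.save_map_png(out / "activity_map.png", result.activity_map)
    np.savetxt(out / "activity_map.csv", result.activity_map, fmt="%d", delimiter=",")
    pd.DataFrame(
        {
            "label": [c.roi_label for c in result.classifications],
            "peak_frequency_hz": [c.peak_frequency for c in result.classifications],
            "peak_power": [c.peak_power for c in result.classifications],
            "accepted": [c.accepted for c in result.classifications],
        }
    ).to_csv(out / "classifications.csv", index=False)
    n_acc = len(result.accepted)
    logger.info("imaging: %d candidate ROIs, %d accepted", len(result.rois), n_acc)
    return {"n_rois": len(result.rois), "n_accepted": n_acc}


def _stage_ephys(cfg: RunConfig, out: Path, trace: ephys.NerveTrace, stim_times: list[float]) -> dict:
    bursts = ephys.detect_bursts(
        trace,
        k_threshold=cfg.ephys.k_threshold,
        min_duration_ms=cfg.ephys.min_duration_ms,
        refractory_ms=cfg.ephys.refractory_ms,
    )
    rows = [
        {
            "onset_s": b.onset,
            "peak_s": b.peak_time,
            "amplitude": b.amplitude,
            "time_to_peak_ms": b.time_to_peak_ms,
            "half_width_ms": b.half_width_ms,
            "decay_time_ms": b.decay_time_ms,
            "censored": b.censored,
        }
        for b in bursts
    ]
    pd.DataFrame(rows).to_csv(out / "bursts.csv", index=False)
    result = {"n_bursts": len(bursts)}
    if stim_times:
        stims = [ephys.StimEvent(onset=s, duration_ms=150.0) for s in stim_times]
        responses, success = ephys.classify_evoked(bursts, stims, cfg.ephys.response_window_s)
        pd.DataFrame(
            {
                "stim_onset_s": [r.stim.onset for r in responses],
                "evoked": [r.evoked for r in responses],
                "latency_ms": [r.latency_ms for r in responses],
            }
        ).to_csv(out / "stim_responses.csv", index=False)
        result["success_rate_pct"] = success
    logger.info("ephys: %d bursts detected", len(bursts))
    return result


def _stage_pleth(cfg: RunConfig, out: Path, animals: list) -> dict:
    plan = (
        pleth.EpochPlan.neonatal_default()
        if cfg.pleth.protocol == "neonatal"
        else pleth.EpochPlan.adult_default()
    )
    groups = []
    for k, (bspec, trace, gt) in enumerate(animals):
        scale = (
            pleth.calibrate(trace, bspec.sample_rate, [bspec.calibration])
            if bspec.calibration is not None
            else gt.scale
        )
        breaths = pleth.segment_breaths(trace, bspec.sample_rate, scale, epoch_plan=plan)
        breaths, _ = pleth.detect_apneas(breaths, k_gap=cfg.pleth.k_gap)
        pleth.breaths_to_frame(breaths).to_csv(out / f"breaths_{k}.csv", index=False)
        pleth.bin_timecourse(breaths, bin_s=cfg.pleth.bin_s).to_csv(
            out / f"timecourse_{k}.csv", index=False
        )
        groups.append(breaths)
    response = pleth.hypercapnic_response(groups, plan, window_s=cfg.pleth.window_s)
    report = {
        "delta_v_e_pct": response.delta_v_e,
        "delta_t_tot_pct": response.delta_t_tot,
        "delta_v_t_pct": response.delta_v_t,
        "sem_v_e": response.sem_v_e,
        "sem_t_tot": response.sem_t_tot,
        "sem_v_t": response.sem_v_t,
        "p_v_e": response.p_v_e,
        "p_t_tot": response.p_t_tot,
        "p_v_t": response.p_v_t,
        "n": response.n,
    }
    (out / "hypercapnic_response.json").write_text(json.dumps(report, indent=2))
    response.per_animal.to_csv(out / "hypercapnic_response_per_animal.csv", index=False)
    logger.info("pleth: dV_E = %.1f%% over %d animals", response.delta_v_e, response.n)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and return the report bundle.

    Writes a ``manifest.json`` with the full parameter set, the seed and the
    software version; rerunning from the same manifest reproduces all
    deterministic outputs bit-identically.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed}

    data = None
    for stage in cfg.stages:
        try:
            if stage == "synthgen":
                data = _stage_synthgen(cfg, out)
            elif stage == "imaging":
                if data is None:
                    raise ValueError("imaging stage needs synthgen outputs")
                report["imaging"] = _stage_imaging(cfg, out, data["movie"][1])
            elif stage == "ephys":
                if data is None:
                    raise ValueError("ephys stage needs synthgen outputs")
                nspec, trace, _ = data["nerve"]
                report["ephys"] = _stage_ephys(cfg, out, trace, list(nspec.stim_times))
            elif stage == "pleth":
                if data is None:
                    raise ValueError("pleth stage needs synthgen outputs")
                report["pleth"] = _stage_pleth(cfg, out, data["animals"])
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {"config": cfg.to_dict(), "version": __version__, "report": report}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return report
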