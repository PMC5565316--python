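"""Pipeline stages behind the CLI: simulate, analyze, cohort statistics.

Every stage writes machine-readable outputs (CSV/JSON/OME-TIFF) plus a
resolved-parameters JSON next to them, and is deterministic for a fixed
seed: rerunning with identical inputs reproduces the files byte for byte
(no timestamps are embedded).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from calmito import __version__
from calmito.calcium import analyze_movie, register_to_first, rois_from_label_mask
from calmito.calcium.movie import CalciumMovie, StimulusWindow
from calmito.io import read_image, read_protocol, read_rois, write_image, write_json
from calmito.mito import (
    GanglionMask,
    MitoStack,
    correct_background,
    correct_bleach,
    mean_fluctuation_score,
    segment_stack_frame,
    select_top_spots,
    track_and_fluctuate,
)
from calmito.simulate import (
    CalciumSimParams,
    MitoSimParams,
    simulate_calcium_movie,
    simulate_mito_stack,
)
from calmito.stats import SubjectSummary, cohort_frame, run_cohort_comparison


def _params_dict(params) -> dict:
    d = dataclasses.asdict(params)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _write_provenance(out_dir: Path, stage: str, params: dict) -> None:
    write_json(
        out_dir / "run_config.json",
        {"stage": stage, "calmito_version": __version__, "params": params},
    )


def simulate_calcium_run(params: CalciumSimParams, out_dir: str | Path) -> Path:
    """Simulate one calcium movie; write movie, ROI mask and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, truth = simulate_calcium_movie(params)
    write_image(
        out / "movie.ome.tif",
        movie.frames,
        axes="TYX",
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )
    write_image(out / "rois.ome.tif", truth.label_mask, axes="YX",
                pixel_size_um=movie.pixel_size_um)
    truth.neurons.to_csv(out / "ground_truth_neurons.csv", index=False)
    write_json(
        out / "ground_truth.json",
        {
            "n_neurons": int(len(truth.neurons)),
            "n_responders": int(truth.neurons["responder"].sum()),
            "drift_px_per_frame": list(params.drift_px_per_frame),
            "stimulus": {
                "label": params.stimulus_label,
                "start_s": params.stimulus_window[0],
                "end_s": params.stimulus_window[1],
            },
        },
    )
    _write_provenance(out, "simulate-calcium", _params_dict(params))
    return out


def simulate_mito_run(params: MitoSimParams, out_dir: str | Path) -> Path:
    """Simulate one TMRE stack; write stack, mask and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, mask, truth = simulate_mito_stack(params)
    write_image(
        out / "stack.ome.tif",
        stack.voxels,
        axes="TZYX",
        pixel_size_um=params.voxel_size_um,
        frame_interval_s=params.frame_interval_s,
    )
    write_image(
        out / "ganglion_mask.ome.tif",
        mask.mask.astype(np.uint8),
        axes="ZYX",
        pixel_size_um=params.voxel_size_um,
    )
    truth.mitochondria.to_csv(out / "ground_truth_mitochondria.csv", index=False)
    np.savetxt(
        out / "ground_truth_intensity.csv",
        truth.true_mean_intensity,
        delimiter=",",
        header="per-mitochondrion rows, per-frame columns",
    )
    _write_provenance(out, "simulate-mito", _params_dict(params))
    return out


def analyze_calcium_run(
    movie_path: str | Path,
    rois_path: str | Path,
    protocol_path: str | Path | None,
    out_dir: str | Path,
    frame_interval_s: float | None = None,
    pixel_size_um: float | None = None,
    noise_method: str = "std",
    amplitude_over: str = "all",
) -> pd.DataFrame:
    """Registration -> traces -> transient calls -> per-stimulus summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, meta = read_image(movie_path, expected_ndim=3)
    dt = frame_interval_s or meta.get("frame_interval_s")
    if dt is None:
        raise ValueError(
            "frame interval not in image metadata; pass frame_interval_s"
        )
    px = pixel_size_um or meta.get("pixel_size_x_um") or 1.0
    windows = read_protocol(protocol_path) if protocol_path else []
    if not windows:
        raise ValueError("a stimulus protocol is required")
    movie = CalciumMovie(
        frames=np.clip(np.asarray(frames, dtype=np.float64), 0, None),
        frame_interval_s=float(dt),
        pixel_size_um=float(px),
        stimulus_windows=windows,
    )
    reg = register_to_first(movie)
    rois = read_rois(rois_path, movie.frames.shape[1:])
    calls, summaries = analyze_movie(
        reg.movie, rois, noise_method=noise_method, amplitude_over=amplitude_over
    )
    calls_df = pd.DataFrame(
        [
            {
                "roi_id": c.roi_id,
                "stimulus": c.stimulus,
                "responder": c.responder,
                "max_amplitude_pct": c.max_amplitude_pct,
                "peak_time_s": c.peak_time_s,
            }
            for c in calls
        ]
    )
    calls_df.to_csv(out / "transient_calls.csv", index=False)
    summary_df = pd.DataFrame(
        [
            {
                "stimulus": s.stimulus,
                "n_neurons": s.n_neurons,
                "pct_responders": s.pct_responders,
                "mean_max_amplitude_pct": s.mean_max_amplitude_pct,
            }
            for s in summaries.values()
        ]
    ).sort_values("stimulus")
    summary_df.to_csv(out / "stimulus_summary.csv", index=False)
    np.savetxt(out / "registration_shifts.csv", reg.shifts, delimiter=",",
               header="dy_px,dx_px")
    _write_provenance(
        out,
        "analyze-calcium",
        {
            "movie": str(movie_path),
            "rois": str(rois_path),
            "frame_interval_s": float(dt),
            "pixel_size_um": float(px),
            "noise_method": noise_method,
            "amplitude_over": amplitude_over,
        },
    )
    return summary_df


def analyze_mito_run(
    stack_path: str | Path,
    mask_path: str | Path,
    out_dir: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    frame_interval_s: float | None = None,
    threshold: float | None = None,
    min_distance_um: float = 1.0,
    log_sigma_um: float = 0.5,
    top_n: int = 500,
) -> dict:
    """Correction -> morphometry on frame 0 -> fluctuation when T > 1."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    voxels, meta = read_image(stack_path, expected_ndim=4 if _is_4d(stack_path) else 3)
    vsize = voxel_size_um or _voxel_from_meta(meta)
    if vsize is None:
        raise ValueError("voxel size not in image metadata; pass voxel_size_um")
    dt = frame_interval_s or meta.get("frame_interval_s", 1.0)
    stack = MitoStack(
        voxels=np.asarray(voxels, dtype=np.float64),
        voxel_size_um=vsize,
        frame_interval_s=float(dt),
    )
    mask_arr, _ = read_image(mask_path, expected_ndim=3)
    mask = GanglionMask(mask_arr > 0, vsize)

    stack, bg = correct_background(stack, mask)
    factors = np.ones(stack.n_frames)
    if stack.n_frames > 1:
        stack, factors = correct_bleach(stack)
    seg = segment_stack_frame(
        stack.frame(0),
        mask,
        threshold=threshold,
        min_distance_um=min_distance_um,
        log_sigma_um=log_sigma_um,
    )
    top = select_top_spots(seg.spots, n=top_n)
    pd.DataFrame(
        [
            {
                "spot_id": s.id,
                "z_um": s.centroid_um[0],
                "y_um": s.centroid_um[1],
                "x_um": s.centroid_um[2],
                "centre_intensity": s.centre_intensity,
            }
            for s in top
        ]
    ).to_csv(out / "spots.csv", index=False)
    summary = {
        "background": bg,
        "bleach_factors": factors.tolist(),
        "total_mito_volume_um3": seg.total_mito_volume_um3,
        "volume_ratio": seg.volume_ratio,
        "n_spots": len(seg.spots),
        "density_per_1000um3": seg.density_per_1000um3,
        "mean_single_volume_um3": seg.mean_single_volume_um3,
        "mask_volume_um3": mask.volume_um3,
    }
    if stack.n_frames >= 10:
        series = track_and_fluctuate(
            stack,
            top,
            mask,
            min_distance_um=min_distance_um,
            log_sigma_um=log_sigma_um,
        )
        summary["fluctuation_score_pct"] = mean_fluctuation_score(series)
        summary["n_tracked"] = len(series)
    write_json(out / "mito_summary.json", summary)
    _write_provenance(
        out,
        "analyze-mito",
        {
            "stack": str(stack_path),
            "mask": str(mask_path),
            "voxel_size_um": list(vsize),
            "threshold": threshold,
            "min_distance_um": min_distance_um,
            "log_sigma_um": log_sigma_um,
            "top_n": top_n,
        },
    )
    return summary


def _is_4d(path: str | Path) -> bool:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        axes = tf.series[0].axes
    return "T" in axes and "Z" in axes


def _voxel_from_meta(meta: dict) -> tuple[float, float, float] | None:
    try:
        return (
            meta["pixel_size_z_um"],
            meta["pixel_size_y_um"],
            meta["pixel_size_x_um"],
        )
    except KeyError:
        return None


def cohort_stats_run(
    summaries_csv: str | Path,
    clinical_csv: str | Path | None,
    out_path: str | Path,
) -> pd.DataFrame:
    """Join per-subject summaries with clinical covariates and run the
    paired cohort comparison; write the results table CSV."""
    df = pd.read_csv(summaries_csv)
    if clinical_csv is not None:
        clin = pd.read_csv(clinical_csv)
        df = df.merge(clin, on=[c for c in ("subject_id", "pair_id", "group")
                                if c in clin.columns], how="left")
    results = run_cohort_comparison(df)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_path, index=False, float_format="%.10g")
    return results


def full_run(
    out_dir: str | Path,
    seed: int = 0,
    n_pairs: int = 6,
    calcium_kwargs: dict | None = None,
    mito_kwargs: dict | None = None,
) -> pd.DataFrame:
    """End-to-end regression fixture: simulate a small paired cohort of
    subjects (one calcium movie and one TMRE stack each), run both analysis
    pipelines per subject, and compare the groups.

    The per-subject simulations are kept small (a dozen neurons, a modest
    stack) so the whole run finishes in well under a minute; all seeds are
    derived deterministically from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    subjects: list[SubjectSummary] = []
    for pair in range(n_pairs):
        for group in ("control", "PD"):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cal_params = CalciumSimParams(
                n_neurons=12,
                responder_fraction=0.6,
                n_frames=80,
                stimulus_window=(15.0, 25.0),
                seed=sub_seed,
                **(calcium_kwargs or {}),
            )
            movie, truth = simulate_calcium_movie(cal_params)
            reg = register_to_first(movie)
            rois = rois_from_label_mask(truth.label_mask)
            _calls, summaries = analyze_movie(reg.movie, rois)
            s = summaries[cal_params.stimulus_label]

            mito_params = MitoSimParams(
                n_mito=40,
                shape_vox=(20, 16, 72, 72),
                min_separation_um=2.5,
                seed=sub_seed + 1,
                **(mito_kwargs or {}),
            )
            stack, mask, _mtruth = simulate_mito_stack(mito_params)
            stack, _bg = correct_background(stack, mask)
            stack, _f = correct_bleach(stack)
            seg = segment_stack_frame(stack.frame(0), mask)
            series = track_and_fluctuate(stack, select_top_spots(seg.spots, 500), mask)
            subjects.append(
                SubjectSummary(
                    subject_id=f"P{pair:02d}-{group}",
                    pair_id=pair,
                    group=group,
                    metrics={
                        "pct_responders": s.pct_responders,
                        "mean_max_amplitude_pct": s.mean_max_amplitude_pct,
                        "volume_ratio": seg.volume_ratio,
                        "density_per_1000um3": seg.density_per_1000um3,
                        "mean_single_volume_um3": seg.mean_single_volume_um3,
                        "fluctuation_score_pct": mean_fluctuation_score(series),
                    },
                    covariates={
                        "age": float(np.round(rng.normal(58.0, 9.0), 1)),
                        "scopa_gi": float(
                            np.round(
                                np.clip(
                                    rng.normal(2.7 if group == "PD" else 0.9, 1.2), 0, 12
                                ),
                                1,
                            )
                        ),
                        **(
                            {
                                "updrs3_off": float(
                                    np.round(np.clip(rng.normal(23.3, 10.0), 5, 60), 1)
                                ),
                                "disease_duration_years": float(
                                    np.round(np.clip(rng.normal(7.8, 3.9), 2, 17), 1)
                                ),
                            }
                            if group == "PD"
                            else {}
                        ),
                    },
                )
            )
    df = cohort_frame(subjects)
    df.to_csv(out / "subject_summaries.csv", index=False, float_format="%.10g")
    results = run_cohort_comparison(df)
    results.to_csv(out / "cohort_results.csv", index=False, float_format="%.10g")
    _write_provenance(
        out,
        "full-run",
        {"seed": seed, "n_pairs": n_pairs},
    )
    return results
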