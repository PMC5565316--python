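"""Tracking and membrane-potential fluctuation quantification.

TMRE partitions into mitochondria in proportion to membrane potential, so
the temporal variation of a tracked mitochondrion's fluorescence reports
potential dynamics. Spots detected on frame 0 are linked frame-to-frame by
greedy nearest-neighbour matching inside a displacement gate; per-frame
intensity is the mean over a fixed-radius sphere around the tracked centre.

The fluctuation score of one mitochondrion is the temporal standard
deviation of its percent deviation from its own temporal mean — i.e. the
coefficient of variation in percent. The subject-level value is the mean
score over all tracked mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from calmito.mito.segmentation import Spot, detect_spots
from calmito.mito.stack import GanglionMask, MitoStack


@dataclass
class FluctuationSeries:
    spot_id: int
    intensity: np.ndarray
    variation_pct: np.ndarray
    fluctuation_score_pct: float


def fluctuation_series(spot_id: int, intensity: np.ndarray) -> FluctuationSeries:
    """Percent-deviation series and CV% score for one intensity series.

    variation_pct(t) = 100 * (I(t) - mean_t I) / mean_t I, which is
    zero-mean by construction; the score is its population standard
    deviation (equivalently 100 x the temporal coefficient of variation).
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.ndim != 1 or len(intensity) < 2:
        raise ValueError("need a 1-D intensity series of length >= 2")
    mean = intensity.mean()
    if mean <= 0:
        raise ValueError("mean intensity must be positive")
    variation = 100.0 * (intensity - mean) / mean
    return FluctuationSeries(
        spot_id=spot_id,
        intensity=intensity,
        variation_pct=variation,
        fluctuation_score_pct=float(variation.std(ddof=0)),
    )


def _sphere_offsets(
    radius_um: float, voxel_size_um: tuple[float, float, float]
) -> np.ndarray:
    vsize = np.asarray(voxel_size_um)
    half = np.maximum(np.floor(radius_um / vsize).astype(int), 0)
    zz, yy, xx = np.mgrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    offsets = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    dist = np.sqrt(((offsets * vsize) ** 2).sum(axis=1))
    return offsets[dist <= radius_um + 1e-9]


def _sample_sphere(
    frame: np.ndarray, centre_vox: np.ndarray, offsets: np.ndarray
) -> float:
    coords = centre_vox[None, :] + offsets
    shape = np.asarray(frame.shape)
    ok = np.all((coords >= 0) & (coords < shape), axis=1)
    return float(frame[tuple(coords[ok].T)].mean())


def track_and_fluctuate(
    stack: MitoStack,
    spots_t0: list[Spot],
    mask: GanglionMask,
    max_displacement_um_per_frame: float = 1.0,
    sample_radius_um: float = 0.5,
    min_frames: int = 10,
    **detect_kwargs,
) -> list[FluctuationSeries]:
    """Track frame-0 spots through the stack and score their fluctuations.

    Spots are re-detected on every frame; each live track is linked to the
    nearest detection within the displacement gate (greedy, one-to-one,
    brightest-track-first) and dropped once no detection matches. Dropped
    tracks are excluded entirely — a partial series would bias the CV.
    """
    if stack.n_frames < min_frames:
        raise ValueError(f"need >= {min_frames} frames; got {stack.n_frames}")
    if not spots_t0:
        raise ValueError("no spots to track")
    offsets = _sphere_offsets(sample_radius_um, stack.voxel_size_um)
    vsize = np.asarray(stack.voxel_size_um)

    order = sorted(range(len(spots_t0)), key=lambda i: -spots_t0[i].centre_intensity)
    positions = {i: np.asarray(spots_t0[i].centroid_um) for i in order}
    alive = list(order)
    samples: dict[int, list[float]] = {
        i: [
            _sample_sphere(
                stack.frame(0),
                np.round(positions[i] / vsize - 0.5).astype(int),
                offsets,
            )
        ]
        for i in alive
    }

    for t in range(1, stack.n_frames):
        frame = stack.frame(t)
        detections = detect_spots(frame, mask, **detect_kwargs)
        det_pos = np.array([d.centroid_um for d in detections])
        taken = np.zeros(len(detections), dtype=bool)
        tree = cKDTree(det_pos) if len(detections) else None
        still_alive = []
        for i in alive:
            match = None
            if tree is not None:
                for j in tree.query_ball_point(
                    positions[i], r=max_displacement_um_per_frame
                ):
                    if not taken[j] and (
                        match is None
                        or np.linalg.norm(det_pos[j] - positions[i])
                        < np.linalg.norm(det_pos[match] - positions[i])
                    ):
                        match = j
            if match is None:
                continue  # track lost
            taken[match] = True
            positions[i] = det_pos[match]
            samples[i].append(
                _sample_sphere(
                    frame, np.round(positions[i] / vsize - 0.5).astype(int), offsets
                )
            )
            still_alive.append(i)
        alive = still_alive
        if not alive:
            break

    full = [i for i in alive if len(samples[i]) == stack.n_frames]
    if not full:
        raise ValueError("no spots survived tracking through the whole recording")
    return [fluctuation_series(i, np.asarray(samples[i])) for i in sorted(full)]


def mean_fluctuation_score(series: list[FluctuationSeries]) -> float:
    """Subject-level fluctuation: mean CV% over tracked mitochondria."""
    if not series:
        raise ValueError("no fluctuation series")
    return float(np.mean([s.fluctuation_score_pct for s in series]))
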