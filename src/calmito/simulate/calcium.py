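"""Synthetic calcium-imaging movies with known ground truth.

Emulates a ganglion of somata imaged through a widefield time-lapse: a
configurable fraction of neurons respond to a stimulus with a
stimulus-locked transient (instantaneous rise to baseline*(1+A/100),
single-exponential decay), non-responders stay flat; additive Gaussian
pixel noise, optional photon (Poisson) noise and optional global rigid
drift. Responder flags, true amplitudes and the ROI label mask are returned
as ground truth, so the downstream detector can be scored without any real
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from calmito.calcium.movie import CalciumMovie, StimulusWindow


@dataclass
class CalciumSimParams:
    """Study conditions for one simulated movie.

    Defaults mirror the acquisition protocol being emulated: a 10 s high-K+
    depolarization delivered after a resting baseline, ganglia of a handful
    to a few tens of somata, amplitudes given as %dF/F0. Frame rate and bit
    depth are unreported for the real recordings; 2 Hz float images are the
    configurable stand-in.
    """

    n_neurons: int = 12
    responder_fraction: float = 0.6
    true_amplitude_pct: tuple[float, float] = (20.0, 5.0)  # (mean, sd)
    baseline_intensity: float = 100.0
    noise_sd: float = 2.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)  # (dy, dx)
    frame_interval_s: float = 0.5
    n_frames: int = 120
    stimulus_window: tuple[float, float] = (20.0, 30.0)
    stimulus_label: str = "highK"
    soma_radius_px: int = 4
    decay_tau_s: float = 5.0
    min_amplitude_pct: float = 0.5
    field_shape: tuple[int, int] | None = None  # (Y, X); auto-sized if None
    pixel_size_um: float = 0.3
    poisson_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("frame_interval_s and decay_tau_s must be positive")
        start, end = self.stimulus_window
        if not (0.0 <= start < end <= self.n_frames * self.frame_interval_s):
            raise ValueError("stimulus window must lie inside the recording")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.soma_radius_px < 1:
            raise ValueError("soma_radius_px must be >= 1")


@dataclass
class CalciumGroundTruth:
    """One record per simulated neuron, plus the frame-0 ROI label mask."""

    neurons: pd.DataFrame  # roi_id, center_y, center_x, responder, true_amplitude_pct
    label_mask: np.ndarray  # (Y, X) int, 0 = background, roi_id elsewhere
    drift_px: np.ndarray  # (T, 2) cumulative (dy, dx) applied per frame
    params: CalciumSimParams = field(repr=False, default=None)  # type: ignore[assignment]


def _place_somata(params: CalciumSimParams, rng: np.random.Generator):
    """Non-overlapping soma centres on a jittered grid.

    The grid guarantees no overlap by construction when the field is large
    enough; a field too small for the requested neuron count is an error.
    """
    r = params.soma_radius_px
    gap = 3  # pixels of guaranteed clearance between somata
    cell = 2 * r + gap
    if params.field_shape is None:
        ncols = int(np.ceil(np.sqrt(params.n_neurons)))
        nrows = int(np.ceil(params.n_neurons / ncols))
        ny = nrows * cell + 2 * gap
        nx = ncols * cell + 2 * gap
    else:
        ny, nx = params.field_shape
        nrows = (ny - 2 * gap) // cell
        ncols = (nx - 2 * gap) // cell
        if nrows * ncols < params.n_neurons:
            raise ValueError(
                f"cannot place {params.n_neurons} somata of radius {r} px "
                f"without overlap in a {(ny, nx)} field"
            )
    cells = [(i, j) for i in range(nrows) for j in range(ncols)]
    idx = rng.permutation(len(cells))[: params.n_neurons]
    jitter_max = gap / 2.0 - 0.5
    centers = []
    for k in idx:
        i, j = cells[k]
        cy = gap + i * cell + cell / 2.0 + rng.uniform(-jitter_max, jitter_max)
        cx = gap + j * cell + cell / 2.0 + rng.uniform(-jitter_max, jitter_max)
        centers.append((cy, cx))
    return np.array(centers), (ny, nx)


def simulate_calcium_movie(
    params: CalciumSimParams,
) -> tuple[CalciumMovie, CalciumGroundTruth]:
    """Render a movie under the stated conditions and return its truth.

    The responder count is exact — round(responder_fraction * n_neurons)
    neurons, chosen at random, carry a transient — so the simulated truth
    equals the nominal fraction rather than a binomial draw around it.
    Amplitudes are N(mean, sd) clipped below at min_amplitude_pct.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    centers, (ny, nx) = _place_somata(params, rng)

    n_resp = int(round(params.responder_fraction * params.n_neurons))
    responder = np.zeros(params.n_neurons, dtype=bool)
    responder[rng.permutation(params.n_neurons)[:n_resp]] = True
    amp_mean, amp_sd = params.true_amplitude_pct
    amplitudes = np.where(
        responder,
        np.clip(
            rng.normal(amp_mean, amp_sd, params.n_neurons), params.min_amplitude_pct, None
        ),
        0.0,
    )

    # per-neuron F(t): flat baseline, instantaneous rise at stimulus onset,
    # exponential decay with tau
    times = np.arange(params.n_frames) * params.frame_interval_s
    t_on_idx = int(np.ceil(params.stimulus_window[0] / params.frame_interval_s - 1e-9))
    t_on = times[t_on_idx]
    kinetics = np.where(
        times >= t_on, np.exp(-(times - t_on) / params.decay_tau_s), 0.0
    )
    traces = params.baseline_intensity * (
        1.0 + (amplitudes[:, None] / 100.0) * kinetics[None, :]
    )  # (N, T)

    # rasterize somata as hard disks; label mask in frame-0 coordinates
    yy, xx = np.mgrid[0:ny, 0:nx]
    label_mask = np.zeros((ny, nx), dtype=np.int32)
    disks = []
    for i, (cy, cx) in enumerate(centers):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= params.soma_radius_px**2
        disks.append(disk)
        label_mask[disk] = i + 1

    frames = np.zeros((params.n_frames, ny, nx), dtype=np.float64)
    for i, disk in enumerate(disks):
        frames[:, disk] = traces[i][:, None]

    drift = np.asarray(params.drift_px_per_frame, dtype=np.float64)
    cum_drift = np.arange(params.n_frames)[:, None] * drift[None, :]
    if np.any(drift != 0):
        for t in range(1, params.n_frames):
            frames[t] = ndi.shift(frames[t], cum_drift[t], order=1, mode="nearest")

    if params.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(np.float64)
    if params.noise_sd > 0:
        frames = frames + rng.normal(0.0, params.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)

    movie = CalciumMovie(
        frames=frames.astype(np.float32),
        frame_interval_s=params.frame_interval_s,
        pixel_size_um=params.pixel_size_um,
        stimulus_windows=[
            StimulusWindow(params.stimulus_label, *params.stimulus_window)
        ],
    )
    truth = CalciumGroundTruth(
        neurons=pd.DataFrame(
            {
                "roi_id": np.arange(1, params.n_neurons + 1),
                "center_y": centers[:, 0],
                "center_x": centers[:, 1],
                "responder": responder,
                "true_amplitude_pct": amplitudes,
            }
        ),
        label_mask=label_mask,
        drift_px=cum_drift,
        params=params,
    )
    return movie, truth
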