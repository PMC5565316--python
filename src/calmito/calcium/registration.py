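"""Rigid registration of a movie to its first frame.

Perfusion and tissue drift displace the field of view over a recording;
every frame is translated back onto frame 0 before ROI traces are read out.
Translation-only, subpixel, via phase cross-correlation with 10x upsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from calmito.calcium.movie import CalciumMovie


@dataclass
class RegistrationResult:
    """Registered movie plus per-frame shift vectors.

    shifts[t] is the (dy, dx) translation that was applied to frame t to
    align it with frame 0 (so a frame drifted by +d gets shift -d).
    filled[t] is the fraction of pixels in frame t that were filled with
    edge values because the shift moved them in from outside the frame.
    """

    movie: CalciumMovie
    shifts: np.ndarray
    filled: np.ndarray


def register_to_first(
    movie: CalciumMovie,
    upsample_factor: int = 10,
    large_shift_warn_frac: float = 0.2,
) -> RegistrationResult:
    """Register every frame of a movie to the first frame.

    Each frame is translated (linear interpolation, edge padding) to maximize
    its phase cross-correlation with frame 0. A warning (never an error) is
    emitted when any shift exceeds ``large_shift_warn_frac`` of the image
    width: such recordings are usually unusable, but the decision is the
    analyst's.
    """
    frames = np.asarray(movie.frames, dtype=np.float64)
    ref = frames[0]
    t_dim, ny, nx = frames.shape
    out = np.empty_like(frames)
    out[0] = ref
    shifts = np.zeros((t_dim, 2))
    filled = np.zeros(t_dim)
    for t in range(1, t_dim):
        shift, _err, _phase = phase_cross_correlation(
            ref, frames[t], upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = shift
        if np.allclose(shift, 0.0):
            out[t] = frames[t]
        else:
            out[t] = ndi.shift(frames[t], shift, order=1, mode="nearest")
            dy, dx = np.abs(shift)
            # pixels translated in from beyond the frame edge
            filled[t] = 1.0 - ((ny - min(dy, ny)) * (nx - min(dx, nx))) / (ny * nx)
    max_abs = np.abs(shifts).max() if t_dim > 1 else 0.0
    if max_abs > large_shift_warn_frac * nx:
        warnings.warn(
            f"registration shift {max_abs:.1f} px exceeds "
            f"{100 * large_shift_warn_frac:.0f}% of image width ({nx} px); "
            "check the recording for gross movement",
            stacklevel=2,
        )
    registered = CalciumMovie(
        frames=np.clip(out, 0.0, None),
        frame_interval_s=movie.frame_interval_s,
        pixel_size_um=movie.pixel_size_um,
        stimulus_windows=list(movie.stimulus_windows),
    )
    return RegistrationResult(movie=registered, shifts=shifts, filled=filled)
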