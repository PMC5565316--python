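"""Per-neuron fluorescence traces: extraction, F/F0 normalization, noise.

The baseline fluorescence F0 is the mean raw intensity over a pre-stimulus
baseline window; traces are expressed as the dimensionless ratio F/F0, so
the resting level is 1 by construction and a transient of amplitude a%
peaks at 1 + a/100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from calmito.calcium.movie import CalciumMovie, NeuronROI


@dataclass
class CalciumTrace:
    """An F/F0 trace for one neuron ROI.

    noise_sigma is the intrinsic noise level in ratio units, estimated from
    the detrended baseline; it defines the 5-sigma transient threshold.
    """

    roi_id: int
    F: np.ndarray
    F0: float
    ratio: np.ndarray
    baseline_window: tuple[int, int]
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        if self.F.shape != self.ratio.shape or self.F.ndim != 1:
            raise ValueError("F and ratio must be equal-length 1-D series")
        if self.F0 <= 0:
            raise ValueError("F0 must be positive")
        lo, hi = self.baseline_window
        if not (0 <= lo < hi <= len(self.F)):
            raise ValueError("baseline_window must be a valid [lo, hi) frame range")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def extract_trace(movie: CalciumMovie, roi: NeuronROI) -> np.ndarray:
    """Per-frame mean raw intensity over the ROI pixels.

    The movie is expected to be registered; the ROI (drawn on frame 0) is
    applied to every frame.
    """
    roi.check_bounds(movie.frames.shape[1:])
    ys, xs = roi.pixels[:, 0], roi.pixels[:, 1]
    return movie.frames[:, ys, xs].mean(axis=1)


def normalize_f0(
    F: np.ndarray,
    baseline_window: tuple[int, int],
    roi_id: int = 0,
) -> CalciumTrace:
    """Normalize a raw trace to its baseline: ratio = F / mean(F[baseline]).

    baseline_window is a half-open [lo, hi) frame range that must precede the
    first stimulus (enforced by the caller, who knows the protocol).
    """
    F = np.asarray(F, dtype=np.float64)
    lo, hi = baseline_window
    if not (0 <= lo < hi <= len(F)):
        raise ValueError("baseline_window must be a valid [lo, hi) frame range")
    f0 = float(F[lo:hi].mean())
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence F0 = {f0:.4g} must be positive")
    return CalciumTrace(
        roi_id=roi_id, F=F, F0=f0, ratio=F / f0, baseline_window=(lo, hi)
    )


def estimate_noise(
    trace: CalciumTrace,
    method: str = "std",
    min_baseline_frames: int = 10,
) -> float:
    """Intrinsic noise level of a trace, in ratio units.

    Spread of the baseline ratio samples after removing a linear trend (a
    slow bleach ramp must not inflate the noise estimate).

    method 'std' uses the sample standard deviation, 'mad' the
    1.4826-scaled median absolute deviation (robust to the occasional
    spontaneous event inside the baseline).
    """
    lo, hi = trace.baseline_window
    n = hi - lo
    if n < min_baseline_frames:
        raise ValueError(
            f"baseline window has {n} frames; need >= {min_baseline_frames} "
            "for a usable noise estimate"
        )
    y = trace.ratio[lo:hi]
    t = np.arange(n, dtype=np.float64)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    if method == "std":
        sigma = float(resid.std(ddof=1))
    elif method == "mad":
        sigma = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    else:
        raise ValueError(f"unknown noise estimator {method!r}")
    return sigma
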