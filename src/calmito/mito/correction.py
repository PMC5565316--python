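"""Background and photobleaching correction for TMRE stacks.

Background is a per-stack scalar (low-percentile estimate) subtracted and
clipped at zero. Bleach correction rescales every frame so its global mean
matches the first frame's, under the acquisition-order assumption that the
first image is the brightest.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from calmito.mito.stack import GanglionMask, MitoStack

#: percentile of (in-mask) intensities taken as the background level
BACKGROUND_PERCENTILE = 5.0


def estimate_background(
    stack: MitoStack, mask: GanglionMask | None = None, percentile: float = BACKGROUND_PERCENTILE
) -> float:
    """Scalar background level: low percentile of (in-mask) intensities."""
    if mask is not None:
        vals = stack.voxels[:, mask.mask]
    else:
        vals = stack.voxels
    return float(np.percentile(vals, percentile))


def correct_background(
    stack: MitoStack,
    mask: GanglionMask | None = None,
    percentile: float = BACKGROUND_PERCENTILE,
) -> tuple[MitoStack, float]:
    """Subtract the estimated scalar background, clipping at zero.

    Returns the corrected stack and the background estimate. A background at
    or above the stack maximum means the image contains no signal.
    """
    bg = estimate_background(stack, mask, percentile)
    if bg >= float(stack.voxels.max()):
        raise ValueError(
            f"estimated background {bg:.4g} is not below the maximum intensity; "
            "degenerate image"
        )
    corrected = np.clip(stack.voxels.astype(np.float64) - bg, 0.0, None)
    return replace(stack, voxels=corrected), bg


def correct_bleach(stack: MitoStack) -> tuple[MitoStack, np.ndarray]:
    """Rescale each frame so its global mean equals frame 0's.

    Correction factors are clipped to >= 1 and made monotone non-decreasing
    (cumulative-maximum projection): bleaching only loses signal over time,
    so an apparent brightening is fluctuation, not recovery of dye.

    Returns the corrected stack and the per-frame factors.
    """
    if stack.n_frames < 2:
        raise ValueError("bleach correction needs a time series (T >= 2)")
    means = stack.voxels.reshape(stack.n_frames, -1).mean(axis=1)
    if np.any(means <= 0):
        t_bad = int(np.argmax(means <= 0))
        raise ValueError(f"frame {t_bad} has non-positive mean intensity")
    factors = means[0] / means
    factors = np.maximum.accumulate(np.clip(factors, 1.0, None))
    corrected = stack.voxels.astype(np.float64) * factors[:, None, None, None]
    return replace(stack, voxels=corrected), factors
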