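"""Containers for calcium-imaging movies and neuron ROIs.

Conventions: (t, y, x) axis order, 0-based pixel indices, half-open time
windows [start_s, end_s) in seconds from the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KNOWN_STIMULI = ("highK", "DMPP", "ES", "custom")


@dataclass(frozen=True)
class StimulusWindow:
    """A labelled stimulus application window.

    label is one of highK (75 mM K+ depolarization, the viability test),
    DMPP (nicotinic agonist), ES (electrical field stimulation) or custom.
    """

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in KNOWN_STIMULI:
            raise ValueError(
                f"unknown stimulus label {self.label!r}; expected one of {KNOWN_STIMULI}"
            )
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError("require 0 <= start_s < end_s")


@dataclass
class CalciumMovie:
    """Single-channel time-lapse movie with acquisition metadata.

    frames: (T, Y, X) float array, arbitrary fluorescence units.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = 1.0
    stimulus_windows: list[StimulusWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, Y, X); got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("frame intensities must be >= 0")
        dur = self.duration_s
        for w in self.stimulus_windows:
            if w.end_s > dur + 1e-9:
                raise ValueError(
                    f"stimulus window {w} extends past the recording ({dur:.3f} s)"
                )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def frame_index(self, t_s: float) -> int:
        """Index of the first frame acquired at or after t_s."""
        return int(np.ceil(t_s / self.frame_interval_s - 1e-9))


@dataclass
class NeuronROI:
    """A neuron region of interest as an explicit pixel set.

    pixels: (N, 2) integer array of 0-based (y, x) indices.
    """

    id: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (N, 2) array of (y, x) indices")
        if self.pixels.shape[0] == 0:
            raise ValueError("ROI must contain at least one pixel")
        if self.pixels.min() < 0:
            raise ValueError("ROI pixel indices must be non-negative")

    @classmethod
    def from_mask(cls, roi_id: int, mask: np.ndarray) -> "NeuronROI":
        return cls(roi_id, np.argwhere(np.asarray(mask, dtype=bool)))

    def check_bounds(self, shape_yx: tuple[int, int]) -> None:
        ny, nx = shape_yx
        if self.pixels[:, 0].max() >= ny or self.pixels[:, 1].max() >= nx:
            raise ValueError(f"ROI {self.id} extends outside the {shape_yx} image")


def rois_from_label_mask(label_mask: np.ndarray) -> list[NeuronROI]:
    """Split an integer label image (0 = background) into ROIs.

    Raises if any label appears twice under different ids (cannot happen for a
    label image) and checks that ROIs are non-empty.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.ndim != 2:
        raise ValueError("label mask must be 2-D (Y, X)")
    labels = np.unique(label_mask)
    labels = labels[labels != 0]
    return [NeuronROI.from_mask(int(lab), label_mask == lab) for lab in labels]


def check_rois_disjoint(rois: list[NeuronROI]) -> None:
    """ROIs may not overlap: each pixel belongs to at most one neuron."""
    seen: set[tuple[int, int]] = set()
    for roi in rois:
        for y, x in map(tuple, roi.pixels):
            if (y, x) in seen:
                raise ValueError(f"ROIs overlap at pixel {(y, x)}")
            seen.add((y, x))
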