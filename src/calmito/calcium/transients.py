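"""Transient detection and per-stimulus responder summaries.

A neuron is a responder to a stimulus when its F/F0 peak inside the
evaluation window strictly exceeds baseline + 5x the intrinsic noise level
(baseline ratio = 1 by construction, so the threshold is 1 + 5*sigma).
The maximum amplitude is the percent change above baseline, dF/F0 * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from calmito.calcium.movie import CalciumMovie, NeuronROI, StimulusWindow
from calmito.calcium.traces import CalciumTrace, estimate_noise, extract_trace, normalize_f0

#: multiples of the intrinsic noise a peak must exceed to count as a transient
NOISE_MULTIPLIER = 5.0

#: seconds appended after the stimulus window when evaluating peaks —
#: transients outlast a 10 s stimulus application
DEFAULT_EVAL_TAIL_S = 10.0


@dataclass(frozen=True)
class TransientCall:
    roi_id: int
    stimulus: str
    responder: bool
    max_amplitude_pct: float
    peak_time_s: float
    threshold_ratio: float


@dataclass(frozen=True)
class StimulusSummary:
    stimulus: str
    n_neurons: int
    pct_responders: float
    mean_max_amplitude_pct: float
    amplitude_denominator: str  # 'all' or 'responders'


def detect_transient(
    trace: CalciumTrace,
    window: StimulusWindow,
    frame_interval_s: float,
    eval_tail_s: float = DEFAULT_EVAL_TAIL_S,
    noise_multiplier: float = NOISE_MULTIPLIER,
) -> TransientCall:
    """Call a transient for one trace and one stimulus window.

    The evaluation window is the stimulus window extended by ``eval_tail_s``
    and clipped to the recording; comparison with the threshold is strict
    (a peak exactly at 1 + 5*sigma is NOT a responder). The peak time is the
    first frame attaining the window maximum.
    """
    if trace.noise_sigma is None:
        raise ValueError("trace.noise_sigma must be computed before detection")
    n = len(trace.ratio)
    lo = int(np.ceil(window.start_s / frame_interval_s - 1e-9))
    hi = int(np.ceil((window.end_s + eval_tail_s) / frame_interval_s - 1e-9))
    lo, hi = max(lo, 0), min(hi, n)
    if hi <= lo:
        raise ValueError(
            f"evaluation window for {window.label} [{window.start_s}, "
            f"{window.end_s}+{eval_tail_s}) s contains no frames"
        )
    seg = trace.ratio[lo:hi]
    k = int(np.argmax(seg))
    peak = float(seg[k])
    threshold = 1.0 + noise_multiplier * trace.noise_sigma
    responder = peak > threshold
    return TransientCall(
        roi_id=trace.roi_id,
        stimulus=window.label,
        responder=responder,
        max_amplitude_pct=max(peak - 1.0, 0.0) * 100.0,
        peak_time_s=(lo + k) * frame_interval_s,
        threshold_ratio=threshold,
    )


def summarize_stimulus(
    calls: list[TransientCall],
    amplitude_over: str = "all",
) -> StimulusSummary:
    """Fraction of responding neurons and mean maximum amplitude.

    amplitude_over selects the denominator of the amplitude mean: 'all'
    analysed neurons (default) or 'responders' only. With no responders the
    'responders' mean is reported as 0.
    """
    if not calls:
        raise ValueError("need at least one transient call")
    stimuli = {c.stimulus for c in calls}
    if len(stimuli) != 1:
        raise ValueError(f"mixed stimulus labels in one summary: {sorted(stimuli)}")
    if amplitude_over not in ("all", "responders"):
        raise ValueError("amplitude_over must be 'all' or 'responders'")
    n = len(calls)
    n_resp = sum(c.responder for c in calls)
    if amplitude_over == "all":
        amps = [c.max_amplitude_pct for c in calls]
    else:
        amps = [c.max_amplitude_pct for c in calls if c.responder]
    return StimulusSummary(
        stimulus=stimuli.pop(),
        n_neurons=n,
        pct_responders=100.0 * n_resp / n,
        mean_max_amplitude_pct=float(np.mean(amps)) if amps else 0.0,
        amplitude_denominator=amplitude_over,
    )


def analyze_movie(
    movie: CalciumMovie,
    rois: list[NeuronROI],
    baseline_window: tuple[int, int] | None = None,
    noise_method: str = "std",
    eval_tail_s: float = DEFAULT_EVAL_TAIL_S,
    amplitude_over: str = "all",
) -> tuple[list[TransientCall], dict[str, StimulusSummary]]:
    """Trace extraction + normalization + detection for every ROI and stimulus.

    The movie must already be registered. The default baseline window is all
    frames before the first stimulus; it must not overlap any stimulus.
    """
    if not movie.stimulus_windows:
        raise ValueError("movie carries no stimulus windows")
    first_stim_s = min(w.start_s for w in movie.stimulus_windows)
    if baseline_window is None:
        baseline_window = (0, movie.frame_index(first_stim_s))
    if baseline_window[1] * movie.frame_interval_s > first_stim_s + 1e-9:
        raise ValueError("baseline window overlaps a stimulus")
    calls: list[TransientCall] = []
    for roi in rois:
        F = extract_trace(movie, roi)
        trace = normalize_f0(F, baseline_window, roi_id=roi.id)
        trace.noise_sigma = estimate_noise(trace, method=noise_method)
        for window in movie.stimulus_windows:
            calls.append(
                detect_transient(
                    trace, window, movie.frame_interval_s, eval_tail_s=eval_tail_s
                )
            )
    summaries = {
        label: summarize_stimulus(
            [c for c in calls if c.stimulus == label], amplitude_over=amplitude_over
        )
        for label in {c.stimulus for c in calls}
    }
    return calls, summaries
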