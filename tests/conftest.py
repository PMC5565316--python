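"""Shared fixtures: small seeded simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from calmito.mito import correct_background
from calmito.simulate import (
    CalciumSimParams,
    MitoSimParams,
    simulate_calcium_movie,
    simulate_mito_stack,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def small_calcium():
    """A 30-neuron noisy movie with known responders (no drift)."""
    params = CalciumSimParams(n_neurons=30, responder_fraction=0.5, seed=101)
    movie, truth = simulate_calcium_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def drifting_calcium():
    """A movie with constant rigid drift, for registration tests."""
    params = CalciumSimParams(
        n_neurons=16, responder_fraction=0.5, drift_px_per_frame=(0.5, 0.25),
        n_frames=40, stimulus_window=(8.0, 18.0), seed=202,
    )
    movie, truth = simulate_calcium_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def small_mito():
    """A clean single-frame stack of well-separated mitochondria."""
    params = MitoSimParams(
        n_mito=60, shape_vox=(1, 24, 112, 112), min_separation_um=2.5,
        fluctuation_cv_pct=0.0, seed=303,
    )
    stack, mask, truth = simulate_mito_stack(params)
    corrected, bg = correct_background(stack, mask)
    return params, corrected, mask, truth
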