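"""Shared fixtures: a small, fast acquisition geometry for unit tests.

The desk-size geometry (48 tracks x 900 samples, ~14 mm deep phantom
with 2.5 / 5.5 / 3 mm layers) keeps per-test simulation under a second
while preserving the physics of the full-size frames.
"""

import dataclasses

import numpy as np
import pytest

from nanoecho import (AcquisitionSpec, PhantomSpec, WindowSpec,
                      simulate_acquisition)


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionSpec:
    return AcquisitionSpec(n_tracks=48, n_samples=900)


@pytest.fixture(scope="session")
def small_phantom() -> PhantomSpec:
    return PhantomSpec(layer_boundaries_mm=(1.5, 4.0, 9.5, 12.5), seed=7)


@pytest.fixture(scope="session")
def small_window() -> WindowSpec:
    return WindowSpec(6, 70, 3, 20)


@pytest.fixture(scope="session")
def small_sim(small_acq, small_phantom):
    """One simulated 2-frame acquisition at the default concentration."""
    return simulate_acquisition(small_phantom, small_acq, 2, seed=11)


@pytest.fixture(scope="session")
def small_control_sim(small_acq, small_phantom):
    ph = dataclasses.replace(small_phantom, hnt_number_conc=0.0)
    return simulate_acquisition(ph, small_acq, 2, seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
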