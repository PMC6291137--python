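"""Shared fixtures: rendered synthetic datasets reused across modules.

Heavier renders (full instrument axis) are session-scoped so the suite
pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from aurimsi import synth


@pytest.fixture(scope="session")
def uniform_noiseless():
    """2x2 homogeneous scene, zero noise/baseline/drift: exact truth."""
    inst = synth.InstrumentModel(noise_sd=0.0, baseline_amplitude=0.0, detector_offset=0.0)
    scene = synth.default_scene("uniform", seed=5, grid_shape=(2, 2))
    ds, truth = synth.render_dataset(scene, inst, seed=5)
    return scene, inst, ds, truth


@pytest.fixture(scope="session")
def uniform_noisy():
    """2x2 homogeneous scene with the default noise model, no drift."""
    inst = synth.InstrumentModel()
    scene = synth.default_scene("uniform", seed=11, grid_shape=(2, 2))
    ds, truth = synth.render_dataset(scene, inst, seed=11)
    return scene, inst, ds, truth


@pytest.fixture(scope="session")
def brain_scene_ds():
    """20x20 brain-like phantom with default instrument (no drift)."""
    scene = synth.default_scene("brain_like", seed=2)
    ds, truth = synth.render_dataset(scene, seed=2)
    return scene, ds, truth


@pytest.fixture(scope="session")
def small_instrument():
    """Coarse-axis instrument for plumbing tests where speed matters."""
    return synth.InstrumentModel(axis_points=40_000)


def rand_peak_list(rng: np.random.Generator, n: int):
    """Random centroided peak list spanning the instrument range."""
    from aurimsi.preprocess import Peak

    mzs = np.sort(rng.uniform(75, 1150, n))
    heights = rng.lognormal(3.0, 1.0, n)
    return [Peak(float(m), float(h), float(h * 0.07), float(h)) for m, h in zip(mzs, heights)]
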