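import numpy as np
import pytest

import herbspec as hs
from herbspec import synth


@pytest.fixture(scope="session")
def axis():
    return hs.make_axis()


@pytest.fixture(scope="session")
def small_truth():
    design = synth.StudyDesign(sulfur_levels=(0, 50, 100),
                               replicates_per_level=2)
    return hs.simulate_study(design, seed=7)


@pytest.fixture(scope="session")
def scene(small_truth, axis):
    return hs.render_scene(small_truth, axis=axis, shape=(64, 96), seed=11)


@pytest.fixture(scope="session")
def refl(scene, axis):
    raw = hs.HyperCube(scene.raw, axis, kind="raw")
    return hs.calibrate(raw, scene.white, scene.dark)


@pytest.fixture(scope="session")
def mask(refl):
    return hs.segment(refl)


@pytest.fixture(scope="session")
def study_spectra():
    """Small analytical study: mean spectra straight from the forward
    model (no image rendering), for fast selector/model tests."""
    ax = hs.make_axis()
    win = ax.window_indices(975, 1646)
    lam = ax.centers[win]
    truth = hs.simulate_study(seed=1)
    rng = np.random.default_rng(21)
    e = {a: synth.absorptivity(a, lam) for a in synth.ANALYTES}
    base = synth.baseline(lam)
    absorb = sum(
        np.outer(truth[a].to_numpy(), e[a]) for a in synth.ANALYTES
    )
    X = base[None, :] * 10.0 ** (-absorb)
    X = X + 3e-4 * rng.standard_normal(X.shape)  # mean-spectrum-level noise
    return truth, X, lam
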