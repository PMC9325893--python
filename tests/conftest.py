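import numpy as np
import pytest

from plvquant.synthgen import NucleiScene3D, VesselScene2D, gen_confocal3d, gen_vessel2d


@pytest.fixture
def make_vessel():
    """Short (1 mm) vessel factory; keeps per-test rendering fast."""

    def _make(coverage=0.7, pattern="banded_heterogeneous", seed=0, **kw):
        kw.setdefault("length_mm", 1.0)
        scene = VesselScene2D(
            coverage_true=coverage, pattern=pattern, seed=seed, **kw
        )
        return gen_vessel2d(scene)

    return _make


@pytest.fixture
def make_stack():
    """Small confocal stack factory (60 in-sheath nuclei by default)."""

    def _make(seed=0, **kw):
        kw.setdefault("n_nuclei_inside", 60)
        kw.setdefault("n_distractors", 15)
        scene = NucleiScene3D(seed=seed, **kw)
        return gen_confocal3d(scene), scene

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
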