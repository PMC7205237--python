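"""Shared fixtures: synthetic scenes and their derived stacks/masks.

Scenes are generated once per session; every test consumes the same
deterministic instances.
"""

import numpy as np
import pytest

import vegseg as vs


@pytest.fixture(scope="session")
def five_scene():
    return vs.benchmark_scene("five_class_easy", size=192, seed=3)


@pytest.fixture(scope="session")
def five_stack(five_scene):
    return vs.build_stack(vs.scale_dn(five_scene.raster))


@pytest.fixture(scope="session")
def five_mask(five_stack):
    return vs.mask_impervious(five_stack, seed=1)


@pytest.fixture(scope="session")
def shadow_scene():
    return vs.benchmark_scene("shadow_river", size=192, seed=5)


@pytest.fixture(scope="session")
def shadow_stack(shadow_scene):
    return vs.build_stack(vs.scale_dn(shadow_scene.raster))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


def make_raster(values, names=("blue", "green", "red", "nir"), **kw):
    return vs.Raster(values=np.asarray(values), channel_names=names, **kw)
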