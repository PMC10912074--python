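"""Shared fixtures: default input function, schedule, and phantoms.

Session-scoped because the default phantom build and the model context are
the expensive pieces shared by many tests.
"""

import numpy as np
import pytest

from fespet import (
    ModelContext,
    build_phantom,
    default_phantom_spec,
    default_schedule,
    make_input_function,
)


@pytest.fixture(scope="session")
def inp():
    return make_input_function()


@pytest.fixture(scope="session")
def sch():
    return default_schedule()


@pytest.fixture(scope="session")
def ctx(inp, sch):
    return ModelContext(inp, sch)


@pytest.fixture(scope="session")
def noiseless_phantom(inp, sch, ctx):
    """Default phantom, noise and PSF off: exact construction checks."""
    spec = default_phantom_spec(inp, sch, noise_coefficient=0.0, psf_fwhm_mm=0.0)
    img, masks = build_phantom(spec, inp, sch, context=ctx)
    return spec, img, masks


@pytest.fixture(scope="session")
def noisy_phantom(inp, sch, ctx):
    """Default phantom under the default noise and PSF (the study conditions)."""
    spec = default_phantom_spec(inp, sch)
    img, masks = build_phantom(spec, inp, sch, context=ctx)
    return spec, img, masks
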