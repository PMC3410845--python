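import pytest
from hypothesis import settings

from epiactin.simulate import MovieSpec, builtin_presets, generate_movie

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def wt_preset():
    return builtin_presets()["wild_type"]


@pytest.fixture(scope="session")
def wt_noiseless(wt_preset):
    """One noiseless wild-type movie with ground truth and ROIs."""
    spec = MovieSpec(preset=wt_preset, noise_sigma=0.0, seed=11)
    return generate_movie(spec)


@pytest.fixture(scope="session")
def leading_roi(wt_noiseless):
    _, _, rois = wt_noiseless
    return next(r for r in rois if r.role == "leading-cell")
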