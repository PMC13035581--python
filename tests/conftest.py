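import numpy as np
import pytest

import closurebench as cb


@pytest.fixture(scope="session")
def segments_grid():
    return cb.enumerate_exp1_params("segments")


@pytest.fixture(scope="session")
def kanizsa_grid():
    return cb.enumerate_exp1_params("kanizsa")


@pytest.fixture(scope="session")
def rendered_segments(segments_grid):
    """All 992 triangle-segment stimuli, rendered once per session."""
    return [cb.render_exp1_stimulus(p) for p in segments_grid]


@pytest.fixture(scope="session")
def rendered_kanizsa(kanizsa_grid):
    return [cb.render_exp1_stimulus(p) for p in kanizsa_grid]


@pytest.fixture(scope="session")
def line_sets():
    """All 288 line-segment pair sets."""
    return [cb.render_pair_set(p) for p in cb.enumerate_exp2_sets("line_segments")]


@pytest.fixture(scope="session")
def kanizsa_sets():
    return [cb.render_pair_set(p) for p in cb.enumerate_exp2_sets("kanizsa_squares")]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
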