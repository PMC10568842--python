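"""Shared fixtures.

The expensive fixture is ``study_bundle``: one full desk-scale study
(16 training eyes, 20 SGD epochs, 50 held-out test eyes) trained and
evaluated once per session and shared by the acceptance tests and the
safety-property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pseudoavg.study import StudyConfig, run_study
from pseudoavg.synthdata import generate_phantom, render_single_frame
from pseudoavg.types import NoiseParams


@pytest.fixture(scope="session")
def study_bundle():
    """Full synthetic study under the default desk-scale conditions."""
    cfg = StudyConfig(seed=1)
    result = run_study(cfg)
    return cfg, result


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom((256, 256), "healthy", seed=1)


@pytest.fixture(scope="session")
def npdr_phantom():
    return generate_phantom((256, 256), "npdr", seed=2)


@pytest.fixture(scope="session")
def noisy_frame(healthy_phantom):
    return render_single_frame(healthy_phantom, NoiseParams(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
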