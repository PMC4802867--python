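"""Shared fixtures.

Heavy artifacts (filter bank, phantom feature stacks, the evaluation suite)
are session-scoped so the many tests that need them pay the cost once.
"""

import numpy as np
import pytest

from discgabor.gabor import GaborBankParams, apply_bank, build_bank
from discgabor.localize import localize_discs
from discgabor.phantom import PhantomSpec, generate
from discgabor.spine import detect_spine


@pytest.fixture(scope="session")
def default_params():
    return GaborBankParams()


@pytest.fixture(scope="session")
def default_bank(default_params):
    return build_bank(default_params)


@pytest.fixture(scope="session")
def phantom_truth():
    return generate(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_stack(phantom_truth, default_bank, default_params):
    return apply_bank(phantom_truth.image, default_bank, default_params)


@pytest.fixture(scope="session")
def phantom_curves(phantom_stack):
    _, curves = detect_spine(phantom_stack)
    return curves


@pytest.fixture(scope="session")
def phantom_detections(phantom_stack, phantom_curves):
    detections, feature = localize_discs(phantom_stack, phantom_curves)
    return detections, feature


@pytest.fixture(scope="session")
def suite_noise_free():
    """The 20-phantom noise-free evaluation suite with the box ablation."""
    from discgabor.pipeline import run_suite
    return run_suite(n_phantoms=20, seed=1, noise_sigma=0.0,
                     compare_box_region=True)


@pytest.fixture(scope="session")
def suite_noisy():
    """The same suite at 5% additive Gaussian noise."""
    from discgabor.pipeline import run_suite
    return run_suite(n_phantoms=20, seed=1, noise_sigma=0.05)
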