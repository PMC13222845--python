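"""Shared phantom fixtures.

Scene phantoms are session-scoped: they are deterministic functions of
(parameters, seed) and read-only in every test.
"""

import numpy as np
import pytest

import kernelpheno as kp


@pytest.fixture(scope="session")
def pure_scene():
    """Noiseless pure-zones scene: every kernel pixel is a pure endmember."""
    return kp.make_kernel_scene(layout=(2, 2), image_shape=(80, 80), bands=60,
                                abundance_pattern="pure_zones", seed=1)


@pytest.fixture(scope="session")
def gradient_scene():
    """Noiseless radial-gradient scene (glassy core -> mealy rim)."""
    return kp.make_kernel_scene(layout=(2, 2), image_shape=(80, 80), bands=60,
                                abundance_pattern="radial_gradient", seed=3)


@pytest.fixture(scope="session")
def noisy_scene():
    """30 dB SNR pure-zones scene at the camera's native band count."""
    return kp.make_kernel_scene(layout=(3, 3), image_shape=(120, 120), bands=200,
                                abundance_pattern="pure_zones", snr_db=30, seed=1)


@pytest.fixture(scope="session")
def darkflat_scene():
    """Noiseless scene on a dark flat (non-zero) platform spectrum."""
    return kp.make_kernel_scene(layout=(2, 2), image_shape=(80, 80), bands=40,
                                background="dark_flat", seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def match_endmembers(est: kp.EndmemberSet, true: kp.EndmemberSet) -> list[int]:
    """Index into est.spectra matching each true endmember by spectral angle."""
    return [int(np.argmin([kp.spectral_angle(e, t) for e in est.spectra]))
            for t in true.spectra]
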