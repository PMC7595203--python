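from __future__ import annotations

import numpy as np
import pytest

import lungdfi as L
from lungdfi.forward import SystemConfig, simulate_scan
from lungdfi.retrieval import retrieve


@pytest.fixture(scope="session")
def geometry():
    return L.GeometryParams()


@pytest.fixture(scope="session")
def noiseless_config():
    return SystemConfig(noise="none")


def _modalities(phantom, config, rng=None):
    reference = simulate_scan(None, config, shape=phantom.shape, rng=rng)
    sample = simulate_scan(phantom, config, rng=rng)
    return retrieve(sample, reference)


@pytest.fixture(scope="session")
def modalities_of():
    """Callable: phantom -> retrieved modalities (noiseless by default)."""
    def _run(phantom, config=None, rng=None):
        return _modalities(phantom, config or SystemConfig(noise="none"), rng)
    return _run


@pytest.fixture(scope="session")
def healthy_phantom(geometry):
    return L.build_thorax_phantom(geometry, L.PathologySpec(), seed=5)


@pytest.fixture(scope="session")
def healthy_modalities(healthy_phantom, modalities_of):
    return modalities_of(healthy_phantom)


@pytest.fixture(scope="session")
def stenosis_phantom(geometry):
    return L.build_thorax_phantom(
        geometry,
        L.PathologySpec(kind="stenosis", stenosis_fraction=0.4,
                        atelectasis_severity=0.5, distal_diameter_mm=1.5),
        seed=3,
    )


@pytest.fixture(scope="session")
def truncation_phantom(geometry):
    return L.build_thorax_phantom(
        geometry, L.PathologySpec(kind="truncation", atelectasis_severity=1.0), seed=4
    )


@pytest.fixture(scope="session")
def pneumothorax_phantom(geometry):
    return L.build_thorax_phantom(geometry, L.PathologySpec(kind="pneumothorax"), seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
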