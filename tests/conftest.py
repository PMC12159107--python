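import math

import numpy as np
import pytest

import nucsas as ns


def sphere_intensity(q, radius, i0=1.0):
    """Analytic homogeneous-sphere I(q) (form-factor oracle)."""
    x = np.asarray(q) * radius
    phi = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return i0 * phi**2


def sphere_pr_mc(radius, n_pairs=200_000, bins=100, seed=7):
    """Monte-Carlo pair-distance distribution of a uniform sphere."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(2, n_pairs, 3))
    u /= np.linalg.norm(u, axis=2, keepdims=True)
    rad = radius * rng.random((2, n_pairs, 1)) ** (1.0 / 3.0)
    d = np.linalg.norm(u[0] * rad[0] - u[1] * rad[1], axis=1)
    hist, edges = np.histogram(d, bins=bins, range=(0, 2 * radius), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist


@pytest.fixture(scope="session")
def sphere_profile():
    """Noise-free sphere curve (R = 54 A) with 1% counting-style sigmas."""
    R = 54.0
    q = np.geomspace(0.009, 0.30, 150)
    i = sphere_intensity(q, R, i0=541.0)
    sigma = 0.01 * np.sqrt(i * i[0])
    return ns.ScatteringProfile(q, i, sigma, {"source": "xray", "label": "sphere"}), R


@pytest.fixture(scope="session")
def noisy_sphere_profile():
    R = 54.0
    q = np.geomspace(0.009, 0.30, 150)
    i = sphere_intensity(q, R, i0=541.0)
    sigma = 0.02 * np.sqrt(i * i[0])
    rng = np.random.default_rng(21)
    return ns.ScatteringProfile(q, i + rng.normal(size=q.size) * sigma, sigma), R


@pytest.fixture(scope="session")
def octamer_comp():
    return ns.nucleosome_composition()


@pytest.fixture(scope="session")
def contrast_series_data():
    """Default 5-fraction synthetic neutron series, 3% noise (seeded)."""
    return ns.simulate_contrast_series(seed=3)


@pytest.fixture(scope="session")
def pressure_series_data():
    """Default pressure ramp + return with 10% residual extended fraction."""
    return ns.simulate_pressure_series(seed=11)
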