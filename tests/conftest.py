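"""Shared fixtures: analytic reference curves and desk-scale pools.

Everything is generated programmatically at test time; the expensive
desk-scale pool (200 conformers for each of the five oligomer states) is
built once per session and shared by the ensemble-fit and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import oligosas as og


SPHERE_R = 30.0  # A; reference homogeneous sphere


def sphere_form_factor(q: np.ndarray, radius: float = SPHERE_R) -> np.ndarray:
    """Closed-form intensity of a homogeneous sphere, normalized to I(0)=1:
    [3 (sin x - x cos x) / x^3]^2 with x = q R."""
    x = np.asarray(q) * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2


def uniform_sphere_beads(n: int, radius: float = SPHERE_R, seed: int = 0) -> np.ndarray:
    """n points uniform in a ball of the given radius."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return radius * rng.random(n)[:, None] ** (1.0 / 3.0) * v


@pytest.fixture(scope="session")
def q_grid():
    return og.default_q_grid()


@pytest.fixture(scope="session")
def sphere_profile(q_grid):
    """Noise-free sphere intensity with a small nominal sigma (0.5%)."""
    i = 100.0 * sphere_form_factor(q_grid)
    sigma = 0.005 * np.abs(i) + 1e-6 * 100.0
    return og.ScatteringProfile(q=q_grid, intensity=i, sigma=sigma, label="sphere30")


@pytest.fixture(scope="session")
def arch():
    return og.DomainArchitecture()


@pytest.fixture(scope="session")
def mini_pool(arch):
    """Small two-state pool for fast unit tests."""
    q = og.default_q_grid(n=60)
    return og.generate_pool(arch, [1, 2], 25, q, seed=13)


@pytest.fixture(scope="session")
def desk_pool(arch, q_grid):
    """Desk-scale pool: 200 conformers per state, states 1..5."""
    return og.generate_pool(arch, [1, 2, 3, 4, 5], 200, q_grid, seed=7)


@pytest.fixture(scope="session")
def preset_fits(desk_pool):
    """Full flexible-oligomer fits of the three reference synthetic
    conditions, computed once and reused across tests."""
    out = {}
    for name in ("apo-like", "monomer-only", "ampnp-like"):
        truth = og.preset(name, seed=3)
        profile, provenance = og.make_mixture_profile(desk_pool, truth)
        report = og.fit_report(profile, desk_pool, og.GAConfig(seed=0, n_runs=3))
        out[name] = {"truth": truth, "profile": profile,
                     "provenance": provenance, "report": report}
    return out
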