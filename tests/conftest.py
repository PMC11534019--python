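"""Shared fixtures: analytic and voxelized phantoms, and the cohort run.

Expensive pipeline runs are session-scoped so several tests can share them.
"""

import numpy as np
import pytest

import scleratopo as st


@pytest.fixture(scope="session")
def sphere_pc():
    """Analytic 24 mm-axial-length eye: exact sphere, radius 12 mm, 20k points."""
    pc, truth = st.make_surface(st.PhantomSpec(semi_axes=(12.0, 12.0, 12.0)), n_points=20000)
    return pc, truth


@pytest.fixture(scope="session")
def sphere_surface_result(sphere_pc):
    pc, _truth = sphere_pc
    return st.analyze_surface(pc, anterior_hint=(0, -1, 0))


@pytest.fixture(scope="session")
def sphere_volume():
    return st.make_volume(st.PhantomSpec(semi_axes=(12.0, 12.0, 12.0)))


@pytest.fixture(scope="session")
def sphere_volume_result(sphere_volume):
    return st.analyze_volume(sphere_volume, anterior_hint=(0, -1, 0))


@pytest.fixture(scope="session")
def prolate_volume():
    return st.make_volume(st.PhantomSpec(semi_axes=(11.0, 14.0, 11.0)))


@pytest.fixture(scope="session")
def cohort_run():
    """Seeded 30-phantom cohort (10 per type) pushed through the full volume
    pipeline; returns (cohort, results) aligned lists."""
    cohort = st.make_cohort(n_per_type=10, seed=42)
    results = [
        st.analyze_volume(eye.volume, anterior_hint=tuple(eye.truth.anterior_hint_world))
        for eye in cohort
    ]
    return cohort, results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
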