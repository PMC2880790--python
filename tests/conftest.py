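"""Shared fixtures: small deterministic bead models of known geometry."""

import numpy as np
import pytest

from pdccore.assembly import (ArmSpec, AssemblySpec, BeadModel,
                              add_flexible_arms, build_core_model,
                              _fibonacci_sphere)


def make_ball_model(R: float = 50.0, n: int = 1000, bead_radius: float = 2.0,
                    seed: int = 0) -> BeadModel:
    """Uniformly filled solid sphere of small beads (seeded sampling)."""
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    frac = rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    return BeadModel(dirs * frac[:, None] * R, bead_radius, label="ball")


def make_shell_model(R: float = 50.0, n: int = 60,
                     bead_radius: float = 5.0) -> BeadModel:
    """Hollow spherical shell of beads."""
    return BeadModel(_fibonacci_sphere(n) * R, bead_radius, label="shell")


@pytest.fixture(scope="session")
def ball_model() -> BeadModel:
    return make_ball_model()


@pytest.fixture(scope="session")
def shell_model() -> BeadModel:
    return make_shell_model()


@pytest.fixture(scope="session")
def core_model() -> BeadModel:
    return build_core_model(AssemblySpec(seed=1))


@pytest.fixture(scope="session")
def armed_model(core_model) -> BeadModel:
    return add_flexible_arms(core_model, ArmSpec(), seed=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
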