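"""Shared fixtures: small graphs, schedules and geometry helpers."""

import numpy as np
import pytest

from tsdiff.diffusion import make_schedule
from tsdiff.fixtures import TEMPLATES


@pytest.fixture(scope="session")
def templates_by_id():
    return {t.template_id: t for t in TEMPLATES}


@pytest.fixture(scope="session")
def methanol_co(templates_by_id):
    """Smallest template (6 atoms): graph plus canonical geometry."""
    t = templates_by_id["methanol_co_cleavage"]
    return t.graph(), t.geometry(0)


@pytest.fixture(scope="session")
def ethane(templates_by_id):
    t = templates_by_id["ethane_homolysis"]
    return t.graph(), t.geometry(0)


@pytest.fixture(scope="session")
def short_schedule():
    return make_schedule(50, beta_start=1e-4, beta_end=5e-2)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
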