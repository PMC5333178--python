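"""Shared fixtures: generated scenarios and their attribute tables.

Everything is generated programmatically; the default scenario (seed 42,
2,000 steps, phases 500/300/400/500/300) is shared session-wide because
the attribute table over it is the most expensive object in the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from ligandpath import synthetic
from ligandpath.attributes import compute_attribute_table
from ligandpath.synthetic import ScenarioSpec

#: ground-truth phase label -> expected positional category
PHASE_TO_CATEGORY = {
    "outside": "outside",
    "surface": "surface",
    "transit": "inside",
    "stuck": "inside",
    "active-site": "active-site",
}


@pytest.fixture(scope="session")
def default_scenario():
    """Default labeled scenario (in memory)."""
    frames, traj, site, truth = synthetic.generate()
    return {"frames": frames, "traj": traj, "site": site, "truth": truth}


@pytest.fixture(scope="session")
def default_table(default_scenario):
    """Attribute table over the default scenario."""
    return compute_attribute_table(
        default_scenario["frames"],
        default_scenario["traj"],
        default_scenario["site"],
    )


@pytest.fixture(scope="session")
def small_scenario_spec():
    return ScenarioSpec(
        seed=7,
        n_steps=120,
        phases=(("outside", 30), ("surface", 30), ("transit", 30), ("stuck", 30)),
    )


@pytest.fixture(scope="session")
def small_scenario(small_scenario_spec):
    frames, traj, site, truth = synthetic.generate(small_scenario_spec)
    return {"frames": frames, "traj": traj, "site": site, "truth": truth}


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory, small_scenario_spec):
    """The small scenario written to disk (PDB/PQR/YAML/JSON bundle)."""
    outdir = tmp_path_factory.mktemp("bundle")
    synthetic.generate(small_scenario_spec, outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def small_table(small_scenario):
    return compute_attribute_table(
        small_scenario["frames"], small_scenario["traj"], small_scenario["site"]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
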