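"""Shared fixtures: synthetic complexes with planted ground truth.

Session-scoped because layout generation is deterministic and the tests
only read from the returned objects (tests that mutate coordinates make
their own copies or regenerate).
"""
import numpy as np
import pytest

from glycomd.conformation import ChiCurve, ChiCurveRegistry, assign_glycosidic_linkages
from glycomd.synthetic import (
    BridgeSpec,
    HBondPlant,
    ToyComplexSpec,
    gen_toy_runs,
)


@pytest.fixture(scope="session")
def stable_bundle():
    """Three stable-mode runs with a planted H-bond (always on) and a
    planted Ca2+ - water - sulfate bridge at (2.0, 3.0) A."""
    spec = ToyComplexSpec(
        mode="stable",
        n_frames=100,
        seed=11,
        bridge=BridgeSpec(ca_water_dist=2.0, water_so3_dist=3.0),
        hbond_plants=[HBondPlant(acceptor=(2, "O4"), distance=2.8, fraction=1.0)],
    )
    trajs, params, extras = gen_toy_runs(spec, 3)
    return trajs, params, extras


@pytest.fixture(scope="session")
def multipose_bundle():
    """Three multi-pose runs with dwell fractions (0.5, 0.3, 0.2)."""
    spec = ToyComplexSpec(mode="multi-pose", n_frames=100, seed=5)
    return gen_toy_runs(spec, 3)


@pytest.fixture(scope="session")
def diffusing_bundle():
    spec = ToyComplexSpec(mode="diffusing", n_frames=80, seed=7)
    return gen_toy_runs(spec, 3)


@pytest.fixture(scope="session")
def chi_registry(stable_bundle):
    """Cosine-well strain curves (minimum at +60 deg) for every linkage of
    the toy ligand."""
    trajs, _, _ = stable_bundle
    linkages = assign_glycosidic_linkages(trajs[0].topology)
    grid = np.linspace(-180.0, 180.0, 25)
    energies = 2.0 * (1.0 - np.cos(np.radians(grid - 60.0)))
    reg = ChiCurveRegistry()
    for link in linkages:
        for torsion in ("phi", "psi"):
            reg.add(link.label, torsion, ChiCurve(grid, energies))
    return reg
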