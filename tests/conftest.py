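"""Shared fixtures: small geometric toys plus one cached full pipeline run.

The dense fixtures are expensive to probe, so detection runs and the
trained forests are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import sespocket as sp
from sespocket.pipeline import RunConfig, detect_pockets, train_models
from sespocket.structures import Atom, Structure


def toy_structure(coords, radius=1.0, radii=None) -> Structure:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    radii = [radius] * len(coords) if radii is None else radii
    atoms = [
        Atom(index=i, element="C", residue_name="ALA", residue_id=("A", i + 1),
             center=c, radius=float(r), is_heavy=True)
        for i, (c, r) in enumerate(zip(coords, radii))
    ]
    return Structure(atoms=atoms, name="toy")


@pytest.fixture
def equilateral():
    """Three unit-radius atoms on an equilateral triangle of side 2 (z = 0)."""
    return toy_structure([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]])


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(n_trees=200, seed=7)


@pytest.fixture(scope="session")
def shell_fixture():
    return sp.make_structure(sp.FixtureSpec(kind="shell_with_mouth", seed=3))


@pytest.fixture(scope="session")
def shell_run(shell_fixture, run_config):
    return detect_pockets(shell_fixture.structure, run_config)


@pytest.fixture(scope="session")
def channel_fixture():
    return sp.make_structure(sp.FixtureSpec(kind="channel", seed=11))


@pytest.fixture(scope="session")
def channel_run(channel_fixture, run_config):
    return detect_pockets(channel_fixture.structure, run_config)


@pytest.fixture(scope="session")
def slab_fixture():
    return sp.make_structure(sp.FixtureSpec(kind="dimpled_slab", seed=11))


@pytest.fixture(scope="session")
def slab_run(slab_fixture, run_config):
    return detect_pockets(slab_fixture.structure, run_config)


@pytest.fixture(scope="session")
def trained_models(shell_fixture, channel_fixture, slab_fixture,
                   shell_run, channel_run, slab_run, run_config):
    """The four forests trained on the three cavity-bearing fixtures."""
    dataset = [(f.structure, [f.ligand])
               for f in (shell_fixture, channel_fixture, slab_fixture)]
    models, manifest = train_models(dataset, run_config,
                                    runs=[shell_run, channel_run, slab_run])
    return models, manifest
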