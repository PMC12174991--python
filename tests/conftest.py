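"""Shared fixtures.

The expensive reduced-scale pre-training run (200 fixtures, 50 epochs) is
session-scoped so the end-to-end criteria, fine-tuning comparison and
attribution checks all reuse one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from xtalformer.fixtures import FixtureSpec, make_crystal


@pytest.fixture(scope="session")
def toy_run():
    from xtalformer.toy import run_toy_pretraining
    return run_toy_pretraining(seed=1, epochs=50)


@pytest.fixture()
def p21_crystal():
    """Two-molecule P2₁ fixture (N₂ template)."""
    s, record = make_crystal(FixtureSpec(space_group=4, molecule_template="N2",
                                         seed=11))
    return s, record


@pytest.fixture()
def two_molecule_ids():
    """Molecule labels for a 2×10-atom cell."""
    return np.repeat([0, 1], 10)
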