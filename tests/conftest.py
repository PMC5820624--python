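"""Shared fixtures.

The expensive objects (the idealized pelvic model, its healthy solution
and the impairment sweeps) are session-scoped so that unit tests and the
acceptance tests measure the same computation once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pelvifem.fem import SolverSettings
from pelvifem.materials import load_fascia_constituents, load_pelvic_structures
from pelvifem.pelvic import (
    PelvicConfig,
    build_idealized_pelvis,
    impairment_sweep,
    solve_healthy,
)

#: impairment levels exercised by the default sweeps in the suite
SWEEP_LEVELS = [0.0, 0.25, 0.5, 0.7, 0.8, 0.9, 0.95]


@pytest.fixture(scope="session")
def constituent_params():
    return load_fascia_constituents()


@pytest.fixture(scope="session")
def structure_params():
    return load_pelvic_structures()


@pytest.fixture(scope="session")
def all_material_params(constituent_params, structure_params):
    """Every bundled single-tissue parameter set, keyed by name."""
    merged = dict(constituent_params)
    for name, params in structure_params.items():
        merged.setdefault(name, params)
    return merged


@pytest.fixture(scope="session")
def pelvic_model():
    return build_idealized_pelvis(PelvicConfig())


@pytest.fixture(scope="session")
def healthy_solution(pelvic_model):
    return solve_healthy(pelvic_model)


@pytest.fixture(scope="session")
def default_sweeps(pelvic_model):
    """Impairment sweeps of the three canonical target sets."""
    return {
        target: impairment_sweep(pelvic_model, target, SWEEP_LEVELS)
        for target in ("fasciae", "ligaments", "all")
    }
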