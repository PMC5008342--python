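"""Shared fixtures: a small synthetic study reused across module tests."""

from __future__ import annotations

import pytest

from secretomics.design import StudyDesign
from secretomics import synthetic


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign(n_replicates=3, n_fractions=12, seed=7)


@pytest.fixture(scope="session")
def glyco_design() -> StudyDesign:
    return StudyDesign(n_replicates=2, n_fractions=1, seed=7)


@pytest.fixture(scope="session")
def small_study(design):
    """40-protein proteome with planted truth plus a simulated PSM table."""
    proteome, truth = synthetic.generate_proteome(40, seed=7)
    psms = synthetic.simulate_psm_tables(
        proteome, truth, design, depth=2.0, decoy_fraction=0.1, seed=8
    )
    return proteome, truth, psms
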