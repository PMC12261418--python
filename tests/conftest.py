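"""Shared fixtures: hand-built catalogs and the session-scoped benchmark runs."""

import numpy as np
import pytest

from exocnv.io import ExonCatalog, ExonDef


@pytest.fixture
def tiny_catalog() -> ExonCatalog:
    """Six exons, two genes on chr1 and one gene on chr2."""
    return ExonCatalog([
        ExonDef("gA.e1", "gA", 1, 100, 300),
        ExonDef("gA.e2", "gA", 1, 1_000, 1_400),
        ExonDef("gA.e3", "gA", 1, 2_000, 2_600),
        ExonDef("gB.e1", "gB", 1, 10_000, 10_500),
        ExonDef("gB.e2", "gB", 1, 12_000, 12_300),
        ExonDef("gC.e1", "gC", 2, 500, 900),
    ])


@pytest.fixture(scope="session")
def recovery_results() -> dict:
    """Pretrain/fine-tune parameter-recovery benchmark over three seeds."""
    from exocnv.benchmark import synthetic_recovery

    return {seed: synthetic_recovery(seed) for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def population_results() -> dict:
    """Population-structure and frequency-spectrum benchmark over three seeds."""
    from exocnv.benchmark import population_recovery

    return {seed: population_recovery(seed) for seed in (0, 1, 2)}
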