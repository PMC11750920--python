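"""Shared fixtures: models and cached full-length washout runs.

Full 200-s simulations take a few seconds each; scenarios used by several
tests are computed once per session and memoised by (area, f_c).
"""

from __future__ import annotations

import numpy as np
import pytest

import mbwsim as m


@pytest.fixture(scope="session")
def raw_table():
    return m.weibel_table()


@pytest.fixture(scope="session")
def scaling(raw_table):
    result, scaled = m.scale_to_volume(raw_table)
    return result, scaled


@pytest.fixture(scope="session")
def sym_model():
    return m.default_model()


@pytest.fixture(scope="session")
def run_cache():
    """Memoised washout runs keyed by (area, f_c, duration)."""
    cache: dict = {}

    def run(area: int | None = None, f_c: float = 1.0, duration: float = 200.0):
        key = (area, f_c, duration)
        if key not in cache:
            spec = m.AsymmetrySpec(area, f_c) if area is not None else None
            model = m.default_model(asymmetry=spec)
            result = m.simulate(m.assemble(model), duration=duration)
            partition = m.partition_lung_units(model, area) if area else None
            metrics = m.breath_metrics(result, partition)
            cache[key] = (model, result, partition, metrics)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def sym_run(run_cache):
    """Full-length symmetric reference washout."""
    return run_cache(None)
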