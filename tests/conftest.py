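"""Shared fixtures: cached pipeline runs so expensive simulations are reused."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from corticalpitch.experiments import Pipeline as _Pipeline


@functools.lru_cache(maxsize=None)
def _pipeline() -> _Pipeline:
    return _Pipeline()


@functools.lru_cache(maxsize=32)
def _irn_run(period_ms: float, seed: int, iterations: int = 16):
    return _pipeline().run_irn(period_ms * 1e-3, iterations=iterations, seed=seed)


@functools.lru_cache(maxsize=32)
def _dyad_run(interval: str, seed: int):
    return _pipeline().run_dyad(interval, seed=seed)


@pytest.fixture(scope="session")
def pipeline():
    """Shared pipeline (lag grid, channel bank, connectivity cached)."""
    return _pipeline()


@pytest.fixture(scope="session")
def irn_run():
    """Factory for cached single-IRN simulations (period in ms)."""
    return _irn_run


@pytest.fixture(scope="session")
def dyad_run():
    """Factory for cached dyad simulations."""
    return _dyad_run


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
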