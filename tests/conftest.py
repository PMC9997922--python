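"""Shared fixtures: landscapes and small simulation runs built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hexevo import engine
from hexevo.hexgrid import (
    BarrierMode,
    EpochName,
    EpochSpec,
    HabitatType,
    build_landscape,
)

#: a scaled-down six-patch layout with the same adjacency plan as the default
#: scenario (two large patches adjoining at the centre, medium/small patches
#: abutting the large ones only): 96/96/24/24/9/9 cells.
SMALL_LAYOUT = (
    (1, 0, 0, 8, 12),
    (2, 8, 0, 8, 12),
    (3, -4, 2, 4, 6),
    (4, 16, 2, 4, 6),
    (5, -3, 9, 3, 3),
    (6, 16, 9, 3, 3),
)


@pytest.fixture(scope="session")
def default_landscape():
    return build_landscape()


@pytest.fixture(scope="session")
def small_landscape():
    return build_landscape(layout=SMALL_LAYOUT)


def small_config(epochs, **kwargs) -> engine.SimConfig:
    kwargs.setdefault("snapshot_steps", ())
    return engine.SimConfig(layout=SMALL_LAYOUT, epochs=epochs, **kwargs)


@pytest.fixture(scope="session")
def small_isolated_log():
    """40 isolated steps on the scaled landscape (closed patches, drift only)."""
    epochs = [EpochSpec(EpochName.ISOLATED, 1, 40, BarrierMode.ABSOLUTE)]
    return engine.run_replicate(small_config(epochs, horizon=40), seed=7)


@pytest.fixture(scope="session")
def small_continuous_log():
    """60 continuous steps on the scaled landscape."""
    epochs = [EpochSpec(EpochName.CONTINUOUS, 1, 60, BarrierMode.NONE)]
    return engine.run_replicate(small_config(epochs, horizon=60), seed=3)
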