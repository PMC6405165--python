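"""Shared fixtures: toy codon tables and a small simulated dual-channel plate."""

from __future__ import annotations

import numpy as np
import pytest

from fishscreen import (
    ConditionModel,
    CodonUsageTable,
    PlateLayout,
    SimulationConfig,
    randomize_layout,
    simulate_plate,
)
from fishscreen.codon import ALL_CODONS

GLYCINE_COUNTS = {"GGC": 30.0, "GGA": 10.0, "GGG": 5.0, "GGT": 5.0}


def make_usage_table(overrides: dict[str, float] | None = None,
                     default: float = 1.0,
                     species: str = "toy") -> CodonUsageTable:
    """A full 64-codon table, uniform except for the given overrides."""
    entries = {c: default for c in ALL_CODONS}
    if overrides:
        entries.update(overrides)
    return CodonUsageTable(species=species, entries=entries)


@pytest.fixture(scope="session")
def glycine_table() -> CodonUsageTable:
    return make_usage_table(GLYCINE_COUNTS)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_plate() -> tuple[SimulationConfig, PlateLayout, dict, tuple]:
    """A small fluorescence plate: 2 conditions x 4 wells, 2 z, 5 timepoints.

    Condition 'dim' has true brightness ratio 0.5, 'bright' has 2.0;
    one extra 'dead-prone' condition is simulated separately in tests.
    """
    plate_layout = randomize_layout({"dim": 4, "bright": 4}, seed=11)
    config = SimulationConfig(
        image_size=64, t_start=2.0, t_end=10.0, t_step=120.0, z_slices=2,
        channels=("GFP", "mCherry"), background_level=20.0,
        noise_sd=2.0, noise_fraction=0.05, embryo_radius=14,
        injection_volume_cv=0.4, dead_well_fraction=0.0, seed=7,
    )
    models = {
        "dim": ConditionModel(name="dim", brightness={"GFP": 3000.0, "mCherry": 6000.0}),
        "bright": ConditionModel(name="bright", brightness={"GFP": 12000.0, "mCherry": 6000.0}),
    }
    series, truth = simulate_plate(config, plate_layout, models,
                                   reference_channel="mCherry")
    return config, plate_layout, models, (series, truth)
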