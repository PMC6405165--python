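"""Canned study protocols: standard simulated assay set-ups.

These bundle the simulator settings for the three screening designs the
package analyses, so an end-to-end run is one function call away:

* :func:`fluorophore_panel` — the ratiometric fluorescent-protein screen:
  a 96-well plate with 8 conditions x 8 wells whose programmed
  green/reference brightness ratios span 0.25-4x, log-normal injection
  volumes (CV 30%) and signal-proportional noise (5%);
* :func:`anaesthesia_panel` — the brightfield movement assay with
  conditions of increasing embryo displacement per frame;
* :func:`viability_panel` — a screen with a 20% dead-well rate and clear
  signal margins, for validating the negative-well QC.

Problem sizes (64 px images, 3 z-slices, 21 timepoints at 30 min) are
deliberately compact: they preserve the assays' signal-to-noise structure
while keeping a full plate simulation in the seconds range.
"""

from __future__ import annotations

from .layout import PlateLayout, randomize_layout
from .simulate import ConditionModel, SimulationConfig

#: Programmed test/reference brightness ratios of the fluorophore panel,
#: spanning 0.25-4x the reference condition (labels follow the commonly
#: screened green/yellow fluorescent proteins).
PANEL_RATIOS: dict[str, float] = {
    "CFP": 0.25,
    "YFP": 0.4,
    "Clover": 0.7,
    "eGFP": 1.0,
    "Venus": 1.4,
    "eGFPvar": 2.0,
    "mGFPmut2": 2.8,
    "mVenusNB": 4.0,
}

#: Reference-channel amplitude in counts.
REFERENCE_BRIGHTNESS = 6000.0


def fluorophore_panel(
    seed: int = 0,
    wells_per_condition: int = 8,
) -> tuple[SimulationConfig, PlateLayout, dict[str, ConditionModel]]:
    """The ratiometric fluorescent-protein screen on one 96-well plate."""
    plate_layout = randomize_layout(
        {name: wells_per_condition for name in PANEL_RATIOS}, seed=seed)
    config = SimulationConfig(
        image_size=64,
        t_start=2.0,
        t_end=12.0,
        t_step=30.0,
        z_slices=3,
        channels=("GFP", "mCherry"),
        background_level=20.0,
        noise_sd=2.0,
        noise_fraction=0.05,
        embryo_radius=14,
        injection_volume_cv=0.3,
        dead_well_fraction=0.0,
        seed=seed,
    )
    models = {
        name: ConditionModel(
            name=name,
            brightness={"GFP": ratio * REFERENCE_BRIGHTNESS,
                        "mCherry": REFERENCE_BRIGHTNESS},
            maturation_time=3.0,
            decay_time=30.0,
        )
        for name, ratio in PANEL_RATIOS.items()
    }
    return config, plate_layout, models


def anaesthesia_panel(
    seed: int = 0,
    amplitudes: dict[str, float] | None = None,
    wells_per_condition: int = 4,
    noise_sd: float = 50.0,
) -> tuple[SimulationConfig, PlateLayout, dict[str, ConditionModel]]:
    """The brightfield movement assay with graded displacement amplitudes."""
    if amplitudes is None:
        amplitudes = {"bungarotoxin": 0.0, "tricaine": 1.0,
                      "etomidate": 2.0, "control": 4.0}
    plate_layout = randomize_layout(
        {name: wells_per_condition for name in amplitudes}, seed=seed)
    config = SimulationConfig(
        image_size=64,
        t_start=0.0,
        t_end=5.0,
        t_step=20.0,
        z_slices=1,
        channels=("BF",),
        brightfield_channels=("BF",),
        noise_sd=noise_sd,
        embryo_radius=14,
        injection_volume_cv=0.0,
        seed=seed,
    )
    models = {name: ConditionModel(name=name, brightness={}, movement_amplitude=a)
              for name, a in amplitudes.items()}
    return config, plate_layout, models


def viability_panel(
    seed: int = 0,
    dead_well_fraction: float = 0.2,
    n_wells: int = 48,
) -> tuple[SimulationConfig, PlateLayout, dict[str, ConditionModel]]:
    """A screen with dead wells and clear signal margins for QC validation
    (read noise well below background, signal well above it)."""
    plate_layout = randomize_layout({"eGFP": n_wells}, seed=seed)
    config = SimulationConfig(
        image_size=64,
        t_start=2.0,
        t_end=10.0,
        t_step=60.0,
        z_slices=2,
        channels=("GFP", "mCherry"),
        background_level=100.0,
        noise_sd=10.0,
        embryo_radius=14,
        injection_volume_cv=0.3,
        dead_well_fraction=dead_well_fraction,
        seed=seed,
    )
    models = {"eGFP": ConditionModel(
        name="eGFP", brightness={"GFP": 4000.0, "mCherry": 4000.0})}
    return config, plate_layout, models
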