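from __future__ import annotations

import numpy as np
import pytest

from wingbeat import (
    Event,
    SensorConfig,
    SpeciesProfile,
    default_species_library,
    simulate_event,
    simulate_labeled_dataset,
)
from wingbeat.evaluate import EventRepresentations

# The reference synthetic study conditions: nine species, 500 events per
# species, peak SNR 30 against unit noise.
DATASET_SEED = 42
N_PER_SPECIES = 500

# Scaled-down network used for experiment grids in the tests (the
# reference 2000/1500/1000 architecture is exercised structurally, not
# trained in full at grid scale).
GRID_NN_LAYERS = (200, 150, 100)
GRID_NN_EPOCHS = 15


@pytest.fixture(scope="session")
def sensor() -> SensorConfig:
    return SensorConfig()


@pytest.fixture(scope="session")
def library():
    return default_species_library()


def make_flyer(
    f0: float,
    f0_sd: float = 0.0,
    decay: float = 0.5,
    cv: float = 0.0,
    **kwargs,
) -> SpeciesProfile:
    """A deterministic test flyer: no individual spread unless asked."""
    return SpeciesProfile(
        name=kwargs.pop("name", f"flyer_{int(f0)}"),
        f0_mean=f0,
        f0_sd=f0_sd,
        harmonic_decay=decay,
        individual_cv=cv,
        **kwargs,
    )


def make_event(
    profile: SpeciesProfile,
    sensor: SensorConfig,
    duration: float = 0.1,
    seed: int = 0,
    amplitude: float = 1.0,
) -> Event:
    seg = simulate_event(profile, sensor, duration, seed, amplitude=amplitude)
    return Event(
        segment=seg, sample_rate=sensor.sample_rate, start=0, end=seg.shape[1]
    )


@pytest.fixture(scope="session")
def default_dataset(library, sensor):
    """The default nine-species labeled dataset (500 events/species)."""
    return simulate_labeled_dataset(
        library,
        n_per_species=N_PER_SPECIES,
        sensor=sensor,
        noise_sd=1.0,
        seed=DATASET_SEED,
        peak_snr=30.0,
    )


@pytest.fixture(scope="session")
def default_reps(default_dataset) -> EventRepresentations:
    """Classifier inputs of the default dataset, computed once."""
    return EventRepresentations.from_dataset(default_dataset)
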