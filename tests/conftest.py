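import numpy as np
import pytest

from ionopore.model import Frame, MembraneSlab, SyntheticConfig, Trajectory, get_species


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_slab():
    return MembraneSlab(4.0, 8.3)


@pytest.fixture
def nacl_config(small_slab):
    """A small non-interacting NaCl system under the standard 0.2 V/nm field."""
    return SyntheticConfig(
        box=(6.0, 6.0, 12.0),
        membrane=small_slab,
        species_counts={"NA": 40, "CL": 40},
        applied_field_Ez=0.2,
        temperature=310.0,
        timestep=1e-3,
        n_steps=200,
        frame_stride=20,
        seed=7,
    )


def make_frame(positions, species_names, box=(6.0, 6.0, 12.0), time=0.0):
    """Frame + species table from explicit positions and species names."""
    order: list[str] = []
    for name in species_names:
        if name not in order:
            order.append(name)
    idx = np.array([order.index(n) for n in species_names], dtype=np.intp)
    species = tuple(get_species(n) for n in order)
    return Frame(time, np.asarray(positions, float), idx, box), species


def single_frame_trajectory(frame, species, config=None):
    return Trajectory([frame], species, config)


@pytest.fixture
def frame_factory():
    return make_frame
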