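import numpy as np
import pytest

from ionopore.langevin import initialize_system, plant_transmembrane_chain
from ionopore.model import MembraneSlab, SyntheticConfig, Trajectory
from ionopore.pores import (
    electroporation_time,
    spanning_chain,
    water_contact_graph,
)

from conftest import make_frame

BOX = (6.0, 6.0, 12.0)
SLAB = MembraneSlab(4.0, 8.3)


def _column(z_lo, z_hi, spacing=0.4, x=3.0, y=3.0):
    zs = np.arange(z_lo, z_hi + spacing / 2, spacing)
    return np.column_stack([np.full(len(zs), x), np.full(len(zs), y), zs])


class TestContactGraph:
    def test_pair_within_cutoff_connected(self):
        frame, _ = make_frame([[1.0, 1.0, 1.0], [1.0, 1.0, 1.5]], ["W", "W"], box=BOX)
        ids, adj = water_contact_graph(frame, np.array([True, True]))
        assert adj[0, 1] and adj[1, 0]

    def test_periodic_contact_across_boundary(self):
        frame, _ = make_frame([[0.1, 1.0, 1.0], [5.9, 1.0, 1.0]], ["W", "W"], box=BOX)
        _, adj = water_contact_graph(frame, np.array([True, True]))
        assert adj[0, 1]

    def test_open_axis_breaks_wraparound_contact(self):
        frame, _ = make_frame([[1.0, 1.0, 0.1], [1.0, 1.0, 11.9]], ["W", "W"], box=BOX)
        _, adj = water_contact_graph(
            frame, np.array([True, True]), periodic=(True, True, False)
        )
        assert adj.nnz == 0

    def test_mask_restricts_nodes(self):
        frame, _ = make_frame(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.4], [1.0, 1.0, 1.8]], ["W"] * 3, box=BOX
        )
        ids, adj = water_contact_graph(frame, np.array([True, False, True]))
        assert list(ids) == [0, 2]
        assert adj.nnz == 0  # 0.8 nm apart without the middle bead


class TestSpanningChain:
    def test_planted_column_is_detected(self):
        pos = _column(SLAB.z_lower - 0.4, SLAB.z_upper + 0.4)
        frame, _ = make_frame(pos, ["W"] * len(pos), box=BOX)
        chain = spanning_chain(frame, np.ones(len(pos), bool), SLAB)
        assert chain is not None
        z = frame.positions[chain, 2]
        assert z.min() <= SLAB.z_lower and z.max() >= SLAB.z_upper

    def test_broken_column_is_not_detected(self):
        pos = _column(SLAB.z_lower - 0.4, SLAB.z_upper + 0.4)
        keep = np.abs(pos[:, 2] - SLAB.midplane) > 0.5  # remove the middle
        frame, _ = make_frame(pos[keep], ["W"] * int(keep.sum()), box=BOX)
        assert spanning_chain(frame, np.ones(int(keep.sum()), bool), SLAB) is None

    def test_bulk_water_never_spans_via_periodic_z(self):
        # Dense water filling only the solvent region percolates around the
        # box in z; the detector must not count that as a membrane pore.
        rng = np.random.default_rng(0)
        n = 1500
        z = rng.uniform(0, 12.0 - SLAB.thickness, n)
        z = np.where(z < SLAB.z_lower, z, z + SLAB.thickness)
        pos = np.column_stack([rng.uniform(0, 6.0, n), rng.uniform(0, 6.0, n), z])
        frame, _ = make_frame(pos, ["W"] * n, box=BOX)
        assert spanning_chain(frame, np.ones(n, bool), SLAB) is None

    def test_chain_is_deterministic(self):
        pos = np.vstack(
            [_column(SLAB.z_lower - 0.4, SLAB.z_upper + 0.4, x=2.0),
             _column(SLAB.z_lower - 0.4, SLAB.z_upper + 0.4, x=4.0)]
        )
        frame, _ = make_frame(pos, ["W"] * len(pos), box=BOX)
        mask = np.ones(len(pos), bool)
        assert spanning_chain(frame, mask, SLAB) == spanning_chain(frame, mask, SLAB)


class TestElectroporationTime:
    def _trajectory(self, chain_frames, n_frames=6, dt=0.2):
        frames = []
        species = None
        for i in range(n_frames):
            if i in chain_frames:
                pos = _column(SLAB.z_lower - 0.4, SLAB.z_upper + 0.4)
            else:
                pos = _column(0.4, SLAB.z_lower - 0.4)  # same count, below slab
            n_fill = 14 - len(pos)
            pos = np.vstack([pos, np.column_stack(
                [np.full(n_fill, 1.0), np.full(n_fill, 1.0),
                 np.linspace(0.3, 1.5, n_fill)])]) if n_fill > 0 else pos[:14]
            frame, species = make_frame(pos[:14], ["W"] * 14, box=BOX,
                                        time=i * dt)
            frames.append(frame)
        return Trajectory(frames, species)

    def test_first_persistent_run_reported(self):
        traj = self._trajectory(chain_frames={1, 3, 4})
        event = electroporation_time(traj, SLAB, persistence=2)
        assert not event.censored
        assert event.frame_index == 3  # frame 1 flicker ignored
        assert event.time == pytest.approx(0.6)
        assert event.chain_particle_ids

    def test_censored_when_no_pore(self):
        traj = self._trajectory(chain_frames=set())
        event = electroporation_time(traj, SLAB, persistence=2)
        assert event.censored
        assert event.time == pytest.approx(1.0)

    def test_persistence_one_counts_flicker(self):
        traj = self._trajectory(chain_frames={1})
        event = electroporation_time(traj, SLAB, persistence=1)
        assert event.frame_index == 1

    def test_intact_generator_trajectory_has_no_pore(self):
        # A realistic dense-water run with the slab intact must stay censored.
        config = SyntheticConfig(
            box=BOX,
            membrane=SLAB,
            species_counts={"W": 500, "NA": 10, "CL": 10},
            n_steps=20,
            frame_stride=5,
            seed=4,
        )
        from ionopore.langevin import run_simulation

        traj = run_simulation(config)
        assert electroporation_time(traj).censored

    def test_planted_chain_in_generator_frame_detected(self):
        config = SyntheticConfig(
            box=BOX,
            membrane=SLAB,
            species_counts={"W": 200, "NA": 5, "CL": 5},
            n_steps=0,
            seed=8,
        )
        frame = initialize_system(config)
        frame, species = plant_transmembrane_chain(
            frame, config.species_table, SLAB, 0.4
        )
        traj = Trajectory([frame], species)
        event = electroporation_time(traj, SLAB, persistence=1)
        assert not event.censored

    def test_invalid_persistence(self):
        traj = self._trajectory(chain_frames=set())
        with pytest.raises(ValueError):
            electroporation_time(traj, SLAB, persistence=0)
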