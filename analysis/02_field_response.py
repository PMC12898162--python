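"""Electrophoretic response under the 0.2 V/nm transmembrane field.

Measures free-ion drift velocities against the Einstein relation
D*q*E/(k_B T), then runs a membrane system and tabulates where each ion
species accumulates: cations drift along +z, wrap through the periodic
boundary and pile against the lower membrane face; anions collect at the
upper face. The time-averaged axial charge profile shows the resulting
charge separation across the slab.

Writes: results/02_drift.tsv, results/02_surface_accumulation.tsv,
        results/02_charge_profile.tsv, results/02_summary.json
"""
import json
from pathlib import Path

import pandas as pd

from ionopore.grids import GridSpec, axial_charge_profile, time_averaged_charge_density
from ionopore.io import write_profile_tsv
from ionopore.kinematics import surface_accumulation, unwrap
from ionopore.langevin import counts_from_concentration, run_simulation
from ionopore.model import MembraneSlab, SyntheticConfig, get_species
from ionopore.validation import einstein_drift_velocity

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

# Free drift: negligible slab so ions never meet the membrane.
free = SyntheticConfig(
    box=(10.0, 10.0, 40.0),
    membrane=MembraneSlab(0.005, 0.015),
    species_counts={"NA": 100, "CL": 100},
    applied_field_Ez=0.2,
    timestep=1e-3,
    n_steps=10_000,
    frame_stride=100,
    seed=2,
)
traj = run_simulation(free)
disp = unwrap(traj)
horizon = traj.times[-1]
rows = []
for name in ("NA", "CL"):
    sp = get_species(name)
    mask = traj.species_mask(name)
    rows.append(
        {
            "species": name,
            "measured_nm_per_ns": disp[-1, mask, 2].mean() / horizon,
            "einstein_nm_per_ns": einstein_drift_velocity(
                sp.diffusion_coefficient, sp.valence, 0.2, 310.0
            ),
            "n_ions": int(mask.sum()),
        }
    )
drift = pd.DataFrame(rows)
drift.to_csv(RESULTS / "02_drift.tsv", sep="\t", index=False)

# Membrane system: accumulation faces and the axial charge profile.
box = (6.4, 6.4, 12.6)
slab = MembraneSlab.centered(12.6)
config = SyntheticConfig(
    box=box,
    membrane=slab,
    species_counts=counts_from_concentration(0.15, "NaCl", box, slab),
    applied_field_Ez=0.2,
    timestep=2e-3,
    n_steps=3000,
    frame_stride=10,
    seed=3,
)
mem_traj = run_simulation(config)
acc = surface_accumulation(mem_traj, shell=1.0)
acc.to_csv(RESULTS / "02_surface_accumulation.tsv", sep="\t", index=False)

spec = GridSpec.from_box(box, 0.2)
window = range(len(mem_traj) // 4, len(mem_traj))
rho = time_averaged_charge_density(mem_traj, spec, "CIC", list(window))
write_profile_tsv(RESULTS / "02_charge_profile.tsv", axial_charge_profile(rho))

last = acc[acc.frame == acc.frame.max()].set_index(["species", "face"])["count"]
summary = {
    "drift": rows,
    "final_counts": {
        f"{sp}_{face}": int(last[sp, face])
        for sp in ("NA", "CL")
        for face in ("lower", "upper")
    },
}
(RESULTS / "02_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print(json.dumps(summary, indent=2))
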