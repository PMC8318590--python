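#!/usr/bin/env python
"""Build the discriminating-contact set and the CV time series.

Reads the reference pair written by 01, applies the +24 signal-peptide
numbering offset, keeps only atom pairs formed in one conformation and
broken in the other (salt bridges weighted 3), and evaluates CV1 (K-E
minus K-D distance difference) and the contact-map distances CV2/CV3
along the two-state trajectory.  Checks the recovered set against the
planted ground truth.
"""

import json
from pathlib import Path

import numpy as np

from ptmetad import (Trajectory, apply_numbering_offset,
                     build_discriminating_contacts, contact_map_distance,
                     cv1_distance_difference, read_pdb)
from ptmetad.io import write_colvar_file, write_contacts_file
from ptmetad.synthetic import ToyKinaseSpec, make_two_state_trajectory

OUT = Path("results/analysis")
SEED = 1


def main():
    active = read_pdb(OUT / "active.pdb", label="active")
    inactive = read_pdb(OUT / "inactive.pdb", label="inactive")
    act = apply_numbering_offset(active)
    ina = apply_numbering_offset(inactive)

    cms = build_discriminating_contacts(act, ina)
    write_contacts_file(cms, OUT / "contacts.txt")
    truth = json.loads((OUT / "ground_truth.json").read_text())
    n_salt = sum(1 for c in cms.contacts if c.weight == 3)
    status = "OK" if (len(cms.contacts) == truth["n_contacts"]
                      and n_salt == truth["n_salt_bridges"]) else "MISMATCH"
    print(f"contact set: {len(cms.contacts)} contacts ({n_salt} salt "
          f"bridges) vs planted {truth['n_contacts']} "
          f"({truth['n_salt_bridges']}) -> {status}")

    # regenerate the trajectory (deterministic) and evaluate all three CVs
    traj, _ = make_two_state_trajectory(
        (active, inactive), 60, [30], noise_sigma=0.02, seed=SEED + 1)
    rows = []
    for frame in traj.frames:
        f = apply_numbering_offset(frame)
        rows.append([cv1_distance_difference(f),
                     contact_map_distance(f, cms, "inactive"),
                     contact_map_distance(f, cms, "active")])
    rows = np.array(rows)
    cv_traj = Trajectory(times=traj.times, cvs=rows,
                         cv_names=["cv1", "cv2", "cv3"])
    write_colvar_file(cv_traj, OUT / "COLVAR_cvs")
    print(f"CV ranges over the trajectory: "
          f"cv1 [{rows[:, 0].min():+.2f}, {rows[:, 0].max():+.2f}] nm, "
          f"cv2 [{rows[:, 1].min():.3f}, {rows[:, 1].max():.3f}], "
          f"cv3 [{rows[:, 2].min():.3f}, {rows[:, 2].max():.3f}]")
    print("cv2 (distance to inactive) is high in active-state frames and "
          "drops to ~0 after the switch; cv3 mirrors it")


if __name__ == "__main__":
    main()
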