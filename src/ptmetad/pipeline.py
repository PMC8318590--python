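"""End-to-end toy pipeline: fixtures → contacts → CVs → WTE+PTmetaD →
FES → minima → MEP → clustering → report.

Every stage writes its artefacts under the configured output directory;
``provenance.json`` records the configuration hash and every seed used,
so re-running an identical configuration reproduces all deterministic
outputs bit-exactly.
"""

from __future__ import annotations

import json
import time as _time
from pathlib import Path

import numpy as np

from . import io as pio
from .clustering import central_structure, gromos_cluster, pairwise_rmsd_matrix
from .config import PipelineConfig
from .cvs import (build_discriminating_contacts, contact_map_distance,
                  cv1_distance_difference)
from .fes import convergence_report, find_minima, minimum_energy_path, sum_hills
from .grids import GridAxis, default_grid_axes
from .potentials import make_potential
from .sampler import (MetaDParams, ParallelTempering, ReplicaLadder,
                      WTEParams, wte_prestage)
from .structures import AtomSelector, apply_numbering_offset, read_pdb, write_pdb
from .synthetic import ToyKinaseSpec, make_toy_kinase_pair, make_two_state_trajectory

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]

    provenance = {
        "schema": config["schema"],
        "config_hash": config.hash(),
        "seed": seed,
        "derived_seeds": {"fixtures": seed, "trajectory": seed + 1,
                          "wte": seed + 2, "production": seed + 3},
        "stages": stages,
        "injected_defaults": config.injected_defaults,
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (outdir / "config.json").write_text(json.dumps(config.data, indent=2,
                                                   default=str))

    state: dict = {}
    report: dict = {"config_hash": config.hash(), "seed": seed}

    runners = {
        "fixtures": _stage_fixtures, "contacts": _stage_contacts,
        "cvs": _stage_cvs, "sampling": _stage_sampling, "fes": _stage_fes,
        "minima": _stage_minima, "mep": _stage_mep,
        "clustering": _stage_clustering, "report": _stage_report,
    }
    for stage in stages:
        try:
            runners[stage](config, outdir, state, report)
        except Exception as exc:  # partial outputs stay on disk
            raise StageError(stage, exc) from exc
    return outdir


def _get_structures(config, outdir, state):
    if "pair" in state:
        return state["pair"]
    paths = config["structures"]
    if paths["active"] and paths["inactive"]:
        pair = (read_pdb(paths["active"], label="active"),
                read_pdb(paths["inactive"], label="inactive"))
        state["pair"] = pair
        state["truth"] = None
        return pair
    raise RuntimeError("no structures: run the fixtures stage or "
                       "configure structure paths")


def _stage_fixtures(config, outdir, state, report):
    fx = config["fixtures"]
    spec = ToyKinaseSpec(n_residues=fx["n_residues"],
                         n_active_contacts=fx["n_active_contacts"],
                         n_inactive_contacts=fx["n_inactive_contacts"],
                         n_salt_bridges=fx["n_salt_bridges"],
                         seed=int(config["seed"]))
    active, inactive, truth = make_toy_kinase_pair(spec)
    write_pdb(active, outdir / "active.pdb")
    write_pdb(inactive, outdir / "inactive.pdb")
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    state["pair"] = (active, inactive)
    state["truth"] = truth

    tj = fx["trajectory"]
    traj, labels = make_two_state_trajectory(
        (active, inactive), tj["n_frames"], tj["switch_times"],
        tj["noise_sigma"], seed=int(config["seed"]) + 1)
    state["structure_traj"] = traj
    state["labels"] = labels
    report["fixtures"] = {"n_contacts_planted": truth["n_contacts"],
                          "n_frames": len(traj)}


def _stage_contacts(config, outdir, state, report):
    active, inactive = _get_structures(config, outdir, state)
    offset = config["structures"]["numbering_offset"]
    act = apply_numbering_offset(active, offset)
    ina = apply_numbering_offset(inactive, offset)
    cms = build_discriminating_contacts(
        act, ina, formed_cutoff=config["contacts"]["formed_cutoff"],
        broken_cutoff=config["contacts"]["broken_cutoff"],
        variant=config["cv"]["variant"])
    pio.write_contacts_file(cms, outdir / "contacts.txt")
    state["cms"] = cms
    state["offset_pair"] = (act, ina)
    n_salt = sum(1 for c in cms.contacts if c.weight == 3)
    report["contacts"] = {"n_contacts": len(cms.contacts),
                          "n_salt_bridges": n_salt}


def _stage_cvs(config, outdir, state, report):
    cms = state["cms"]
    traj = state["structure_traj"]
    offset = config["structures"]["numbering_offset"]
    form = config["cv"]["form"]
    rows = {"cv1": [], "cv2": [], "cv3": []}
    for frame in traj.frames:
        f = apply_numbering_offset(frame, offset)
        rows["cv1"].append(cv1_distance_difference(f))
        rows["cv2"].append(contact_map_distance(f, cms, "inactive", form))
        rows["cv3"].append(contact_map_distance(f, cms, "active", form))
    from .trajectory import Trajectory
    cv_traj = Trajectory(times=traj.times,
                         cvs=np.column_stack([rows["cv1"], rows["cv2"],
                                              rows["cv3"]]),
                         cv_names=["cv1", "cv2", "cv3"])
    pio.write_colvar_file(cv_traj, outdir / "COLVAR_structures")
    state["cv_traj"] = cv_traj
    report["cvs"] = {k: [float(np.min(v)), float(np.max(v))]
                     for k, v in rows.items()}


def _stage_sampling(config, outdir, state, report):
    sp = config["sampler"]
    pot_cfg = dict(sp["potential"])
    potential = make_potential(pot_cfg.pop("name"), **pot_cfg)
    ladder = ReplicaLadder(temperatures=tuple(sp["ladder"]),
                           exchange_period=sp["exchange_period"])
    seed = int(config["seed"])

    wte = WTEParams(**sp["wte"])
    pre = wte_prestage(ladder, potential, wte, seed=seed + 2,
                       dt=sp["dt"], friction=sp["friction"])
    report["wte"] = {"achieved_rate": pre.achieved_rate,
                     "n_attempts": pre.n_attempts,
                     "hills_per_replica": len(pre.ledgers[0])}
    pio.write_hills_file(pre.ledgers[0], outdir / "HILLS_energy.0")

    # a fraction of replicas starts in the opposite (inactive-like) basin
    lo, hi = potential.domain
    n_rep = len(ladder)
    n_alt = int(round(sp["inactive_start_fraction"] * n_rep))
    x0 = np.tile(np.atleast_1d(lo) * 0.5, (n_rep, 1))
    rng = np.random.default_rng(seed + 3)
    alt = rng.choice(n_rep, size=n_alt, replace=False)
    x0[alt] = np.atleast_1d(hi) * 0.5

    metad = MetaDParams(**sp["metad"])
    pt = ParallelTempering(potential, ladder, seed=seed + 3, dt=sp["dt"],
                           friction=sp["friction"], x0=x0, metad=metad,
                           energy_bias=pre.energy_bias)
    pt.run(int(sp["n_steps"]))
    ledger = pt.cv_ledgers[0]
    traj = pt.trajectory(0)
    pio.write_hills_file(ledger, outdir / "HILLS.0")
    pio.write_colvar_file(traj, outdir / "COLVAR.0")
    state["ledger"] = ledger
    state["sample_traj"] = traj
    state["potential"] = potential
    report["sampling"] = {
        "n_hills": len(ledger),
        "mean_exchange_rate": pt.mean_pair_rate(),
        "final_hill_height": float(ledger.heights[-1]),
    }


def _stage_fes(config, outdir, state, report):
    ledger = state["ledger"]
    n = config["fes"]["grid_nodes"]
    potential = state.get("potential")
    axes = (default_grid_axes(potential.domain, n=n)
            if potential is not None else None)
    fes = sum_hills(ledger, axes=axes)
    pio.write_fes_text(fes, outdir / "fes.dat")
    pio.write_fes_csv(fes, outdir / "fes.csv")
    conv = convergence_report(ledger,
                              window=config["fes"]["convergence"]["window"],
                              threshold=config["fes"]["convergence"]["threshold"],
                              cv_series=state.get("sample_traj"), axes=axes)
    state["fes"] = fes
    report["fes"] = {"converged": conv.converged,
                     "max_delta_kcal": conv.max_delta,
                     "window_ps": conv.window,
                     "diffusivity": conv.diffusivity}


def _stage_minima(config, outdir, state, report):
    fes = state["fes"]
    basins = find_minima(fes, min_depth=config["fes"]["min_depth"])
    state["basins"] = basins
    with open(outdir / "minima.csv", "w") as fh:
        fh.write("basin,coords,f_min_kcal,depth_kcal,n_members\n")
        for i, b in enumerate(basins):
            coords = ";".join(f"{c:.4f}" for c in b.coords)
            fh.write(f"{i},{coords},{b.f_min:.4f},{b.depth:.4f},"
                     f"{len(b.members)}\n")
    report["minima"] = [{"coords": [float(c) for c in b.coords],
                         "depth_kcal": b.depth} for b in basins]


def _stage_mep(config, outdir, state, report):
    basins = state.get("basins", [])
    if len(basins) < 2:
        report["mep"] = None
        return
    fes = state["fes"]
    path = minimum_energy_path(fes, basins[0].minimum, basins[1].minimum)
    with open(outdir / "mep.csv", "w") as fh:
        fh.write("step," + ",".join(ax.name for ax in fes.axes)
                 + ",f_kcal\n")
        for s, node in enumerate(path.nodes):
            coords = fes.node_coords(node)
            fh.write(f"{s}," + ",".join(f"{c:.5f}" for c in coords)
                     + f",{path.profile[s]:.4f}\n")
    report["mep"] = {"barrier_kcal": path.barrier,
                     "n_nodes": len(path.nodes)}


def _stage_clustering(config, outdir, state, report):
    traj = state["structure_traj"]
    frames = traj.frames
    # Cα selection over the whole toy chain (the A-loop/αC-helix analogue)
    sel = [AtomSelector(a.chain, a.resid, a.name)
           for a in frames[0].atoms if a.name == "CA"]
    dmat = pairwise_rmsd_matrix(frames, sel, superpose=True)
    cset = gromos_cluster(dmat, cutoff=config["clustering"]["cutoff"])
    with open(outdir / "clusters.csv", "w") as fh:
        fh.write("frame,cluster\n")
        for ci, members in enumerate(cset.clusters):
            for m in members:
                fh.write(f"{m},{ci}\n")
    reps = [central_structure(members, dmat) for members in cset.clusters]
    with open(outdir / "cluster_summary.csv", "w") as fh:
        fh.write("cluster,size,central_frame\n")
        for ci, (members, rep) in enumerate(zip(cset.clusters, reps)):
            fh.write(f"{ci},{len(members)},{rep}\n")
    report["clustering"] = {"n_clusters": len(cset.clusters),
                            "sizes": [len(m) for m in cset.clusters],
                            "central_frames": reps}


def _stage_report(config, outdir, state, report):
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
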