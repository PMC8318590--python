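"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here at desk scale:

* a pair of coarse two-state "kinase" structures differing in a planted
  set of discriminating contacts (including Lys–Glu salt bridges) and in
  a K/E/D triad whose distances flip sign of the distance-difference CV;
* two-state coordinate trajectories with planted switch times;
* hill streams with prescribed convergence behaviour;
* toy potentials paired with their exact inter-basin ΔF from
  high-resolution quadrature (the oracle for sampler tests).

The toy geometry is deliberately abstract: residues sit on a widely
spaced backbone (2 nm pitch) so that *only* the planted atom pairs can
satisfy a contact cutoff, which makes ground-truth recovery exact.
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .potentials import ToyPotential, make_potential
from .sampler import Hill, HillsLedger
from .structures import Atom, AtomSelector, Structure
from .trajectory import Trajectory

__all__ = [
    "ToyKinaseSpec", "HillsStreamSpec",
    "make_toy_kinase_pair", "make_two_state_trajectory",
    "make_hills_stream", "make_reference_potential", "quadrature_delta_f",
]

#: PDB-convention residue ids of the CV1 triad (+24 gives the
#: signal-peptide "paper" numbering: K745, E762, D855).
TRIAD_PDB_RESIDS = {"K": 721, "E": 738, "D": 831}


@dataclass
class ToyKinaseSpec:
    """Blueprint of the synthetic active/inactive reference pair."""

    n_residues: int = 140
    first_resid: int = 700            # pdb-convention numbering
    n_active_contacts: int = 5        # formed in active, broken in inactive
    n_inactive_contacts: int = 5      # the reverse
    n_salt_bridges: int = 2           # Lys–Glu subset of the active class
    d_ke_active: float = 0.35         # triad distances, nm
    d_ke_inactive: float = 1.20
    d_kd_active: float = 1.00
    d_kd_inactive: float = 0.40
    contact_distance: float = 0.40    # planted formed-pair distance, nm
    backbone_pitch: float = 2.0       # nm between consecutive residues
    seed: int = 0

    def __post_init__(self):
        if min(self.n_active_contacts, self.n_inactive_contacts,
               self.n_salt_bridges) < 1:
            raise ValueError("planted counts must be at least 1")
        if self.n_salt_bridges > self.n_active_contacts:
            raise ValueError("salt bridges are a subset of the "
                             "active-specific contacts")
        d = (self.d_ke_active, self.d_ke_inactive,
             self.d_kd_active, self.d_kd_inactive, self.contact_distance)
        if min(d) <= 0:
            raise ValueError("distances must be positive")
        if not (self.d_ke_active < self.d_ke_inactive
                and self.d_kd_inactive < self.d_kd_active):
            raise ValueError("contradictory triad distances: each triad "
                             "contact must be short in exactly one state")
        last = self.first_resid + self.n_residues - 1
        if last < max(TRIAD_PDB_RESIDS.values()):
            raise ValueError("chain too short to host the K/E/D triad")


def _base_atoms(spec: ToyKinaseSpec):
    """Residue table: (resid, resname, sidechain atom name, element)."""
    triad = {TRIAD_PDB_RESIDS["K"]: ("LYS", "NZ", "N"),
             TRIAD_PDB_RESIDS["E"]: ("GLU", "CD", "C"),
             TRIAD_PDB_RESIDS["D"]: ("ASP", "CG", "C")}
    rows = []
    for k in range(spec.n_residues):
        resid = spec.first_resid + k
        resname, sc, el = triad.get(resid, ("ALA", "CB", "C"))
        rows.append((resid, resname, sc, el))
    return rows


def make_toy_kinase_pair(spec: ToyKinaseSpec) -> tuple[Structure, Structure, dict]:
    """Generate the two-state reference pair plus its ground truth.

    Returns ``(active, inactive, truth)`` where ``truth`` lists every
    planted discriminating contact (triad contacts included) with its
    origin and weight, so contact-builder recovery can be checked
    exactly.  Structures are in pdb numbering; apply the +24 offset to
    resolve the K745/E762/D855 selectors.
    """
    rng = np.random.default_rng(spec.seed)
    rows = _base_atoms(spec)
    resids = [r[0] for r in rows]
    pitch = spec.backbone_pitch

    home_ca = {resid: np.array([pitch * i, 0.0, 0.0])
               for i, resid in enumerate(resids)}
    sc_off = np.array([0.0, 0.3, 0.0])

    # choose disjoint (anchor, mover) residue pairs for planted contacts,
    # keeping clear of the triad and of short sequence separations
    triad_ids = set(TRIAD_PDB_RESIDS.values())
    guard = {t + d for t in triad_ids for d in range(-2, 3)}
    pool = [r for r in resids if r not in guard]
    rng.shuffle(pool)
    n_pairs = spec.n_active_contacts + spec.n_inactive_contacts
    pairs = []
    while pool and len(pairs) < n_pairs:
        anchor = pool.pop()
        mate = next((p for p in pool if abs(p - anchor) >= 5), None)
        if mate is None:
            break
        pool.remove(mate)
        pairs.append((anchor, mate))
    if len(pairs) < n_pairs:
        raise ValueError("chain too short for the requested contact counts")

    # residue typing for planted salt bridges (Lys anchor, Glu mover)
    overrides = {}
    for idx in range(spec.n_salt_bridges):
        a, m = pairs[idx]
        overrides[a] = ("LYS", "NZ", "N")
        overrides[m] = ("GLU", "OE1", "O")

    def sidechain(resid):
        if resid in overrides:
            return overrides[resid]
        i = resids.index(resid)
        return rows[i][1], rows[i][2], rows[i][3]

    def build(state: str) -> Structure:
        atoms = []
        moved_sc: dict = {}
        if state == "active":
            planted = pairs[:spec.n_active_contacts]
        else:
            planted = pairs[spec.n_active_contacts:n_pairs]
        for anchor, mover in planted:
            anchor_sc = home_ca[anchor] + sc_off
            moved_sc[mover] = anchor_sc + np.array([0.0, spec.contact_distance, 0.0])

        nz = home_ca[TRIAD_PDB_RESIDS["K"]] + sc_off
        if state == "active":
            d_ke, d_kd = spec.d_ke_active, spec.d_kd_active
        else:
            d_ke, d_kd = spec.d_ke_inactive, spec.d_kd_inactive
        triad_sc = {TRIAD_PDB_RESIDS["E"]: nz + np.array([d_ke, 0.0, 0.0]),
                    TRIAD_PDB_RESIDS["D"]: nz + np.array([-d_kd, 0.0, 0.0])}

        for resid in resids:
            resname, sc_name, sc_el = sidechain(resid)
            if resid in triad_sc:
                sc_pos = triad_sc[resid]
                ca_pos = home_ca[resid]
            elif resid in moved_sc:
                sc_pos = moved_sc[resid]
                ca_pos = sc_pos + sc_off
            else:
                ca_pos = home_ca[resid]
                sc_pos = ca_pos + sc_off
            atoms.append(Atom("A", resid, resname, "CA", "C", ca_pos))
            atoms.append(Atom("A", resid, resname, sc_name, sc_el, sc_pos))
        return Structure(atoms, label=state, numbering_convention="pdb")

    active = build("active")
    inactive = build("inactive")

    truth_contacts = []
    for idx, (anchor, mover) in enumerate(pairs[:spec.n_active_contacts]):
        an, asn, _ = sidechain(anchor)
        mn, msn, _ = sidechain(mover)
        truth_contacts.append({
            "pair": (f"A:{anchor}:{asn}", f"A:{mover}:{msn}"),
            "origin": "active-specific",
            "weight": 3 if idx < spec.n_salt_bridges else 1})
    for anchor, mover in pairs[spec.n_active_contacts:n_pairs]:
        _, asn, _ = sidechain(anchor)
        _, msn, _ = sidechain(mover)
        truth_contacts.append({
            "pair": (f"A:{anchor}:{asn}", f"A:{mover}:{msn}"),
            "origin": "inactive-specific",
            "weight": 1})
    kk, ee, dd = (TRIAD_PDB_RESIDS[x] for x in "KED")
    truth_contacts.append({"pair": (f"A:{kk}:NZ", f"A:{ee}:CD"),
                           "origin": "active-specific", "weight": 1})
    truth_contacts.append({"pair": (f"A:{kk}:NZ", f"A:{dd}:CG"),
                           "origin": "inactive-specific", "weight": 1})

    truth = {
        "contacts": truth_contacts,
        "n_contacts": len(truth_contacts),
        "n_salt_bridges": spec.n_salt_bridges,
        "cv1_active": spec.d_ke_active - spec.d_kd_active,
        "cv1_inactive": spec.d_ke_inactive - spec.d_kd_inactive,
    }
    return active, inactive, truth


def make_two_state_trajectory(pair, n_frames: int, switch_times,
                              noise_sigma: float = 0.02, seed: int = 0
                              ) -> tuple[Trajectory, np.ndarray]:
    """Coordinate frames jittering around one state, toggling at the
    given frame indices.  Returns the trajectory (frames attached, 1 ps
    spacing) and the planted per-frame state labels (0 active,
    1 inactive)."""
    active, inactive = pair
    if n_frames < 1:
        raise ValueError("need at least one frame")
    switch_times = sorted(int(t) for t in switch_times)
    if switch_times and switch_times[-1] >= n_frames:
        raise ValueError("switch time beyond the trajectory length")
    labels = np.zeros(n_frames, dtype=int)
    state = 0
    prev = 0
    for t in switch_times + [n_frames]:
        labels[prev:t] = state
        state = 1 - state
        prev = t

    rng = np.random.default_rng(seed)
    base = {0: active.coords(), 1: inactive.coords()}
    frames = []
    for i in range(n_frames):
        coords = base[labels[i]]
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        src = active if labels[i] == 0 else inactive
        frames.append(src.with_coords(coords, label=f"frame{i}"))

    # CV1 triad series as the canonical per-frame CV (pdb-numbered ids)
    k = AtomSelector("A", TRIAD_PDB_RESIDS["K"], "NZ")
    e = AtomSelector("A", TRIAD_PDB_RESIDS["E"], "CD")
    d = AtomSelector("A", TRIAD_PDB_RESIDS["D"], "CG")
    from .cvs import cv1_distance_difference
    cv1 = np.array([cv1_distance_difference(f, k, e, d) for f in frames])
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      cvs=cv1[:, None], cv_names=["cv1"], frames=frames)
    return traj, labels


@dataclass
class HillsStreamSpec:
    """Synthetic hill stream: ``converging`` (geometrically decaying
    heights), ``drifting`` (constant-height hills marching along the
    first CV) or ``constant`` (identical repeated hill)."""

    pattern: str = "converging"
    length: int = 300
    dim: int = 1
    sigma: float = 0.1
    height: float = 3.0
    decay: float = 20.0          # e-folding (in hills) for "converging"
    drift_step: float = 0.05     # nm per hill for "drifting"
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("converging", "drifting", "constant"):
            raise ValueError(f"unknown hills pattern {self.pattern!r}")
        if self.length < 1 or self.dim < 1:
            raise ValueError("length and dim must be positive")


def make_hills_stream(spec: HillsStreamSpec) -> HillsLedger:
    rng = np.random.default_rng(spec.seed)
    sigma = np.full(spec.dim, spec.sigma)
    ledger = HillsLedger(temperature=300.0,
                         cv_names=[f"cv{i+1}" for i in range(spec.dim)])
    for k in range(spec.length):
        t = float(k + 1)
        if spec.pattern == "converging":
            center = rng.uniform(-1.0, 1.0, spec.dim)
            height = spec.height * np.exp(-k / spec.decay)
        elif spec.pattern == "drifting":
            center = np.zeros(spec.dim)
            center[0] = k * spec.drift_step
            height = spec.height
        else:  # constant
            center = np.zeros(spec.dim)
            height = spec.height
        ledger.append(Hill(time=t, center=center, sigma=sigma,
                           height=float(height)))
    return ledger


def quadrature_delta_f(potential: ToyPotential, temperature: float = 300.0,
                       split: float = 0.0, n_nodes: int = 20001,
                       richardson_tol: float = 1e-6) -> float:
    """Exact inter-basin ΔF (kJ/mol) by trapezoid quadrature of e^(−βU).

    Basins are the half-spaces of the first coordinate either side of
    ``split``; ΔF = F(x₁ > split) − F(x₁ < split).  The result is
    Richardson-checked against half resolution.
    """
    beta = 1.0 / (KB * temperature)
    lo, hi = potential.domain
    lo, hi = np.atleast_1d(lo), np.atleast_1d(hi)

    def basin_weight(gx, n):
        # each basin integrated on its own subgrid so the split point is
        # a quadrature node (keeps the trapezoid error at O(h^2))
        if potential.dim == 1:
            w = np.exp(-beta * potential.energy(gx[:, None]))
        else:
            n2 = max(801, min(n, 4001) // 4)
            gy = np.linspace(lo[1], hi[1], n2)
            xx, yy = np.meshgrid(gx, gy, indexing="ij")
            w2 = np.exp(-beta * potential.energy(np.stack([xx, yy], axis=-1)))
            w = np.trapezoid(w2, gy, axis=1)
        return np.trapezoid(w, gx)

    def delta(n):
        if potential.dim not in (1, 2):
            raise ValueError("quadrature supports 1D and 2D potentials")
        n = min(n, 4001) if potential.dim == 2 else n
        left = basin_weight(np.linspace(lo[0], split, n), n)
        right = basin_weight(np.linspace(split, hi[0], n), n)
        return float(-np.log(right / left) / beta)

    full = delta(n_nodes)
    half = delta(n_nodes // 2 + 1)
    if abs(full - half) > max(richardson_tol, 1e-9 * abs(full)) * 100:
        raise RuntimeError("quadrature not converged; refine the grid")
    return full


def make_reference_potential(name: str, temperature: float = 300.0,
                             **params) -> tuple[ToyPotential, float]:
    """A toy potential together with its exact inter-basin ΔF (kJ/mol).

    Supported: ``double_well_1d`` and ``double_well_2d`` (basins split at
    x = 0).  A single-basin potential (``harmonic``) has no inter-basin
    ΔF and raises.
    """
    potential = make_potential(name, **params)
    if name == "harmonic":
        raise ValueError("harmonic well has a single basin; ΔF undefined")
    if name not in ("double_well_1d", "double_well_2d"):
        raise ValueError(f"no analytic ΔF defined for potential {name!r}")
    return potential, quadrature_delta_f(potential, temperature)
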