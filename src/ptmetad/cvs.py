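"""Collective variables for the kinase active ⇌ Src-like-inactive transition.

Three CVs are biased simultaneously in production runs:

* **CV1** — distance difference d(K:NZ, E:CD) − d(K:NZ, D:CG) between the
  catalytic lysine, the αC-helix glutamate and the DFG aspartate
  (K745/E762/D855 in EGFR signal-peptide numbering).  Negative values mean
  the K–E salt bridge is the shorter pair (αC-in, active-like); positive
  values mean K pairs with D (αC-out, Src-like inactive-like).
* **CV2 / CV3** — distances in contact-map space from the Src-like
  inactive and active reference conformations respectively, built on a set
  Γ of *discriminating* contacts: atom pairs formed in one reference
  conformation and broken in the other.

The degree of formation of a contact is a rational switching function of
the interatomic distance r,

    D(r) = w * (1 - (r/r0)^n) / (1 - (r/r0)^m),   n = 6, m = 10,

bounded in (0, w], equal to 0.6*w at r = r0 (removable singularity), and
strictly decreasing in r.  w is 1 for regular contacts and 3 for salt
bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import AtomSelector, Structure, atom_distance

__all__ = [
    "Contact",
    "ContactMapSet",
    "CVFrame",
    "switching_degree",
    "cv1_distance_difference",
    "contact_map_distance",
    "build_discriminating_contacts",
    "interlobal_distance",
    "salt_bridge_series",
    "DEFAULT_TRIAD",
]

#: Default CV1 triad selectors in signal-peptide ("paper") numbering.
DEFAULT_TRIAD = {
    "k": AtomSelector("A", 745, "NZ"),
    "e": AtomSelector("A", 762, "CD"),
    "d": AtomSelector("A", 855, "CG"),
}

#: Basic (side-chain nitrogen) atoms of Lys/Arg and acidic (carboxylate)
#: atoms of Asp/Glu used to flag salt bridges.
_BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass(frozen=True)
class Contact:
    """One discriminating contact γ of the set Γ."""

    pair: tuple[AtomSelector, AtomSelector]
    r0: float                    # reference contact distance, nm
    weight: float = 1.0          # 1 regular, 3 salt bridge
    origin: str = "active-specific"   # or "inactive-specific"

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("contact reference distance r0 must be positive")
        if self.weight not in (1.0, 3.0, 1, 3):
            raise ValueError("contact weight must be 1 (regular) or 3 (salt bridge)")
        a, b = self.pair
        if (a.chain, a.resid) == (b.chain, b.resid):
            raise ValueError("contact atoms must belong to distinct residues")


@dataclass
class ContactMapSet:
    """The contact set Γ with exponents, normalisation and reference degrees."""

    contacts: list[Contact]
    n: int = 6
    m: int = 10
    normalization: float = 1.0
    ref_degrees_active: np.ndarray = field(default=None)
    ref_degrees_inactive: np.ndarray = field(default=None)
    variant: str = "rational"

    def __post_init__(self):
        if not self.contacts:
            raise ValueError("contact set must contain at least one contact")
        if not self.n < self.m:
            raise ValueError("exponents must satisfy n < m")
        if self.normalization <= 0:
            raise ValueError("normalization must be positive")
        for name in ("ref_degrees_active", "ref_degrees_inactive"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (len(self.contacts),):
                    raise ValueError(f"{name} length must match contact count")
                setattr(self, name, v)

    def degrees(self, structure: Structure) -> np.ndarray:
        """Per-contact degrees of formation D_γ evaluated on ``structure``."""
        out = np.empty(len(self.contacts))
        for i, c in enumerate(self.contacts):
            try:
                r = atom_distance(structure, *c.pair)
            except KeyError as exc:
                raise KeyError(f"contact {c.pair[0]}–{c.pair[1]}: {exc}") from None
            out[i] = switching_degree(r, c.r0, self.n, self.m, c.weight,
                                      self.variant)
        return out


@dataclass(frozen=True)
class CVFrame:
    """CV values of one trajectory frame."""

    time: float                   # ps
    cv1: float                    # nm
    cv2: float
    cv3: float
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("frame time must be non-negative")
        vals = [self.cv1, self.cv2, self.cv3, *self.aux.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("CV values must be finite")


def switching_degree(r, r0: float, n: int = 6, m: int = 10,
                     w: float = 1.0, variant: str = "rational"):
    """Degree of formation of a contact at distance ``r`` (nm).

    ``variant="rational"`` (default): w·(1−(r/r0)^n)/(1−(r/r0)^m), the
    standard rational switching function, with the removable singularity at
    r = r0 evaluated as its limit w·n/m.  ``variant="literal"``:
    w·(r/r0)^(n−m), which diverges at r = 0 and is provided only for
    comparison.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    x = r / r0
    if variant == "rational":
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(np.abs(x - 1.0) < 1e-8, n / m,
                           (1.0 - x ** n) / (1.0 - x ** m))
        out = w * val
    elif variant == "literal":
        if np.any(r == 0):
            raise ValueError("literal switching function diverges at r = 0")
        out = w * x ** (n - m)
    else:
        raise ValueError(f"unknown switching variant {variant!r}")
    return float(out) if out.ndim == 0 else out


def cv1_distance_difference(structure: Structure,
                            k: AtomSelector = DEFAULT_TRIAD["k"],
                            e: AtomSelector = DEFAULT_TRIAD["e"],
                            d: AtomSelector = DEFAULT_TRIAD["d"]) -> float:
    """CV1 = d(k, e) − d(k, d) in nm (negative: active-like, K–E formed)."""
    return atom_distance(structure, k, e) - atom_distance(structure, k, d)


def contact_map_distance(structure: Structure, cms: ContactMapSet,
                         reference: str = "inactive",
                         form: str = "normalized_rms") -> float:
    """Distance in contact-map space from a reference conformation.

    Default form: (1/N)·sqrt(Σ_γ (D_γ(s) − D_γ(ref))²).  Alternate forms:
    ``"mean_sq"`` = (1/N)·Σ(ΔD)² and ``"unnormalized"`` = sqrt(Σ(ΔD)²).
    Every form is zero when evaluated at the reference structure itself.
    """
    ref = {"active": cms.ref_degrees_active,
           "inactive": cms.ref_degrees_inactive}.get(reference)
    if ref is None:
        raise ValueError(f"reference degrees for {reference!r} not available")
    delta = cms.degrees(structure) - ref
    return contact_degree_distance(delta, cms.normalization, form)


def contact_degree_distance(delta: np.ndarray, normalization: float,
                            form: str = "normalized_rms") -> float:
    """Aggregate per-contact degree differences into one CV value."""
    ss = float(np.sum(np.asarray(delta, dtype=float) ** 2))
    if form == "normalized_rms":
        return np.sqrt(ss) / normalization
    if form == "mean_sq":
        return ss / normalization
    if form == "unnormalized":
        return np.sqrt(ss)
    raise ValueError(f"unknown contact-map distance form {form!r}")


def _heavy_atoms(structure: Structure):
    return [a for a in structure.atoms if a.element != "H"]


def build_discriminating_contacts(active: Structure, inactive: Structure,
                                  formed_cutoff: float = 0.45,
                                  broken_cutoff: float = 0.80,
                                  min_seq_separation: int = 4,
                                  n: int = 6, m: int = 10,
                                  variant: str = "rational") -> ContactMapSet:
    """Build the set Γ of contacts that discriminate the two conformations.

    Candidate pairs are heavy atoms of residues at least
    ``min_seq_separation`` apart in sequence (or on different chains).  A
    pair enters Γ iff its distance is ≤ ``formed_cutoff`` in one reference
    and ≥ ``broken_cutoff`` in the other; r0 is the distance in the
    conformation where the contact is formed.  Salt bridges (Lys/Arg
    side-chain nitrogen against Asp/Glu carboxylate oxygen) get weight 3,
    everything else weight 1.  The normalisation N is the number of
    retained contacts.
    """
    if not formed_cutoff < broken_cutoff:
        raise ValueError("formed_cutoff must be below broken_cutoff")

    heavy = _heavy_atoms(active)
    keys = [(a.chain, a.resid, a.name) for a in heavy]
    try:
        coords_act = np.array([active.resolve(AtomSelector(*k)).coord for k in keys])
        coords_ina = np.array([inactive.resolve(AtomSelector(*k)).coord for k in keys])
    except KeyError as exc:
        raise KeyError(f"structures do not share candidate atoms: {exc}") from None

    contacts: list[Contact] = []
    natoms = len(heavy)
    d_act = np.linalg.norm(coords_act[:, None, :] - coords_act[None, :, :], axis=-1)
    d_ina = np.linalg.norm(coords_ina[:, None, :] - coords_ina[None, :, :], axis=-1)

    for i in range(natoms):
        for j in range(i + 1, natoms):
            ai, aj = heavy[i], heavy[j]
            if ai.chain == aj.chain and abs(ai.resid - aj.resid) < min_seq_separation:
                continue
            da, di = d_act[i, j], d_ina[i, j]
            if da <= formed_cutoff and di >= broken_cutoff:
                origin, r0 = "active-specific", da
            elif di <= formed_cutoff and da >= broken_cutoff:
                origin, r0 = "inactive-specific", di
            else:
                continue
            pi = (ai.resname, ai.name)
            pj = (aj.resname, aj.name)
            salt = ((pi in _BASIC_ATOMS and pj in _ACIDIC_ATOMS) or
                    (pj in _BASIC_ATOMS and pi in _ACIDIC_ATOMS))
            contacts.append(Contact(
                pair=(AtomSelector(ai.chain, ai.resid, ai.name),
                      AtomSelector(aj.chain, aj.resid, aj.name)),
                r0=float(r0), weight=3.0 if salt else 1.0, origin=origin))

    if not contacts:
        raise ValueError("no discriminating contacts found with "
                         f"cutoffs {formed_cutoff}/{broken_cutoff} nm")

    cms = ContactMapSet(contacts=contacts, n=n, m=m,
                        normalization=float(len(contacts)), variant=variant)
    cms.ref_degrees_active = cms.degrees(active)
    cms.ref_degrees_inactive = cms.degrees(inactive)
    return cms


def interlobal_distance(structure: Structure, nlobe_residues, clobe_residues,
                        chain: str = "A") -> float:
    """Distance between the Cα centres of geometry of the two kinase lobes."""
    def cog(resids):
        pts = [a.coord for a in structure.atoms
               if a.chain == chain and a.name == "CA" and a.resid in resids]
        if not pts:
            raise ValueError("empty lobe selection")
        return np.mean(pts, axis=0)

    return float(np.linalg.norm(cog(set(nlobe_residues)) - cog(set(clobe_residues))))


def salt_bridge_series(frames: list[Structure],
                       pair: tuple[AtomSelector, AtomSelector],
                       cutoff: float = 0.45) -> tuple[np.ndarray, float]:
    """Per-frame distance (nm) of an ion pair and its formed-fraction.

    Occupancy is the fraction of frames with distance ≤ ``cutoff``.
    """
    if not frames:
        raise ValueError("empty trajectory")
    dists = np.array([atom_distance(f, *pair) for f in frames])
    return dists, float(np.mean(dists <= cutoff))
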