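"""Text-format readers and writers.

HILLS and COLVAR files follow the PLUMED dialect: a ``#! FIELDS ...``
header naming the columns, whitespace-separated numeric rows, values
round-tripping at 9 significant digits.  Columns are mapped by name,
never by position.  Contact sets and FES grids use simple commented
column formats; FES grids are additionally written in the sum_hills
layout (one node per line, blank line between rows of the first axis).
"""

from __future__ import annotations

import numpy as np

from .cvs import Contact, ContactMapSet
from .fes import FESGrid
from .grids import GridAxis
from .sampler import Hill, HillsLedger, MetaDParams
from .structures import AtomSelector
from .trajectory import Trajectory

__all__ = [
    "write_hills_file", "read_hills_file",
    "write_colvar_file", "read_colvar_file",
    "write_contacts_file", "read_contacts_file",
    "write_fes_text", "write_fes_csv",
]

_FMT = "%.9g"


def _parse_fields_header(line: str, path, lineno: int) -> list[str]:
    if not line.startswith("#!"):
        raise ValueError(f"{path}:{lineno}: missing '#! FIELDS' header")
    tokens = line[2:].split()
    if not tokens or tokens[0] != "FIELDS":
        raise ValueError(f"{path}:{lineno}: malformed FIELDS header")
    return tokens[1:]


def write_hills_file(ledger: HillsLedger, path) -> None:
    names = ledger.cv_names or [f"cv{i+1}" for i in range(ledger.dim)]
    cols = (["time"] + names + [f"sigma_{n}" for n in names]
            + ["height", "biasf"])
    biasf = (ledger.params.bias_factor if ledger.params is not None else 1.0)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for h in ledger.hills:
            row = ([h.time] + list(h.center) + list(h.sigma)
                   + [h.height, biasf])
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_hills_file(path, temperature: float = 300.0) -> HillsLedger:
    """Read a HILLS file; columns are matched by header name.

    Field layout: ``time``, one column per CV, ``sigma_<cv>`` per CV,
    ``height`` and optionally ``biasf``.  Non-monotone times or unknown
    columns are reported with their line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    fields = _parse_fields_header(lines[0].rstrip("\n"), path, 1)
    known = {"time", "height", "biasf"}
    cv_names = [f for f in fields
                if f not in known and not f.startswith("sigma_")]
    for f in fields:
        if f.startswith("sigma_") and f[len("sigma_"):] not in cv_names:
            raise ValueError(f"{path}:1: sigma column {f!r} has no CV")
    if "time" not in fields or "height" not in fields:
        raise ValueError(f"{path}:1: need 'time' and 'height' columns")
    col = {f: i for i, f in enumerate(fields)}

    hills = []
    biasf = None
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(f"{path}:{lineno}: expected {len(fields)} "
                             f"columns, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numeric value")
        t = vals[col["time"]]
        if hills and t <= hills[-1].time:
            raise ValueError(f"{path}:{lineno}: non-monotone time {t}")
        center = np.array([vals[col[n]] for n in cv_names])
        sigma = np.array([vals[col[f"sigma_{n}"]] for n in cv_names])
        hills.append(Hill(time=t, center=center, sigma=sigma,
                          height=vals[col["height"]]))
        if "biasf" in col:
            biasf = vals[col["biasf"]]
    if not hills:
        raise ValueError(f"{path}: no hills")
    params = None
    if biasf is not None and biasf > 1.0:
        params = MetaDParams(w0=float(max(h.height for h in hills)),
                             bias_factor=biasf)
    ledger = HillsLedger(params=params, temperature=temperature,
                         cv_names=cv_names)
    for h in hills:
        ledger.append(h)
    return ledger


def write_colvar_file(traj: Trajectory, path) -> None:
    aux_names = list(traj.aux)
    cols = ["time"] + list(traj.cv_names) + ["bias"] + aux_names
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for i in range(len(traj)):
            row = ([traj.times[i]] + list(traj.cvs[i]) + [traj.bias[i]]
                   + [np.atleast_1d(traj.aux[a][i])[0] for a in aux_names])
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_colvar_file(path, temperature: float = 300.0) -> Trajectory:
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    fields = _parse_fields_header(lines[0].rstrip("\n"), path, 1)
    if "time" not in fields:
        raise ValueError(f"{path}:1: need a 'time' column")
    cv_names = [f for f in fields if f not in ("time", "bias")]
    col = {f: i for i, f in enumerate(fields)}
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(f"{path}:{lineno}: expected {len(fields)} "
                             f"columns, got {len(parts)}")
        rows.append([float(p) for p in parts])
    data = np.array(rows)
    if data.size == 0:
        raise ValueError(f"{path}: no frames")
    return Trajectory(
        times=data[:, col["time"]],
        cvs=data[:, [col[n] for n in cv_names]],
        bias=data[:, col["bias"]] if "bias" in col else None,
        temperature=temperature, cv_names=cv_names)


def write_contacts_file(cms: ContactMapSet, path) -> None:
    """One contact per line: selectors, r0 (nm), weight, origin and the
    reference degrees at both conformations."""
    with open(path, "w") as fh:
        fh.write(f"# contact map set: n={cms.n} m={cms.m} "
                 f"N={_FMT % cms.normalization} variant={cms.variant}\n")
        fh.write("# atomA atomB r0_nm weight origin "
                 "ref_deg_active ref_deg_inactive\n")
        for i, c in enumerate(cms.contacts):
            da = cms.ref_degrees_active[i] if cms.ref_degrees_active is not None else np.nan
            di = cms.ref_degrees_inactive[i] if cms.ref_degrees_inactive is not None else np.nan
            fh.write(f"{c.pair[0]} {c.pair[1]} {_FMT % c.r0} "
                     f"{int(c.weight)} {c.origin} {_FMT % da} {_FMT % di}\n")


def read_contacts_file(path) -> ContactMapSet:
    contacts, da, di = [], [], []
    n, m, norm, variant = 6, 10, None, "rational"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("# contact map set:"):
                for tok in line.split(":", 1)[1].split():
                    key, val = tok.split("=")
                    if key == "n":
                        n = int(val)
                    elif key == "m":
                        m = int(val)
                    elif key == "N":
                        norm = float(val)
                    elif key == "variant":
                        variant = val
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            contacts.append(Contact(
                pair=(AtomSelector.parse(parts[0]),
                      AtomSelector.parse(parts[1])),
                r0=float(parts[2]), weight=float(parts[3]), origin=parts[4]))
            da.append(float(parts[5]))
            di.append(float(parts[6]))
    if not contacts:
        raise ValueError(f"{path}: no contacts")
    return ContactMapSet(
        contacts=contacts, n=n, m=m,
        normalization=norm if norm is not None else float(len(contacts)),
        ref_degrees_active=np.array(da), ref_degrees_inactive=np.array(di),
        variant=variant)


def write_fes_text(fes: FESGrid, path) -> None:
    """sum_hills-style grid: one node per line, blank line between rows."""
    names = [ax.name for ax in fes.axes]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + " free\n")
        for ax in fes.axes:
            fh.write(f"#! SET min_{ax.name} {_FMT % ax.lo}\n")
            fh.write(f"#! SET max_{ax.name} {_FMT % ax.hi}\n")
            fh.write(f"#! SET nbins_{ax.name} {ax.n}\n")
        if fes.dim == 1:
            for i, x in enumerate(fes.axes[0].nodes):
                fh.write(f"{_FMT % x} {_FMT % fes.values[i]}\n")
        else:
            for i, x in enumerate(fes.axes[0].nodes):
                for j, y in enumerate(fes.axes[1].nodes):
                    fh.write(f"{_FMT % x} {_FMT % y} "
                             f"{_FMT % fes.values[i, j]}\n")
                fh.write("\n")


def write_fes_csv(fes: FESGrid, path) -> None:
    names = [ax.name for ax in fes.axes]
    with open(path, "w") as fh:
        fh.write(",".join(names + ["free_kcal_mol", "sampled"]) + "\n")
        for idx in np.ndindex(fes.values.shape):
            coords = fes.node_coords(idx)
            fh.write(",".join([_FMT % c for c in coords]
                              + [_FMT % fes.values[idx],
                                 str(int(fes.mask[idx]))]) + "\n")
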