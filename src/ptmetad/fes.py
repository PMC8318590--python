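"""Free-energy surfaces from metadynamics hills.

The well-tempered estimator is used throughout: with bias factor f the
deposited bias converges to −(1 − 1/f)·F(s), so the surface is recovered
as F = −(f/(f−1))·V, min-shifted to zero.  Internal bias energies are
kJ/mol; every reported free energy is in kcal/mol, matching the way
basin depths and convergence thresholds are quoted in the kinase
literature.

Grid conventions: 1D grids use 2-neighbourhoods, 2D grids use
8-neighbourhoods, both for basin detection (steepest-descent watershed
with persistence-based merging) and for minimum-energy paths (minimax
barrier criterion with cumulative-energy tie-break, a grid-global search
in the spirit of MEPSA).  Unsampled nodes carry NaN and are impassable.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import KB, KJ_PER_KCAL
from .grids import GridAxis
from .sampler import HillsLedger
from .trajectory import Trajectory, count_well_transitions

__all__ = [
    "FESGrid", "Basin", "PathResult", "ConvergenceReport",
    "sum_hills", "convergence_report", "reweight_project",
    "find_minima", "free_energy_difference", "minimum_energy_path",
    "ledger_delta_f",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = KB / KJ_PER_KCAL


@dataclass
class FESGrid:
    """Free energy on a regular 1–2D CV grid, kcal/mol, min-shifted to 0.

    ``mask`` flags sampled nodes; unsampled nodes hold NaN and are never
    silently treated as zero.
    """

    axes: list[GridAxis]
    values: np.ndarray
    mask: np.ndarray = None
    temperature: float = 300.0
    bias_factor: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(ax.n for ax in self.axes)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} does not "
                             f"match axes {expected}")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.any():
            vmin = np.nanmin(self.values[self.mask])
            self.values = self.values - vmin
            if not np.all(np.isfinite(self.values[self.mask])):
                raise ValueError("non-finite free energy on sampled nodes")

    @property
    def dim(self) -> int:
        return len(self.axes)

    def node_coords(self, idx) -> np.ndarray:
        idx = (idx,) if np.isscalar(idx) else tuple(idx)
        return np.array([ax.nodes[i] for ax, i in zip(self.axes, idx)])

    def nearest_node(self, coords) -> tuple:
        coords = np.atleast_1d(coords)
        return tuple(int(np.argmin(np.abs(ax.nodes - c)))
                     for ax, c in zip(self.axes, coords))

    def grid_points(self) -> np.ndarray:
        """All node coordinates, shape (n_nodes, dim)."""
        meshes = np.meshgrid(*[ax.nodes for ax in self.axes], indexing="ij")
        return np.stack([m.ravel() for m in meshes], axis=-1)

    def interpolate(self, points) -> np.ndarray:
        """Multilinear interpolation of F at off-node points."""
        from scipy.interpolate import RegularGridInterpolator
        interp = RegularGridInterpolator(
            [ax.nodes for ax in self.axes], self.values,
            bounds_error=False, fill_value=np.nan)
        return interp(np.atleast_2d(points))


@dataclass
class Basin:
    """One free-energy basin: its minimum, watershed members and depth
    (kcal/mol above the global minimum)."""

    minimum: tuple                  # grid index of the minimum node
    members: list                   # grid indices assigned by watershed
    depth: float                    # F(min) - F(global min), kcal/mol
    coords: np.ndarray              # CV coordinates of the minimum
    f_min: float                    # F at the minimum (shifted scale)
    persistence: float              # depth below the lowest escape saddle


@dataclass
class PathResult:
    nodes: list                     # grid indices from start to end
    barrier: float                  # max F along the path, kcal/mol
    profile: np.ndarray             # per-node F along the path


@dataclass
class ConvergenceReport:
    converged: bool
    max_delta: float                # kcal/mol
    window: float                   # ps actually used
    diffusivity: dict = field(default_factory=dict)  # per-CV crossing count


def _resolve_axes(ledger: HillsLedger, axes=None, n: int = 128):
    if axes is not None:
        return list(axes)
    if not ledger.hills:
        raise ValueError("grid axes required for an empty ledger")
    c, s = ledger.centers, ledger.sigmas
    lo = (c - 3 * s).min(axis=0)
    hi = (c + 3 * s).max(axis=0)
    names = ledger.cv_names or [f"cv{i+1}" for i in range(ledger.dim)]
    return [GridAxis(names[k], float(lo[k]), float(hi[k]), n)
            for k in range(ledger.dim)]


def sum_hills(ledger: HillsLedger, axes=None, projection=None,
              temperature: float | None = None) -> FESGrid:
    """Reconstruct the FES by summing the deposited bias on a grid.

    The full-dimensional bias is summed exactly (direct Gaussian
    summation) on the grid, rescaled by −f/(f−1) and min-shifted.  A
    ``projection`` (subset of CV axis names) marginalises the dropped
    axes by F_proj = −kB·T·ln Σ exp(−F/kB·T).
    """
    axes = _resolve_axes(ledger, axes)
    f = ledger.params.bias_factor if ledger.params is not None else None
    rescale = f / (f - 1.0) if f is not None else 1.0
    temperature = temperature if temperature is not None else ledger.temperature

    meshes = np.meshgrid(*[ax.nodes for ax in axes], indexing="ij")
    points = np.stack([m.ravel() for m in meshes], axis=-1)
    v = ledger.bias_at(points).reshape([ax.n for ax in axes])
    f_kj = -rescale * v

    if projection is not None:
        names = [ax.name for ax in axes]
        keep = [names.index(p) for p in projection]
        if len(keep) != len(projection):
            raise ValueError("projection axis not present in ledger")
        drop = [k for k in range(len(axes)) if k not in keep]
        if drop:
            beta = 1.0 / (KB * temperature)
            # marginalise dropped axes at fixed kept-axis nodes
            f_kj = np.transpose(f_kj, keep + drop)
            flat = f_kj.reshape(f_kj.shape[:len(keep)] + (-1,))
            f_kj = -logsumexp(-beta * flat, axis=-1) / beta
        else:
            f_kj = np.transpose(f_kj, keep)
        axes = [axes[k] for k in keep]

    return FESGrid(axes=axes, values=f_kj / KJ_PER_KCAL,
                   temperature=temperature, bias_factor=f)


def convergence_report(ledger: HillsLedger, window: float = 100_000.0,
                       threshold: float = 2.5,
                       cv_series: Trajectory | None = None,
                       axes=None) -> ConvergenceReport:
    """Check that the FES stopped evolving over the trailing window.

    The criterion passes when the min-shifted FES changed by no more than
    ``threshold`` kcal/mol (≤ convention: a change exactly at the
    threshold still passes) between t_end − window and t_end.  Runs
    shorter than the window fall back to the trailing 10% of the run.
    ``diffusivity`` counts, per CV, the crossings between the outer
    quartiles of the sampled range within the window.
    """
    if not ledger.hills:
        raise ValueError("cannot assess convergence of an empty ledger")
    t_end = ledger.times[-1]
    span = ledger.span
    win = window if span > window else 0.1 * span
    axes = _resolve_axes(ledger, axes)
    f_end = sum_hills(ledger, axes=axes)
    f_prev = sum_hills(ledger.subset(t_end - win), axes=axes)
    max_delta = float(np.max(np.abs(f_end.values - f_prev.values)))

    diffusivity = {}
    if cv_series is not None and len(cv_series):
        in_win = cv_series.times >= (cv_series.times[-1] - win)
        for k, name in enumerate(cv_series.cv_names):
            x = cv_series.cvs[:, k]
            q1, q3 = np.percentile(x, [25, 75])
            diffusivity[name] = count_well_transitions(x[in_win], q1, q3)

    return ConvergenceReport(converged=max_delta <= threshold,
                             max_delta=max_delta, window=win,
                             diffusivity=diffusivity)


def reweight_project(traj: Trajectory, new_cv: np.ndarray,
                     temperature: float, axes) -> FESGrid:
    """Project the free energy onto an unbiased CV by static reweighting.

    Each frame i carries the final-ledger bias V(s_i); its weight is
    w_i ∝ exp(V(s_i)/kB·T).  The projected free energy is
    −kB·T·ln Σ w_i per bin, min-shifted; empty bins are flagged as
    unsampled, never imputed.
    """
    if traj.bias is None:
        raise ValueError("trajectory carries no bias column")
    axes = [axes] if isinstance(axes, GridAxis) else list(axes)
    new_cv = np.asarray(new_cv, dtype=float)
    if new_cv.ndim == 1:
        new_cv = new_cv[:, None]
    if new_cv.shape[0] != len(traj):
        raise ValueError("new_cv length must match trajectory")

    beta = 1.0 / (KB * temperature)
    logw = beta * (traj.bias - traj.bias.max())

    edges = []
    for ax in axes:
        nodes = ax.nodes
        half = ax.spacing / 2.0
        edges.append(np.concatenate([nodes - half, [nodes[-1] + half]]))

    shape = tuple(ax.n for ax in axes)
    log_hist = np.full(shape, -np.inf)
    idx = []
    inside = np.ones(new_cv.shape[0], dtype=bool)
    for k, ax in enumerate(axes):
        i = np.digitize(new_cv[:, k], edges[k]) - 1
        inside &= (i >= 0) & (i < ax.n)
        idx.append(i)
    flat = np.ravel_multi_index([i[inside] for i in idx], shape)
    lw = logw[inside]
    order = np.argsort(flat, kind="stable")
    flat, lw = flat[order], lw[order]
    uniq, starts = np.unique(flat, return_index=True)
    for u, a, b in zip(uniq, starts, np.append(starts[1:], len(flat))):
        log_hist.ravel()[u] = logsumexp(lw[a:b])

    with np.errstate(invalid="ignore"):
        f_kj = np.where(np.isfinite(log_hist), -log_hist / beta, np.nan)
    return FESGrid(axes=axes, values=f_kj / KJ_PER_KCAL,
                   mask=np.isfinite(f_kj), temperature=temperature)


def ledger_delta_f(ledger: HillsLedger, split: float = 0.0,
                   temperature: float | None = None,
                   tail_fraction: float = 0.3, n_slices: int = 7,
                   axes=None) -> float:
    """Inter-basin ΔF (kJ/mol) from a well-tempered hills ledger.

    Basins are the half-spaces of the first CV either side of ``split``;
    each basin's free energy is the Boltzmann integral of the
    reconstructed FES.  Because the instantaneous well-tempered estimate
    oscillates around the converged surface, the estimate is averaged
    over ``n_slices`` time points spanning the trailing ``tail_fraction``
    of the run — the usual time-averaged estimator.
    """
    temperature = temperature if temperature is not None else ledger.temperature
    beta = 1.0 / (KB * temperature)
    axes = _resolve_axes(ledger, axes)

    def one(t_max):
        fes = sum_hills(ledger.subset(t_max), axes=axes,
                        temperature=temperature)
        x = fes.axes[0].nodes
        f_kj = fes.values * KJ_PER_KCAL
        if fes.dim == 2:
            f_kj = -logsumexp(-beta * f_kj, axis=1) / beta
        w = np.exp(-beta * (f_kj - f_kj.min()))
        left = np.trapezoid(np.where(x < split, w, 0.0), x)
        right = np.trapezoid(np.where(x > split, w, 0.0), x)
        return float(-np.log(right / left) / beta)

    t_end = ledger.times[-1]
    t_lo = t_end * (1.0 - tail_fraction)
    return float(np.mean([one(t) for t in np.linspace(t_lo, t_end, n_slices)]))


# ---------------------------------------------------------------------------
# Basins and paths


def _neighbors(shape, idx):
    """Grid neighbours: 2-neighbourhood in 1D, 8-neighbourhood in 2D."""
    if len(shape) == 1:
        (i,) = idx
        for di in (-1, 1):
            j = i + di
            if 0 <= j < shape[0]:
                yield (j,)
    else:
        i, j = idx
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if di == dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < shape[0] and 0 <= b < shape[1]:
                yield (a, b)


def find_minima(fes: FESGrid, min_depth: float = 0.0) -> list[Basin]:
    """Locate basins deeper than ``min_depth`` below their escape saddle.

    Nodes are processed in increasing free energy (persistence/watershed
    sweep): a local minimum spawns a component, and when two components
    meet at a saddle the shallower one either merges (persistence below
    ``min_depth``) or survives as its own basin.  Members are assigned by
    steepest descent on the grid graph; flat ties break toward the lowest
    node index.  The global minimum's persistence is the full sampled
    range of F, so a flat surface yields no basins.
    """
    shape = fes.values.shape
    vals = fes.values
    mask = fes.mask
    order = sorted((idx for idx in np.ndindex(shape) if mask[idx]),
                   key=lambda idx: (vals[idx], idx))
    if not order:
        return []

    parent: dict = {}
    comp_min: dict = {}
    absorbed: dict = {}   # minimum -> surviving minimum it merged into
    saddles: dict = {}    # minimum -> F at its lowest escape saddle
    processed: set = set()

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    spawned: set = set()  # nodes that started a component = local minima
    for idx in order:
        roots = {find(nb) for nb in _neighbors(shape, idx)
                 if nb in processed}
        processed.add(idx)
        if not roots:
            parent[idx] = idx
            comp_min[idx] = idx
            spawned.add(idx)
            continue
        main = min(roots, key=lambda r: (vals[comp_min[r]], comp_min[r]))
        parent[idx] = main
        for r in roots - {main}:
            dead_min = comp_min[r]
            saddles[dead_min] = vals[idx]
            absorbed[dead_min] = comp_min[main]
            parent[r] = main

    f_max = vals[order[-1]]
    f_global = vals[order[0]]

    def persistence(m):
        if m in saddles:
            return saddles[m] - vals[m]
        return f_max - f_global  # global minimum never dies

    retained = {m for m in spawned if persistence(m) > min_depth}
    if not retained:
        return []

    def resolve(m):
        # follow the merge tree up to the first retained minimum
        while m not in retained:
            m = absorbed[m]
        return m

    # steepest-descent watershed assignment; every descent terminates on a
    # local minimum (a spawned node), flat ties resolved lexicographically
    terminal_cache: dict = {}

    def descend(start_idx):
        path = []
        cur = start_idx
        while cur not in terminal_cache:
            path.append(cur)
            nxt = cur
            for nb in _neighbors(shape, cur):
                if mask[nb] and (vals[nb], nb) < (vals[nxt], nxt):
                    nxt = nb
            if nxt == cur:
                terminal_cache[cur] = cur
                break
            cur = nxt
        term = terminal_cache[cur]
        for p in path:
            terminal_cache[p] = term
        return term

    members: dict = {m: [] for m in retained}
    for idx in order:
        members[resolve(descend(idx))].append(idx)

    basins = []
    for m in sorted(retained, key=lambda m: (vals[m], m)):
        basins.append(Basin(minimum=m, members=members[m],
                            depth=float(vals[m] - f_global),
                            coords=fes.node_coords(m),
                            f_min=float(vals[m]),
                            persistence=float(persistence(m))))
    return basins


def free_energy_difference(fes: FESGrid, a: Basin, b: Basin,
                           mode: str = "min-to-min") -> float:
    """ΔF = F(b) − F(a) in kcal/mol, min-to-min or Boltzmann-integrated.

    ``integrated`` mode compares basin partition functions
    Z = Σ_members exp(−F/kB·T); a wide shallow basin can therefore be
    favoured over a narrow deep one, and the two modes legitimately
    disagree in that situation.
    """
    if a.minimum != b.minimum and set(a.members) & set(b.members):
        raise ValueError("basins overlap")
    if mode == "min-to-min":
        return b.f_min - a.f_min
    if mode == "integrated":
        beta = 1.0 / (KB_KCAL * fes.temperature)
        za = logsumexp([-beta * fes.values[m] for m in a.members])
        zb = logsumexp([-beta * fes.values[m] for m in b.members])
        return float(-(zb - za) / beta)
    raise ValueError(f"unknown mode {mode!r}")


def minimum_energy_path(fes: FESGrid, start, end) -> PathResult:
    """Minimax path between two nodes: minimise the highest F crossed.

    Among all grid paths the returned one minimises the maximum node
    energy (the barrier); ties are broken by minimal cumulative energy
    along the path, then deterministically by node order.  Unsampled
    nodes are impassable.
    """
    shape = fes.values.shape
    vals = fes.values
    mask = fes.mask
    start = tuple(start) if not np.isscalar(start) else (int(start),)
    end = tuple(end) if not np.isscalar(end) else (int(end),)
    for p, nm in ((start, "start"), (end, "end")):
        if not mask[p]:
            raise ValueError(f"{nm} node {p} lies in an unsampled region")

    best = {start: (vals[start], vals[start])}
    pred = {start: None}
    heap = [(vals[start], vals[start], start)]
    visited = set()
    while heap:
        fmax, fcum, node = heapq.heappop(heap)
        if node in visited:
            continue
        visited.add(node)
        if node == end:
            break
        for nb in _neighbors(shape, node):
            if not mask[nb] or nb in visited:
                continue
            cand = (max(fmax, vals[nb]), fcum + vals[nb])
            if nb not in best or cand < best[nb]:
                best[nb] = cand
                pred[nb] = node
                heapq.heappush(heap, (*cand, nb))
    if end not in visited:
        raise ValueError("no connected sampled path between start and end")

    nodes = [end]
    while pred[nodes[-1]] is not None:
        nodes.append(pred[nodes[-1]])
    nodes.reverse()
    profile = np.array([vals[n] for n in nodes])
    return PathResult(nodes=nodes, barrier=float(profile.max()),
                      profile=profile)
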