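"""Desk-scale sampling engine: Langevin dynamics on toy potentials,
well-tempered metadynamics, parallel tempering, the well-tempered-ensemble
(WTE) pre-stage and steered (moving-restraint) runs.

The sampler stands in for the MD package of a production study.  Toy
potentials are defined directly in CV space, so the integrated coordinates
*are* the collective variables.  Units: nm, ps, kJ/mol, K; masses are 1
throughout (the toys carry no physical inertia scale).

Well-tempered hill schedule: a Gaussian of height

    W = W0 * exp(-V(s, t) / ((f - 1) kB T))

is deposited every ``stride`` ps, where V(s, t) is the bias already
present at the deposition point and f > 1 the bias factor.  Replica
exchange uses the bias-including Metropolis criterion

    Δ = (β_i − β_j)(U(x_i) − U(x_j)) + β_i[V_i(s_i) − V_i(s_j)]
                                     + β_j[V_j(s_j) − V_j(s_i)]

with acceptance min(1, e^Δ); on acceptance coordinates swap between the
rungs (velocities rescaled by sqrt(T_new/T_old)) while bias ledgers stay
with their temperature rung.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .grids import GridAxis, GridBias, default_grid_axes
from .potentials import ToyPotential
from .trajectory import Trajectory

__all__ = [
    "MetaDParams", "Hill", "HillsLedger", "ReplicaLadder", "WTEParams",
    "Replica", "LangevinState", "WTEResult",
    "hill_height", "bias_energy", "langevin_step", "run_wt_metad",
    "pt_exchange", "wte_prestage", "steered_run",
    "ParallelTempering", "DEFAULT_LADDER",
]

#: Production replica-temperature ladder (K).
DEFAULT_LADDER = (300.0, 305.0, 310.0, 318.0, 326.0, 335.0,
                  344.0, 354.0, 363.0, 375.0, 382.0)


@dataclass
class MetaDParams:
    """Well-tempered metadynamics parameters.

    ``w0`` initial hill height (kJ/mol), ``bias_factor`` f (dimensionless),
    ``stride`` deposition period (ps), ``widths`` per-CV Gaussian sigma
    (CV units; if None a heuristic of one third of the unbiased CV standard
    deviation from a short pre-run is used), ``grid`` optional bias grid.
    """

    w0: float = 4.0
    bias_factor: float = 15.0
    stride: float = 1.0
    widths: np.ndarray | None = None
    grid: list[GridAxis] | None = None

    def __post_init__(self):
        if self.w0 <= 0:
            raise ValueError("initial hill height W0 must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.stride <= 0:
            raise ValueError("deposition stride must be positive")
        if self.widths is not None:
            self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
            if np.any(self.widths <= 0):
                raise ValueError("hill widths must be positive")


@dataclass(frozen=True)
class Hill:
    time: float
    center: np.ndarray
    sigma: np.ndarray
    height: float

    def __post_init__(self):
        object.__setattr__(self, "center",
                           np.atleast_1d(np.asarray(self.center, dtype=float)))
        object.__setattr__(self, "sigma",
                           np.atleast_1d(np.asarray(self.sigma, dtype=float)))
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("hill widths must be positive")


class HillsLedger:
    """Time-ordered record of deposited Gaussians."""

    def __init__(self, hills=None, params: MetaDParams | None = None,
                 temperature: float = 300.0, cv_names: list[str] | None = None):
        self.params = params
        self.temperature = temperature
        self.hills: list[Hill] = []
        self.cv_names = list(cv_names) if cv_names else None
        for h in hills or []:
            self.append(h)

    def append(self, hill: Hill) -> None:
        if self.hills:
            if hill.time <= self.hills[-1].time:
                raise ValueError("hill times must be strictly increasing")
            if hill.center.size != self.dim:
                raise ValueError("inconsistent CV dimensionality in ledger")
        if self.params is not None and hill.height > self.params.w0 + 1e-12:
            raise ValueError("hill height exceeds W0")
        self.hills.append(hill)
        if self.cv_names is None:
            self.cv_names = [f"cv{i+1}" for i in range(hill.center.size)]

    def __len__(self) -> int:
        return len(self.hills)

    @property
    def dim(self) -> int:
        if self.hills:
            return self.hills[0].center.size
        return len(self.cv_names) if self.cv_names else 0

    @property
    def times(self) -> np.ndarray:
        return np.array([h.time for h in self.hills])

    @property
    def centers(self) -> np.ndarray:
        return np.array([h.center for h in self.hills]).reshape(len(self), self.dim)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([h.sigma for h in self.hills]).reshape(len(self), self.dim)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h.height for h in self.hills])

    @property
    def span(self) -> float:
        return self.times[-1] - self.times[0] if self.hills else 0.0

    def subset(self, t_max: float) -> "HillsLedger":
        """Hills deposited up to and including time ``t_max``."""
        out = HillsLedger(params=self.params, temperature=self.temperature,
                          cv_names=self.cv_names)
        out.hills = [h for h in self.hills if h.time <= t_max]
        return out

    def bias_at(self, points: np.ndarray) -> np.ndarray:
        """Direct Gaussian-summation bias V(s) at points of shape (n, d)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.dim and self.hills:
            raise ValueError("point dimensionality does not match ledger")
        if not self.hills:
            return np.zeros(points.shape[0])
        c = self.centers
        s = self.sigmas
        h = self.heights
        out = np.zeros(points.shape[0])
        chunk = max(1, int(2e6 / max(len(self), 1)))
        for i in range(0, points.shape[0], chunk):
            p = points[i:i + chunk]
            arg = np.sum(((p[:, None, :] - c[None, :, :]) / s[None, :, :]) ** 2,
                         axis=-1)
            out[i:i + chunk] = np.exp(-0.5 * arg) @ h
        return out


@dataclass
class ReplicaLadder:
    """Replica temperatures (K) and the exchange-attempt period (ps)."""

    temperatures: tuple = DEFAULT_LADDER
    exchange_period: float = 2.0

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2:
            raise ValueError("ladder needs at least 2 rungs for exchanges")
        if np.any(np.diff(t) < 0):
            raise ValueError("ladder temperatures must be non-decreasing")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive")
        if self.exchange_period <= 0:
            raise ValueError("exchange period must be positive")
        self.temperatures = tuple(float(x) for x in t)

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class WTEParams:
    """Well-tempered-ensemble pre-stage parameters.

    Potential-energy hills of height ``energy_hill_height`` (kJ/mol) and
    width ``energy_sigma`` (kJ/mol) are deposited every ``stride`` ps per
    replica until the moving-average adjacent-pair exchange acceptance over
    the last ``window`` attempts reaches ``target_rate``.
    """

    energy_hill_height: float = 1.0
    energy_sigma: float = 100.0
    target_rate: float = 0.15
    stride: float = 1.0
    window: int = 100
    min_attempts: int = 50
    max_hills_per_replica: int = 5000
    energy_grid: tuple = (-500.0, 1500.0, 512)

    def __post_init__(self):
        if self.energy_hill_height <= 0 or self.energy_sigma <= 0:
            raise ValueError("WTE hill height and width must be positive")
        if not 0 < self.target_rate < 1:
            raise ValueError("target exchange rate must lie in (0, 1)")


def hill_height(v_at_s: float, params: MetaDParams, temperature: float) -> float:
    """Well-tempered hill height W0·exp(−V/((f−1)·kB·T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return params.w0 * math.exp(-max(v_at_s, 0.0)
                                / ((params.bias_factor - 1.0) * KB * temperature))


def bias_energy(s, ledger: HillsLedger) -> float:
    """Bias potential V(s) as the direct sum over deposited Gaussians."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if ledger.hills and s.size != ledger.dim:
        raise ValueError("CV dimensionality does not match ledger")
    return float(ledger.bias_at(s[None, :])[0])


@dataclass
class LangevinState:
    x: np.ndarray
    v: np.ndarray
    force: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))


def _total_force(x, potential: ToyPotential, bias=None):
    f = -potential.gradient(x)
    if bias is not None:
        f = f - bias.grad(x)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError(f"non-finite force at x={x}")
    return f


def langevin_step(state: LangevinState, potential: ToyPotential,
                  temperature: float, friction: float, dt: float,
                  rng: np.random.Generator | None, bias=None) -> LangevinState:
    """One BAOAB Langevin update (unit mass).

    ``rng=None`` disables the thermal noise (the O-substep becomes pure
    velocity damping), which makes the update fully deterministic.
    """
    if dt <= 0 or friction <= 0:
        raise ValueError("dt and friction must be positive")
    x, v = state.x.copy(), state.v.copy()
    f = state.force if state.force is not None else _total_force(x, potential, bias)
    v = v + 0.5 * dt * f
    x = x + 0.5 * dt * v
    c1 = math.exp(-friction * dt)
    if rng is not None:
        c2 = math.sqrt((1.0 - c1 * c1) * KB * temperature)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    else:
        v = c1 * v
    x = x + 0.5 * dt * v
    f = _total_force(x, potential, bias)
    v = v + 0.5 * dt * f
    return LangevinState(x, v, force=f)


def _default_widths(potential: ToyPotential, temperature: float, dt: float,
                    friction: float, seed: int, n_pre: int = 2000) -> np.ndarray:
    """Heuristic hill widths: one third of the unbiased CV std-dev."""
    rng = np.random.default_rng(seed)
    lo, hi = potential.domain
    x = 0.5 * (np.atleast_1d(lo) + np.atleast_1d(hi))
    state = LangevinState(x, np.zeros_like(x))
    samples = np.empty((n_pre, potential.dim))
    for i in range(n_pre):
        state = langevin_step(state, potential, temperature, friction, dt, rng)
        samples[i] = state.x
    return np.maximum(samples.std(axis=0) / 3.0, 1e-3)


def run_wt_metad(potential: ToyPotential, metad: MetaDParams,
                 temperature: float = 300.0, n_steps: int = 100_000,
                 seed: int = 0, dt: float = 0.01, friction: float = 2.0,
                 x0=None, record_every: int = 10
                 ) -> tuple[Trajectory, HillsLedger]:
    """Well-tempered metadynamics on a toy potential.

    Hills are deposited every ``metad.stride`` ps with the well-tempered
    height schedule evaluated at the current CV position; the trajectory
    records CV values, the instantaneous bias and the temperature.  The
    run is bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    axes = metad.grid or default_grid_axes(potential.domain, n=256)
    widths = metad.widths
    if widths is None:
        widths = _default_widths(potential, temperature, dt, friction, seed + 1)
    widths = np.broadcast_to(np.atleast_1d(widths), (potential.dim,)).astype(float)

    bias = GridBias(axes)
    ledger = HillsLedger(params=metad, temperature=temperature,
                         cv_names=[ax.name for ax in axes])
    if x0 is None:
        lo, _ = potential.domain
        x0 = np.atleast_1d(lo) * 0.5
    state = LangevinState(np.atleast_1d(np.asarray(x0, dtype=float)),
                          np.zeros(potential.dim))

    stride_steps = max(1, int(round(metad.stride / dt)))
    n_rec = n_steps // record_every
    times = np.empty(n_rec)
    cvs = np.empty((n_rec, potential.dim))
    biases = np.empty(n_rec)
    irec = 0

    for step in range(1, n_steps + 1):
        state = langevin_step(state, potential, temperature, friction, dt,
                              rng, bias=bias)
        t = step * dt
        if step % stride_steps == 0:
            v_here = float(bias.value(state.x))
            w = hill_height(v_here, metad, temperature)
            hill = Hill(time=t, center=state.x.copy(), sigma=widths, height=w)
            ledger.append(hill)
            bias.add_hill(hill.center, hill.sigma, hill.height)
            # the cached force predates this hill; refresh it
            state.force = None
            state = LangevinState(state.x, state.v)
        if step % record_every == 0 and irec < n_rec:
            times[irec] = t
            cvs[irec] = state.x
            biases[irec] = float(bias.value(state.x))
            irec += 1

    traj = Trajectory(times=times[:irec], cvs=cvs[:irec], bias=biases[:irec],
                      temperature=temperature,
                      cv_names=[ax.name for ax in axes])
    return traj, ledger


# ---------------------------------------------------------------------------
# Replica exchange


@dataclass
class Replica:
    """One rung of a parallel-tempering simulation."""

    temperature: float
    x: np.ndarray
    v: np.ndarray
    potential: ToyPotential
    cv_bias: object | None = None       # has .value(x) in kJ/mol
    energy_bias: object | None = None   # has .value(E) in kJ/mol

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def bias_value(self, x) -> float:
        v = 0.0
        if self.cv_bias is not None:
            v += float(self.cv_bias.value(x))
        if self.energy_bias is not None:
            v += float(self.energy_bias.value(float(self.potential.energy(x))))
        return v


def exchange_log_weight(beta_i, beta_j, u_i, u_j, vi_si, vi_sj, vj_si, vj_sj):
    """Log acceptance weight Δ of the bias-including exchange criterion.

    Detailed balance against the biased stationary densities
    exp(−β_r (U + V_r)) gives

        Δ = (β_i − β_j)(U(x_i) − U(x_j))
            + β_i [V_i(s_i) − V_i(s_j)] + β_j [V_j(s_j) − V_j(s_i)]

    so that handing the lower-energy configuration to the colder rung is
    always favourable.
    """
    return ((beta_i - beta_j) * (u_i - u_j)
            + beta_i * (vi_si - vi_sj) + beta_j * (vj_sj - vj_si))


def pt_exchange(rep_i: Replica, rep_j: Replica,
                rng: np.random.Generator) -> bool:
    """Attempt a coordinate swap between two replicas (Metropolis).

    On acceptance the coordinates are exchanged (velocities rescaled to
    the receiving temperature) while each bias stays with its rung.
    """
    if rep_i.x.size != rep_j.x.size:
        raise ValueError("replicas have mismatched CV dimensionality")
    beta_i = 1.0 / (KB * rep_i.temperature)
    beta_j = 1.0 / (KB * rep_j.temperature)
    u_i = float(rep_i.potential.energy(rep_i.x))
    u_j = float(rep_j.potential.energy(rep_j.x))
    delta = exchange_log_weight(
        beta_i, beta_j, u_i, u_j,
        rep_i.bias_value(rep_i.x), rep_i.bias_value(rep_j.x),
        rep_j.bias_value(rep_i.x), rep_j.bias_value(rep_j.x))
    accepted = delta >= 0 or rng.random() < math.exp(delta)
    if accepted:
        scale_i = math.sqrt(rep_i.temperature / rep_j.temperature)
        rep_i.x, rep_j.x = rep_j.x, rep_i.x
        rep_i.v, rep_j.v = rep_j.v * scale_i, rep_i.v / scale_i
    return accepted


class _ReplicaEnergyBias:
    """Per-replica bias on the potential-energy CV, tabulated on a shared
    energy axis for vectorised evaluation across the ladder."""

    def __init__(self, n_replicas: int, grid: tuple):
        lo, hi, n = grid
        self.energies = np.linspace(lo, hi, int(n))
        self.de = self.energies[1] - self.energies[0]
        self.tables = np.zeros((n_replicas, int(n)))
        self.dtables = np.zeros((n_replicas, int(n)))

    def add_hill(self, replica: int, center: float, sigma: float,
                 height: float) -> None:
        dx = self.energies - center
        g = height * np.exp(-0.5 * (dx / sigma) ** 2)
        self.tables[replica] += g
        self.dtables[replica] += g * (-dx / sigma ** 2)

    def _interp(self, tables, energies):
        u = (np.asarray(energies, dtype=float) - self.energies[0]) / self.de
        u = np.clip(u, 0.0, len(self.energies) - 1 - 1e-12)
        i = np.floor(u).astype(int)
        f = u - i
        rows = np.arange(tables.shape[0])
        return tables[rows, i] * (1 - f) + tables[rows, i + 1] * f

    def value_all(self, energies):
        """V_r(E_r) for every replica r (vectorised)."""
        return self._interp(self.tables, energies)

    def deriv_all(self, energies):
        return self._interp(self.dtables, energies)

    def cross_value(self, replica: int, energy: float) -> float:
        """V_replica evaluated at an arbitrary energy (for exchanges)."""
        u = (energy - self.energies[0]) / self.de
        u = min(max(u, 0.0), len(self.energies) - 1 - 1e-12)
        i = int(u)
        f = u - i
        t = self.tables[replica]
        return float(t[i] * (1 - f) + t[i + 1] * f)

    def single(self, replica: int):
        """View of one replica's energy bias with a scalar .value(E)."""
        parent = self

        class _View:
            def value(self, energy):
                return parent.cross_value(replica, float(energy))

        return _View()


@dataclass
class WTEResult:
    ledgers: list            # per-replica HillsLedger on the energy CV
    achieved_rate: float
    energy_bias: _ReplicaEnergyBias
    n_attempts: int


class ParallelTempering:
    """Vectorised parallel-tempering engine over a temperature ladder.

    Supports plain PT, PT with per-replica well-tempered metadynamics on
    the CVs, an active WTE stage depositing potential-energy hills, and
    production runs with a frozen energy bias carried over from the
    pre-stage.  Adjacent pairs are attempted with alternating even/odd
    parity every ``ladder.exchange_period`` ps.
    """

    def __init__(self, potential: ToyPotential, ladder: ReplicaLadder,
                 seed: int = 0, dt: float = 0.02, friction: float = 2.0,
                 x0=None, metad: MetaDParams | None = None,
                 wte: WTEParams | None = None,
                 energy_bias: _ReplicaEnergyBias | None = None,
                 record_every: int = 10, record_rungs=(0,)):
        self.potential = potential
        self.ladder = ladder
        self.temps = np.asarray(ladder.temperatures, dtype=float)
        self.n_rep = len(self.temps)
        self.dt = dt
        self.friction = friction
        self.rng = np.random.default_rng(seed)
        if x0 is None:
            lo, _ = potential.domain
            x0 = np.tile(np.atleast_1d(lo) * 0.5, (self.n_rep, 1))
        self.x = np.array(x0, dtype=float).reshape(self.n_rep, potential.dim)
        self.v = np.zeros_like(self.x)

        self.metad = metad
        self.cv_biases = None
        self.cv_ledgers = None
        self.widths = None
        if metad is not None:
            axes = metad.grid or default_grid_axes(potential.domain, n=128)
            self.cv_biases = [GridBias(axes) for _ in range(self.n_rep)]
            self.cv_ledgers = [
                HillsLedger(params=metad, temperature=float(t),
                            cv_names=[ax.name for ax in axes])
                for t in self.temps]
            w = metad.widths
            if w is None:
                w = _default_widths(potential, float(self.temps[0]), dt,
                                    friction, seed + 101)
            self.widths = np.broadcast_to(np.atleast_1d(w),
                                          (potential.dim,)).astype(float)

        self.wte = wte
        self.energy_bias = energy_bias
        self.wte_ledgers = None
        if wte is not None:
            if self.energy_bias is None:
                self.energy_bias = _ReplicaEnergyBias(self.n_rep,
                                                      wte.energy_grid)
            self.wte_ledgers = [
                HillsLedger(temperature=float(t), cv_names=["energy"])
                for t in self.temps]

        self.record_every = record_every
        self.record_rungs = tuple(record_rungs)
        self._records = {r: {"t": [], "x": [], "bias": []}
                         for r in self.record_rungs}

        self.time = 0.0
        self.step_count = 0
        self._parity = 0
        self.pair_attempts = np.zeros(self.n_rep - 1, dtype=int)
        self.pair_accepts = np.zeros(self.n_rep - 1, dtype=int)
        self.recent_outcomes: list[bool] = []

        self._c1 = math.exp(-friction * dt)
        self._noise = np.sqrt((1.0 - self._c1 ** 2) * KB * self.temps)[:, None]
        self._force = self._forces()

    # -- dynamics ----------------------------------------------------------

    def _forces(self):
        f = -self.potential.gradient(self.x)
        if self.energy_bias is not None:
            e = self.potential.energy(self.x)
            scale = 1.0 + self.energy_bias.deriv_all(e)
            f = f * scale[:, None]
        if self.cv_biases is not None:
            for r in range(self.n_rep):
                f[r] -= self.cv_biases[r].grad(self.x[r])
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("non-finite force in replica ensemble")
        return f

    def _md_step(self):
        self.v += 0.5 * self.dt * self._force
        self.x += 0.5 * self.dt * self.v
        self.v = self._c1 * self.v + self._noise * self.rng.standard_normal(
            self.v.shape)
        self.x += 0.5 * self.dt * self.v
        self._force = self._forces()
        self.v += 0.5 * self.dt * self._force
        self.time += self.dt
        self.step_count += 1

    def _deposit_cv_hills(self):
        for r in range(self.n_rep):
            v_here = float(self.cv_biases[r].value(self.x[r]))
            w = hill_height(v_here, self.metad, float(self.temps[r]))
            hill = Hill(time=self.time, center=self.x[r].copy(),
                        sigma=self.widths, height=w)
            self.cv_ledgers[r].append(hill)
            self.cv_biases[r].add_hill(hill.center, hill.sigma, hill.height)
        self._force = self._forces()

    def _deposit_energy_hills(self):
        e = self.potential.energy(self.x)
        for r in range(self.n_rep):
            self.energy_bias.add_hill(r, float(e[r]), self.wte.energy_sigma,
                                      self.wte.energy_hill_height)
            self.wte_ledgers[r].append(Hill(
                time=self.time, center=np.array([e[r]]),
                sigma=np.array([self.wte.energy_sigma]),
                height=self.wte.energy_hill_height))
        self._force = self._forces()

    # -- exchanges ---------------------------------------------------------

    def _bias_cross(self, rung: int, x, energy: float) -> float:
        v = 0.0
        if self.cv_biases is not None:
            v += float(self.cv_biases[rung].value(x))
        if self.energy_bias is not None:
            v += self.energy_bias.cross_value(rung, energy)
        return v

    def attempt_exchanges(self):
        """One round of adjacent-pair attempts at the current parity."""
        u = self.potential.energy(self.x)
        pairs = range(self._parity, self.n_rep - 1, 2)
        for i in pairs:
            j = i + 1
            beta_i = 1.0 / (KB * self.temps[i])
            beta_j = 1.0 / (KB * self.temps[j])
            delta = exchange_log_weight(
                beta_i, beta_j, float(u[i]), float(u[j]),
                self._bias_cross(i, self.x[i], float(u[i])),
                self._bias_cross(i, self.x[j], float(u[j])),
                self._bias_cross(j, self.x[i], float(u[i])),
                self._bias_cross(j, self.x[j], float(u[j])))
            accepted = delta >= 0 or self.rng.random() < math.exp(delta)
            self.pair_attempts[i] += 1
            self.recent_outcomes.append(accepted)
            if accepted:
                self.pair_accepts[i] += 1
                scale = math.sqrt(self.temps[i] / self.temps[j])
                self.x[[i, j]] = self.x[[j, i]]
                self.v[[i, j]] = np.stack([self.v[j] * scale,
                                           self.v[i] / scale])
                u[[i, j]] = u[[j, i]]
        self._parity = 1 - self._parity
        self._force = self._forces()

    def recent_rate(self, window: int = 100) -> float:
        """Moving-average acceptance over the last ``window`` attempts."""
        if not self.recent_outcomes:
            return 0.0
        tail = self.recent_outcomes[-window:]
        return float(np.mean(tail))

    def mean_pair_rate(self) -> float:
        """Mean acceptance rate across adjacent pairs (each pair weighted
        equally)."""
        with np.errstate(invalid="ignore"):
            rates = self.pair_accepts / np.maximum(self.pair_attempts, 1)
        return float(np.mean(rates[self.pair_attempts > 0]))

    def reset_exchange_stats(self):
        self.pair_attempts[:] = 0
        self.pair_accepts[:] = 0
        self.recent_outcomes = []

    # -- driver ------------------------------------------------------------

    def run(self, n_steps: int):
        """Advance all replicas by ``n_steps`` integrator steps."""
        exch_steps = max(1, int(round(self.ladder.exchange_period / self.dt)))
        cv_stride = (max(1, int(round(self.metad.stride / self.dt)))
                     if self.metad is not None else None)
        wte_stride = (max(1, int(round(self.wte.stride / self.dt)))
                      if self.wte is not None else None)
        for _ in range(n_steps):
            self._md_step()
            s = self.step_count
            if cv_stride and s % cv_stride == 0:
                self._deposit_cv_hills()
            if wte_stride and s % wte_stride == 0:
                self._deposit_energy_hills()
            if s % exch_steps == 0:
                self.attempt_exchanges()
            if s % self.record_every == 0:
                for r in self.record_rungs:
                    rec = self._records[r]
                    rec["t"].append(self.time)
                    rec["x"].append(self.x[r].copy())
                    rec["bias"].append(
                        self._bias_cross(r, self.x[r],
                                         float(self.potential.energy(self.x[r])))
                        if (self.cv_biases or self.energy_bias) else 0.0)

    def trajectory(self, rung: int = 0) -> Trajectory:
        rec = self._records[rung]
        names = (self.cv_ledgers[rung].cv_names if self.cv_ledgers
                 else [f"cv{i+1}" for i in range(self.potential.dim)])
        return Trajectory(times=np.array(rec["t"]),
                          cvs=np.array(rec["x"]).reshape(len(rec["t"]), -1),
                          bias=np.array(rec["bias"]),
                          temperature=float(self.temps[rung]),
                          cv_names=names)


def wte_prestage(ladder: ReplicaLadder, potential: ToyPotential,
                 wte: WTEParams, seed: int = 0, dt: float = 0.02,
                 friction: float = 2.0, x0=None) -> WTEResult:
    """Run the well-tempered-ensemble pre-stage until the exchange target.

    Potential-energy hills (width ``wte.energy_sigma``, default 100 kJ/mol)
    are deposited per replica; after every exchange round the moving
    average of the last ``wte.window`` attempted exchanges is compared to
    ``wte.target_rate`` (default 15%).  On success the energy bias is
    frozen and returned so production runs can load it as initial bias.
    """
    pt = ParallelTempering(potential, ladder, seed=seed, dt=dt,
                           friction=friction, x0=x0, wte=wte)
    exch_steps = max(1, int(round(ladder.exchange_period / dt)))
    while True:
        pt.run(exch_steps)
        rate = pt.recent_rate(wte.window)
        if (len(pt.recent_outcomes) >= wte.min_attempts
                and rate >= wte.target_rate):
            return WTEResult(ledgers=pt.wte_ledgers, achieved_rate=rate,
                             energy_bias=pt.energy_bias,
                             n_attempts=int(pt.pair_attempts.sum()))
        if len(pt.wte_ledgers[0]) >= wte.max_hills_per_replica:
            raise RuntimeError(
                "WTE pre-stage failed to reach the target exchange rate "
                f"({wte.target_rate:.0%}) within the hill budget; "
                f"achieved {rate:.1%}")


def steered_run(potential: ToyPotential, start, target_cv, n_steps: int,
                spring_k: float = 1e4, temperature: float = 300.0,
                dt: float = 0.01, friction: float = 2.0, seed: int = 0,
                record_every: int = 10) -> Trajectory:
    """Steer the system along a linearly moving harmonic restraint.

    The restraint centre interpolates from ``start`` to ``target_cv`` over
    ``n_steps``; the trajectory's ``aux`` carries the per-frame restraint
    centre and the distance to the target (the toy analogue of monitoring
    the RMSD to the target conformation during steered MD).
    """
    if spring_k <= 0:
        raise ValueError("spring constant must be positive")
    start = np.atleast_1d(np.asarray(start, dtype=float))
    target = np.atleast_1d(np.asarray(target_cv, dtype=float))
    if n_steps <= 0:
        if not np.allclose(start, target):
            raise ValueError("zero-step schedule with distinct start/target")
        n_steps = 1
    rng = np.random.default_rng(seed)
    x = start.copy()
    v = np.zeros_like(x)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * KB * temperature)

    def force(x, center):
        return -potential.gradient(x) - spring_k * (x - center)

    f = force(x, start)
    times, cvs, centers, dists = [], [], [], []
    for step in range(1, n_steps + 1):
        center = start + (target - start) * (step / n_steps)
        v = v + 0.5 * dt * f
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v
        f = force(x, center)
        v = v + 0.5 * dt * f
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            cvs.append(x.copy())
            centers.append(center.copy())
            dists.append(float(np.linalg.norm(x - target)))
    return Trajectory(times=np.array(times), cvs=np.array(cvs),
                      temperature=temperature,
                      aux={"restraint_center": np.array(centers),
                           "dist_to_target": np.array(dists)})
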