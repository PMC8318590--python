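"""Analytic toy potentials standing in for the all-atom energy landscape.

Each potential provides vectorised ``energy`` (kJ/mol) and ``gradient``
(kJ/mol/nm) over points of shape (..., dim), plus a rectangular ``domain``
used for quadrature oracles and default bias grids.  Toy sampling is run
directly in CV space: the coordinates *are* the collective variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ToyPotential", "make_potential", "MUELLER_BROWN_MINIMA"]


@dataclass
class ToyPotential:
    name: str
    dim: int
    params: dict
    _energy: callable = field(repr=False)
    _gradient: callable = field(repr=False)
    domain: tuple = None  # ((lo...), (hi...)) in nm

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self._energy(np.atleast_1d(x))

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self._gradient(np.atleast_1d(x))


def _harmonic(params):
    k = np.atleast_1d(np.asarray(params.get("k", 100.0), dtype=float))
    x0 = np.atleast_1d(np.asarray(params.get("x0", 0.0), dtype=float))
    dim = max(k.size, x0.size)
    k = np.broadcast_to(k, (dim,))
    x0 = np.broadcast_to(x0, (dim,))

    def energy(x):
        return 0.5 * np.sum(k * (x - x0) ** 2, axis=-1)

    def grad(x):
        return k * (x - x0)

    lo = x0 - 5.0 * np.sqrt(10.0 / k)
    hi = x0 + 5.0 * np.sqrt(10.0 / k)
    return dim, energy, grad, (lo, hi)


def _double_well_1d(params):
    """U(x) = h ((x/a)² − 1)² + (ε/2)(x/a): wells near ±a, barrier ≈ h,
    right well raised by ≈ ε relative to the left."""
    h = float(params.get("barrier", 10.0))
    a = float(params.get("half_separation", 0.5))
    tilt = float(params.get("tilt", 0.0))

    def energy(x):
        u = x[..., 0] / a
        return h * (u * u - 1.0) ** 2 + 0.5 * tilt * u

    def grad(x):
        u = x[..., 0] / a
        g = (4.0 * h * u * (u * u - 1.0) + 0.5 * tilt) / a
        return g[..., None]

    lo = np.array([-2.0 * a])
    hi = np.array([2.0 * a])
    return 1, energy, grad, (lo, hi)


def _double_well_2d(params):
    """Separable 2D double well: the 1D form along x plus a harmonic y."""
    h = float(params.get("barrier", 10.0))
    a = float(params.get("half_separation", 0.5))
    tilt = float(params.get("tilt", 0.0))
    ky = float(params.get("ky", 50.0))

    def energy(x):
        u = x[..., 0] / a
        return h * (u * u - 1.0) ** 2 + 0.5 * tilt * u + 0.5 * ky * x[..., 1] ** 2

    def grad(x):
        u = x[..., 0] / a
        gx = (4.0 * h * u * (u * u - 1.0) + 0.5 * tilt) / a
        gy = ky * x[..., 1]
        return np.stack([gx, gy], axis=-1)

    lo = np.array([-2.0 * a, -5.0 * np.sqrt(10.0 / ky)])
    hi = np.array([2.0 * a, 5.0 * np.sqrt(10.0 / ky)])
    return 2, energy, grad, (lo, hi)


# Classic Müller–Brown parameters; three minima, two saddles.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])

#: Known minima of the (unscaled) Müller–Brown surface.
MUELLER_BROWN_MINIMA = np.array([
    [-0.5582, 1.4417],
    [0.6235, 0.0280],
    [-0.0500, 0.4667],
])


def _mueller_brown(params):
    scale = float(params.get("scale", 1.0))

    def energy(x):
        xx = x[..., 0, None] - _MB_x0
        yy = x[..., 1, None] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * xx ** 2 + _MB_b * xx * yy + _MB_c * yy ** 2)
        return scale * np.sum(terms, axis=-1)

    def grad(x):
        xx = x[..., 0, None] - _MB_x0
        yy = x[..., 1, None] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * xx ** 2 + _MB_b * xx * yy + _MB_c * yy ** 2)
        gx = np.sum(terms * (2.0 * _MB_a * xx + _MB_b * yy), axis=-1)
        gy = np.sum(terms * (_MB_b * xx + 2.0 * _MB_c * yy), axis=-1)
        return scale * np.stack([gx, gy], axis=-1)

    lo = np.array([-1.5, -0.5])
    hi = np.array([1.2, 2.0])
    return 2, energy, grad, (lo, hi)


_FACTORIES = {
    "harmonic": _harmonic,
    "double_well_1d": _double_well_1d,
    "double_well_2d": _double_well_2d,
    "mueller_brown": _mueller_brown,
}


def make_potential(name: str, **params) -> ToyPotential:
    """Instantiate a named toy potential with keyword parameters."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown potential {name!r}; choose from {sorted(_FACTORIES)}"
        ) from None
    dim, energy, grad, domain = factory(params)
    return ToyPotential(name=name, dim=dim, params=dict(params),
                        _energy=energy, _gradient=grad, domain=domain)
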