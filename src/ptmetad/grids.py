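"""Regular CV grids and grid-accumulated bias potentials.

``GridBias`` accumulates deposited Gaussians (values and analytic
gradients) on a regular 1D/2D grid so that the bias force costs O(1) per
integrator step instead of O(n_hills).  Hills are separable Gaussians, so
each deposition is an outer product of per-axis profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridAxis", "GridBias", "default_grid_axes"]


@dataclass(frozen=True)
class GridAxis:
    name: str
    lo: float
    hi: float
    n: int

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError(f"axis {self.name}: upper bound must exceed lower")
        if self.n < 2:
            raise ValueError(f"axis {self.name}: need at least 2 nodes")

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)


def default_grid_axes(domain, names=None, n: int = 128) -> list[GridAxis]:
    """Grid axes spanning a potential's rectangular domain."""
    lo, hi = domain
    lo = np.atleast_1d(lo)
    hi = np.atleast_1d(hi)
    names = names or [f"cv{i+1}" for i in range(lo.size)]
    return [GridAxis(names[i], float(lo[i]), float(hi[i]), n)
            for i in range(lo.size)]


class GridBias:
    """Bias potential V(s) accumulated on a regular grid (1D or 2D).

    Evaluation between nodes uses multilinear interpolation of the value
    and of the analytically accumulated gradient; points outside the grid
    are clamped to the boundary (the bias is flat there).
    """

    def __init__(self, axes: list[GridAxis]):
        if len(axes) not in (1, 2):
            raise ValueError("GridBias supports 1 or 2 CV axes")
        self.axes = list(axes)
        self.dim = len(axes)
        self._nodes = [ax.nodes for ax in axes]
        shape = tuple(ax.n for ax in axes)
        self.values = np.zeros(shape)
        self.grads = [np.zeros(shape) for _ in axes]

    def add_hill(self, center, sigma, height: float) -> None:
        center = np.atleast_1d(np.asarray(center, dtype=float))
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        profs, dprofs = [], []
        for k in range(self.dim):
            dx = self._nodes[k] - center[k]
            g = np.exp(-0.5 * (dx / sigma[k]) ** 2)
            profs.append(g)
            dprofs.append(g * (-dx / sigma[k] ** 2))
        if self.dim == 1:
            self.values += height * profs[0]
            self.grads[0] += height * dprofs[0]
        else:
            self.values += height * np.outer(profs[0], profs[1])
            self.grads[0] += height * np.outer(dprofs[0], profs[1])
            self.grads[1] += height * np.outer(profs[0], dprofs[1])

    def _locate(self, x):
        x = np.asarray(x, dtype=float)
        idx, frac = [], []
        for k, ax in enumerate(self.axes):
            u = (x[..., k] - ax.lo) / ax.spacing
            u = np.clip(u, 0.0, ax.n - 1 - 1e-12)
            i = np.floor(u).astype(int)
            idx.append(i)
            frac.append(u - i)
        return idx, frac

    def _interp(self, arr, idx, frac):
        if self.dim == 1:
            i, f = idx[0], frac[0]
            return arr[i] * (1 - f) + arr[i + 1] * f
        i, j = idx
        fx, fy = frac
        return (arr[i, j] * (1 - fx) * (1 - fy)
                + arr[i + 1, j] * fx * (1 - fy)
                + arr[i, j + 1] * (1 - fx) * fy
                + arr[i + 1, j + 1] * fx * fy)

    def value(self, x):
        """Bias V(s) at point(s) ``x`` of shape (..., dim)."""
        idx, frac = self._locate(x)
        return self._interp(self.values, idx, frac)

    def grad(self, x):
        """Bias gradient at point(s) ``x``; shape (..., dim)."""
        idx, frac = self._locate(x)
        return np.stack([self._interp(g, idx, frac) for g in self.grads],
                        axis=-1)
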