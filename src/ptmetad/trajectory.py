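"""Trajectory container: CV time series with bias, temperature and
optionally full coordinate frames."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "count_well_transitions"]


@dataclass
class Trajectory:
    """Frame sequence of CV values.

    ``cvs`` has shape (n_frames, n_cvs); ``bias`` is the instantaneous
    metadynamics bias V(s_i, t_i) in kJ/mol (zeros for unbiased runs);
    ``temperature`` is the thermostat temperature in K (scalar or
    per-frame); ``frames`` optionally holds full coordinate frames
    (Structure objects) aligned with the CV rows.
    """

    times: np.ndarray                 # ps
    cvs: np.ndarray                   # (n, d)
    bias: np.ndarray = None           # kJ/mol
    temperature: float | np.ndarray = 300.0
    cv_names: list[str] = field(default_factory=list)
    frames: list = None
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cvs = np.atleast_2d(np.asarray(self.cvs, dtype=float))
        if self.cvs.shape[0] != self.times.shape[0]:
            self.cvs = self.cvs.T
        if self.cvs.shape[0] != self.times.shape[0]:
            raise ValueError("times and cvs lengths differ")
        if self.bias is None:
            self.bias = np.zeros(len(self.times))
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.shape != self.times.shape:
            raise ValueError("bias length must match times")
        if not self.cv_names:
            self.cv_names = [f"cv{i+1}" for i in range(self.cvs.shape[1])]

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_cvs(self) -> int:
        return self.cvs.shape[1]

    def cv(self, name: str) -> np.ndarray:
        return self.cvs[:, self.cv_names.index(name)]


def count_well_transitions(series: np.ndarray, lo: float, hi: float) -> int:
    """Count crossings between the regions below ``lo`` and above ``hi``.

    Frames in the intermediate band are ignored (hysteresis), so thermal
    jitter around a single threshold is not counted as transitions.
    """
    series = np.asarray(series, dtype=float)
    state = np.where(series <= lo, -1, np.where(series >= hi, 1, 0))
    state = state[state != 0]
    if state.size < 2:
        return 0
    return int(np.sum(state[1:] != state[:-1]))
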