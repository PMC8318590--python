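"""Pipeline configuration: YAML in, validated defaults out.

The defaults mirror the production protocol of the kinase study: the
11-rung 300–382 K ladder, W0 = 4 kJ/mol, bias factor 15, 1 ps hill
stride, 2 ps exchange period, 100 kJ/mol energy-hill width with a 15%
exchange-rate target, 0.2 nm clustering cutoff and the 2.5 kcal/mol
convergence threshold — so an empty config runs a protocol-default toy
pipeline end to end.  Every injected default is logged.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "validate_config", "DEFAULTS", "ALL_STAGES"]

SCHEMA_ID = "ptmetad-config-1"

ALL_STAGES = ["fixtures", "contacts", "cvs", "sampling", "fes",
              "minima", "mep", "clustering", "report"]

DEFAULTS: dict = {
    "schema": SCHEMA_ID,
    "seed": 0,
    "output_dir": "results/pipeline",
    "stages": list(ALL_STAGES),
    "structures": {"active": None, "inactive": None,
                   "numbering_offset": 24},
    "fixtures": {"n_residues": 140, "n_active_contacts": 5,
                 "n_inactive_contacts": 5, "n_salt_bridges": 2,
                 "trajectory": {"n_frames": 60, "switch_times": [30],
                                "noise_sigma": 0.02}},
    "contacts": {"formed_cutoff": 0.45, "broken_cutoff": 0.80},
    "cv": {"variant": "rational", "form": "normalized_rms"},
    "sampler": {
        "potential": {"name": "double_well_2d", "barrier": 12.0,
                      "half_separation": 0.5, "tilt": 4.0, "ky": 50.0},
        "ladder": [300, 305, 310, 318, 326, 335, 344, 354, 363, 375, 382],
        "exchange_period": 2.0,
        "inactive_start_fraction": 3 / 11,
        "metad": {"w0": 4.0, "bias_factor": 15.0, "stride": 1.0,
                  "widths": None},
        "wte": {"energy_hill_height": 1.0, "energy_sigma": 100.0,
                "target_rate": 0.15, "min_attempts": 50},
        "dt": 0.02, "friction": 2.0, "n_steps": 25000,
    },
    "fes": {"grid_nodes": 96, "min_depth": 0.3,
            "convergence": {"window": 100000.0, "threshold": 2.5}},
    "clustering": {"cutoff": 0.2},
}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    data: dict
    injected_defaults: list[str] = field(default_factory=list)

    def __getitem__(self, key):
        return self.data[key]

    def hash(self) -> str:
        """Stable hash of the full configuration for provenance records."""
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merge(defaults, given, path, log):
    if not isinstance(given, dict):
        return copy.deepcopy(given)
    out = {}
    for key, dval in defaults.items():
        if key not in given:
            out[key] = copy.deepcopy(dval)
            log.append(f"{path}{key} = {dval!r} (default)")
        elif isinstance(dval, dict):
            out[key] = _merge(dval, given[key], f"{path}{key}.", log)
        else:
            out[key] = copy.deepcopy(given[key])
    for key in given:
        if key not in defaults:
            raise ValueError(f"unknown configuration key {path}{key!r}")
    return out


def validate_config(raw) -> PipelineConfig:
    """Parse YAML text (or a dict) into a validated configuration.

    Missing keys are filled from the production-protocol defaults and logged;
    out-of-range parameters raise with an explanatory message.
    """
    if isinstance(raw, str):
        given = yaml.safe_load(raw) or {}
    else:
        given = dict(raw or {})
    if not isinstance(given, dict):
        raise ValueError("configuration must be a mapping")

    log: list[str] = []
    data = _merge(DEFAULTS, given, "", log)

    stages = data["stages"]
    if not stages:
        raise ValueError("no stages requested")
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {ALL_STAGES}")

    metad = data["sampler"]["metad"]
    if metad["bias_factor"] <= 1:
        raise ValueError("bias factor must exceed 1")
    if metad["w0"] <= 0:
        raise ValueError("initial hill height W0 must be positive")
    if metad["stride"] <= 0:
        raise ValueError("hill stride must be positive")

    ladder = data["sampler"]["ladder"]
    if len(ladder) < 2:
        raise ValueError("replica ladder needs at least two temperatures "
                         "for exchanges")
    if any(t2 < t1 for t1, t2 in zip(ladder, ladder[1:])):
        raise ValueError("ladder temperatures must be non-decreasing")

    wte = data["sampler"]["wte"]
    if not 0 < wte["target_rate"] < 1:
        raise ValueError("WTE target exchange rate must lie in (0, 1)")

    contacts = data["contacts"]
    if not contacts["formed_cutoff"] < contacts["broken_cutoff"]:
        raise ValueError("formed cutoff must be below broken cutoff")

    if data["clustering"]["cutoff"] <= 0:
        raise ValueError("clustering cutoff must be positive")
    if data["sampler"]["dt"] <= 0 or data["sampler"]["friction"] <= 0:
        raise ValueError("dt and friction must be positive")

    for key in ("active", "inactive"):
        p = data["structures"][key]
        if p is not None:
            import os
            if not os.path.exists(p):
                raise ValueError(f"structure path does not exist: {p}")

    return PipelineConfig(data=data, injected_defaults=log)
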