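"""Run configuration: YAML/dict parsing, validation, defaults.

A :class:`RunConfig` bundles everything a run needs — geometry, transport,
source (either a direct volumetric rate ``k`` or a mean ion release rate to
be converted through the transmissive-zone volume), pulse schedule, uptake,
solver controls, probe radii and the seed.  Every run echoes its effective
configuration into the output metadata so results are reproducible from
the artefacts alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from . import budget as _budget
from .params import (
    BufferModel,
    ParameterError,
    PulseSchedule,
    SourceSpec,
    SynapseGeometry,
    TransportParams,
    UptakeModel,
)

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

#: defaults follow the reference cleft: a 3 um synapse with a 500 nm
#: transmissive zone, 40 nm cleft height, a 3x-hindered diffusion
#: coefficient of 2e-10 m^2/s, 100 Hz / 5 ms pulsed release at p=0.5, and a
#: conservative mean release of 1400 ions/s (28 ions x 50 expected fusions).
DEFAULTS: dict = {
    "geometry": {"R": 500e-9, "S": 3e-6, "h": 40e-9},
    "transport": {"D": 2e-10, "buffer": {"c_B": 0.0, "k_on": 0.0, "k_off": 1.0}},
    "source": {"mean_ion_rate": 1400.0},
    "schedule": {
        "frequency": 100.0, "pulse_duration": 5e-3, "train_duration": 1.0,
        "release_probability": 0.5, "mode": "expected",
    },
    "uptake": {"J_max": 3e-6, "K_m": 1e-2, "enabled": False},
    "solver": {"n_cells": 150, "dt": None, "t_end": 0.08, "save_every": 200},
    "probes": [100e-9, 1e-6],
    "baseline": 0.0,
    "seed": 0,
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ParameterError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


@dataclass(frozen=True)
class RunConfig:
    geometry: SynapseGeometry
    transport: TransportParams
    source: SourceSpec
    schedule: PulseSchedule
    uptake: UptakeModel
    n_cells: int
    dt: float | None
    t_end: float
    save_every: int
    probes: tuple
    baseline: float
    seed: int
    raw: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_dict(cls, data: dict | None = None) -> "RunConfig":
        """Build a validated config from a (possibly partial) dict.

        Unknown keys are rejected; missing keys take the documented
        defaults.  The source may be given as ``{"k": ...}`` (mol/(m^3 s))
        or ``{"mean_ion_rate": ...}`` (ions/s, converted through pi R^2 h).
        """
        data = dict(data or {})
        src_in = data.get("source")
        if src_in is not None:
            if not isinstance(src_in, dict) or not (
                    set(src_in) <= {"k", "mean_ion_rate"}) or len(src_in) != 1:
                raise ParameterError(
                    "source must specify exactly one of 'k' or 'mean_ion_rate'")
            data = {**data, "source": src_in}
        merged = _merge({**DEFAULTS, "source": {"k": None, "mean_ion_rate": None}},
                        data)
        if src_in is None:
            merged["source"] = dict(DEFAULTS["source"])

        geom = SynapseGeometry(**merged["geometry"])
        buf = BufferModel(**merged["transport"]["buffer"])
        transport = TransportParams(D=merged["transport"]["D"], buffer=buf)
        src = merged["source"]
        if src.get("k") is not None:
            source = SourceSpec(k=float(src["k"]))
        else:
            source = SourceSpec(k=_budget.source_rate_from_budget(
                float(src["mean_ion_rate"]), geom))
        sched_kw = dict(merged["schedule"])
        seed = int(merged["seed"])
        if sched_kw.get("mode") == "stochastic":
            sched_kw.setdefault("seed", seed)
        schedule = PulseSchedule(**sched_kw)
        uptake = UptakeModel(**merged["uptake"])
        solver = merged["solver"]
        return cls(
            geometry=geom, transport=transport, source=source,
            schedule=schedule, uptake=uptake,
            n_cells=int(solver["n_cells"]),
            dt=None if solver["dt"] is None else float(solver["dt"]),
            t_end=float(solver["t_end"]),
            save_every=int(solver["save_every"]),
            probes=tuple(float(r) for r in merged["probes"]),
            baseline=float(merged["baseline"]),
            seed=seed,
            raw=merged,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path!r} must contain a mapping")
        return cls.from_dict(data)

    def echo(self) -> dict:
        """Effective configuration for output metadata (JSON-serialisable)."""
        return {
            "geometry": {"R": self.geometry.R, "S": self.geometry.S, "h": self.geometry.h},
            "transport": {"D": self.transport.D, "D_eff": self.transport.D_eff,
                          "buffer_G": self.transport.buffer.G},
            "source_k": self.source.k,
            "schedule": {
                "frequency": self.schedule.frequency,
                "pulse_duration": self.schedule.pulse_duration,
                "train_duration": self.schedule.train_duration,
                "release_probability": self.schedule.release_probability,
                "mode": self.schedule.mode,
            },
            "uptake": {"J_max": self.uptake.J_max, "K_m": self.uptake.K_m,
                       "enabled": self.uptake.enabled},
            "solver": {"n_cells": self.n_cells, "dt": self.dt,
                       "t_end": self.t_end, "save_every": self.save_every},
            "probes": list(self.probes),
            "baseline": self.baseline,
            "seed": self.seed,
        }


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (optional) and apply override values on top."""
    base = {}
    if path is not None:
        with open(path) as fh:
            base = yaml.safe_load(fh) or {}
    if overrides:
        base = _deep_update(base, overrides)
    return RunConfig.from_dict(base)


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out
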