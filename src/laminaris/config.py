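"""Configuration files and result writers.

A run configuration is a nested key/value document (YAML) with blocks

.. code-block:: yaml

    variant: one_comp_active_if
    soma:       {c_soma: 24.0, g_leak: 48.0, g_klva: 192.0, ...}
    node:       {c_node: 0.2, g_leak: 2.0, g_axon: 117.8}     # two-comp only
    generator:  {i_const: 200.0, a1: 3500.0, ..., v_theta: -58.3, t_ref: 0.9}
    kinetics:   {q10: 2.5, t_rec: 23.0, t_sim: 40.0, speedup: true}
    input:      {f_stim: 4000.0, lambda0: 500.0, r: 0.6, m: 150, ...}
    integration: {dt_us: 10.0, duration_ms: 1000.0, warmup_ms: 20.0}
    seed: 0

Every field is optional; an empty document yields the published default
parameter tables for the chosen variant (default: the single-compartment
active model).  Unknown keys are rejected with their location rather than
silently ignored.  Units: mV, ms, nS, pF, pA, with the integration step
given in microseconds for readability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inputs import InputParams
from .kinetics import KLVAKinetics
from .model import ModelSpec, NodeParams, SomaParams, SpikeGenerator

__all__ = [
    "IntegrationParams",
    "RunConfig",
    "load_config",
    "config_to_dict",
    "write_config",
    "write_trace",
    "write_spike_times",
    "write_trains",
    "read_trains",
    "write_conductance",
    "read_conductance",
    "write_results",
]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass(frozen=True)
class IntegrationParams:
    dt_us: float = 10.0
    duration_ms: float = 1000.0
    warmup_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.dt_us <= 0 or self.duration_ms <= 0 or self.warmup_ms < 0:
            raise ConfigError("integration parameters must be positive")

    @property
    def dt_ms(self) -> float:
        return self.dt_us * 1e-3


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved run configuration: model, input, integration, seed."""

    spec: ModelSpec
    input: InputParams = field(default_factory=InputParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    seed: int = 0


def _build(cls, block: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in block '{where}'")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid block '{where}': {exc}") from exc


def config_from_dict(doc: dict | None) -> RunConfig:
    """Build a :class:`RunConfig` from a nested dict (schema-checked)."""
    doc = dict(doc or {})
    known = {"variant", "soma", "node", "generator", "kinetics",
             "input", "integration", "seed"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    variant = doc.get("variant", "one_comp_active_if")
    try:
        base = ModelSpec.default(variant)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    soma = _build(SomaParams, {**dataclasses.asdict(base.soma), **doc.get("soma", {})},
                  "soma")
    if "node" in doc and base.node is None:
        raise ConfigError("block 'node' only applies to the two-compartment variant")
    node = (_build(NodeParams, {**dataclasses.asdict(base.node), **doc.get("node", {})},
                   "node") if base.node is not None else None)
    if "generator" in doc and base.gen is None:
        raise ConfigError("block 'generator' does not apply to the non-spiking variant")
    gen = (_build(SpikeGenerator,
                  {**dataclasses.asdict(base.gen), **doc.get("generator", {})},
                  "generator") if base.gen is not None else None)
    if "kinetics" in doc and not base.has_klva and variant == "one_comp_passive_if":
        raise ConfigError("block 'kinetics' does not apply to the passive variant")
    kin = _build(KLVAKinetics,
                 {**dataclasses.asdict(base.kinetics), **doc.get("kinetics", {})},
                 "kinetics")
    try:
        spec = ModelSpec(variant, soma, node, gen, kin)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    inp = _build(InputParams, doc.get("input", {}), "input")
    integ = _build(IntegrationParams, doc.get("integration", {}), "integration")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    return RunConfig(spec=spec, input=inp, integration=integ, seed=seed)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(doc)


def config_to_dict(cfg: RunConfig) -> dict:
    """Fully-resolved nested dict (inverse of :func:`config_from_dict`)."""
    doc: dict = {"variant": cfg.spec.variant,
                 "soma": dataclasses.asdict(cfg.spec.soma)}
    if cfg.spec.node is not None:
        doc["node"] = dataclasses.asdict(cfg.spec.node)
    if cfg.spec.gen is not None:
        doc["generator"] = dataclasses.asdict(cfg.spec.gen)
    if cfg.spec.variant != "one_comp_passive_if":
        doc["kinetics"] = dataclasses.asdict(cfg.spec.kinetics)
    doc["input"] = dataclasses.asdict(cfg.input)
    doc["integration"] = dataclasses.asdict(cfg.integration)
    doc["seed"] = cfg.seed
    return doc


def write_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
    return path


def write_trace(result, path: str | Path, g_syn=None) -> Path:
    """Write a voltage trace as CSV ``time_ms,V_soma_mV[,V_node_mV][,d][,g_syn_nS]``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_ms": result.times, "V_soma_mV": result.v_soma}
    if result.v_node is not None:
        cols["V_node_mV"] = result.v_node
    if result.d is not None:
        cols["d"] = result.d
    if g_syn is not None:
        vals = getattr(g_syn, "values", g_syn)
        cols["g_syn_nS"] = np.asarray(vals)[: len(result.v_soma)]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    return path


def write_spike_times(times_ms: np.ndarray, path: str | Path) -> Path:
    """One event time (ms, 6 decimals) per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for t in np.asarray(times_ms, dtype=float):
            fh.write(f"{t:.6f}\n")
    return path


def write_trains(trains, path: str | Path) -> Path:
    """Write spike trains as a two-column ``fiber_id,time_ms`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [(tr.fiber_id, t) for tr in trains for t in tr.times]
    frame = pd.DataFrame(rows, columns=["fiber_id", "time_ms"])
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_trains(path: str | Path, duration: float):
    """Read spike trains written by :func:`write_trains`."""
    from .inputs import SpikeTrain

    frame = pd.read_csv(path)
    return [
        SpikeTrain(times=np.sort(group["time_ms"].to_numpy()), duration=duration,
                   fiber_id=int(fid))
        for fid, group in frame.groupby("fiber_id")
    ]


def write_conductance(trace, path: str | Path) -> Path:
    """Write a conductance trace as ``time_ms,g_nS`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": trace.times, "g_nS": trace.values}).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_conductance(path: str | Path):
    """Read a conductance trace written by :func:`write_conductance`."""
    from .inputs import ConductanceTrace

    frame = pd.read_csv(path)
    t = frame["time_ms"].to_numpy()
    dt = float(t[1] - t[0])
    return ConductanceTrace(dt=dt, values=frame["g_nS"].to_numpy())


def write_results(
    out_dir: str | Path,
    cfg: RunConfig,
    tables: dict[str, pd.DataFrame] | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write result tables plus the resolved config and a run manifest.

    Every output directory is self-describing: the resolved configuration and
    the manifest (seed, protocol summary) suffice to regenerate its files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["config"] = write_config(cfg, out_dir / "config.yaml")
    for name, frame in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p
    if manifest is not None:
        p = out_dir / "manifest.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        paths["manifest"] = p
    return paths
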