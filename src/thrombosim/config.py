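"""Run configuration: a single YAML file in SI units.

An empty file (or missing sections) resolves to the reference 2D setup:
a 150 x 50 µm channel at 1 µm resolution, pressure-gradient driving with
delta_p = 30 Pa, and the torch-regime growth coefficients (lambda = 3 µm,
k_adh = 8e-11 m, k_rol = 7e-5, c_b = 0.9, a 15 µm mid-wall injury).
Unknown keys and invariant violations are rejected with the offending key
path.

Coordinate convention: origin at the inlet/bottom-wall corner, x along
the flow, y across; cell centers at ((i+0.5) dx, (j+0.5) dy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from thrombosim.core_1d import AdsorptionParams1D, Grid1D
from thrombosim.flow_2d import ChannelGrid2D, FlowBC, FluidParams
from thrombosim.thrombus_2d import InjurySpec, ThrombusParams

__all__ = ["NumericsConfig", "OutputConfig", "SimulationConfig", "load_config"]


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and solver controls."""

    dt: float | None = None  # explicit step, s (None = stability bound)
    safety: float = 0.5  # CFL safety factor
    t_end: float = 50.0  # simulated horizon, s
    record_every: float | None = None  # snapshot cadence, s
    solver_mode: str = "stokes"  # steady-flow solver: stokes | march
    coupling_mode: str = "quasi_steady"  # quasi_steady | explicit
    n_refresh: int = 100  # max concentration steps between flow refreshes
    shear_mode: str = "strain"  # gamma definition: strain | dudy
    tol: float = 1e-10  # steady-flow convergence tolerance

    def __post_init__(self) -> None:
        if self.dt is not None and not self.dt > 0:
            raise ValueError("numerics.dt must be > 0")
        if not (0 < self.safety <= 1):
            raise ValueError("numerics.safety must lie in (0, 1]")
        if not self.t_end >= 0:
            raise ValueError("numerics.t_end must be >= 0")
        if self.solver_mode not in ("stokes", "march"):
            raise ValueError("numerics.solver_mode must be stokes or march")
        if self.coupling_mode not in ("quasi_steady", "explicit"):
            raise ValueError(
                "numerics.coupling_mode must be quasi_steady or explicit"
            )
        if self.n_refresh < 1:
            raise ValueError("numerics.n_refresh must be >= 1")


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "runs"
    formats: tuple[str, ...] = ("csv",)

    def __post_init__(self) -> None:
        for f in self.formats:
            if f not in ("csv", "vtk"):
                raise ValueError(f"output.formats: unknown format {f!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """All physical and numerical parameters of a run."""

    model_1d: AdsorptionParams1D = field(default_factory=AdsorptionParams1D)
    grid_1d: Grid1D = field(default_factory=lambda: Grid1D(1e-4, 200))
    thrombus: ThrombusParams = field(default_factory=ThrombusParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    flow_bc: FlowBC = field(default_factory=FlowBC)
    injury: InjurySpec = field(default_factory=InjurySpec)
    grid: ChannelGrid2D = field(default_factory=ChannelGrid2D)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        def conv(obj):
            d = {}
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                d[f.name] = list(v) if isinstance(v, tuple) else v
            return d

        return {name: conv(getattr(self, name)) for name in _SECTIONS}


_SECTIONS = {
    "model_1d": AdsorptionParams1D,
    "grid_1d": Grid1D,
    "thrombus": ThrombusParams,
    "fluid": FluidParams,
    "flow_bc": FlowBC,
    "injury": InjurySpec,
    "grid": ChannelGrid2D,
    "numerics": NumericsConfig,
    "output": OutputConfig,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown config key: {name}.{key}")
    kwargs = dict(data)
    if name == "output" and "formats" in kwargs:
        kwargs["formats"] = tuple(kwargs["formats"])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config section {name!r}: {exc}") from exc


def config_from_dict(data: dict | None) -> SimulationConfig:
    """Validated configuration from a nested dict; omitted fields take the
    reference defaults."""
    data = data or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section: {sorted(unknown)[0]}")
    sections = {
        name: _build_section(name, cls, data.get(name, {}) or {})
        for name, cls in _SECTIONS.items()
    }
    return SimulationConfig(**sections)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the full reference default setup.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def set_dotted(data: dict, key: str, raw: str) -> None:
    """Apply a ``section.field=value`` CLI override to a config dict."""
    parts = key.split(".")
    if len(parts) != 2:
        raise ValueError(f"override key must be section.field, got {key!r}")
    section, fname = parts
    value = yaml.safe_load(raw)
    if isinstance(value, str):
        # YAML 1.1 misses dot-less scientific notation ("5e-07")
        try:
            value = float(value)
        except ValueError:
            pass
    data.setdefault(section, {})[fname] = value
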