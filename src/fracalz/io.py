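"""Trajectory CSV dialect, run configuration, and JSON reports.

The trajectory dialect is a plain comma-separated file with header
exactly ``time,F_N,I_N,A_beta,T_mu,M_rho`` (plus ``z1,z2`` when the
trajectory carries controls), one row per grid node, values rendered
with 17 significant digits so the round-trip is bit-lossless for
double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .glsolver import SolverGrid, Trajectory
from .model import STATE_NAMES, ModelParameters, get_preset

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "load_config",
    "write_json_report",
]

_BASE_HEADER = ("time",) + STATE_NAMES
_CTRL_HEADER = _BASE_HEADER + ("z1", "z2")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a 5-state trajectory in the standard CSV dialect."""
    if traj.states.shape[1] != 5:
        raise ValueError("CSV dialect requires exactly the 5 model states")
    cols = [traj.times] + [traj.states[:, i] for i in range(5)]
    header = _BASE_HEADER
    if traj.controls is not None:
        cols += [traj.controls[:, 0], traj.controls[:, 1]]
        header = _CTRL_HEADER
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in data:
            fh.write(",".join(f"{x:.17g}" for x in row) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    The header is validated strictly; a shuffled or renamed column is
    a format error naming the offending column.
    """
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split(","))
        if header not in (_BASE_HEADER, _CTRL_HEADER):
            expect = _CTRL_HEADER if len(header) == 8 else _BASE_HEADER
            for got, want in zip(header, expect):
                if got != want:
                    raise ValueError(f"trajectory header mismatch: got {got!r}, expected {want!r}")
            raise ValueError(f"trajectory header mismatch: {header!r}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    times = data[:, 0]
    n_steps = times.size - 1
    if n_steps < 1:
        raise ValueError("trajectory must have at least two nodes")
    grid = SolverGrid(float(times[-1]), n_steps)
    if not np.allclose(times, grid.times, rtol=0, atol=1e-9 * max(1.0, times[-1])):
        raise ValueError("trajectory time column is not a uniform grid starting at 0")
    controls = data[:, 6:8] if len(header) == 8 else None
    return Trajectory(grid, data[:, 1:6], controls)


@dataclass
class RunConfig:
    """Structured run configuration (serializable snapshot).

    Either ``preset`` or explicit ``params`` must be given; explicit
    entries override preset values field-by-field.
    """

    preset: str | None = "table1"
    params: dict = field(default_factory=dict)
    initial_state: list | None = None
    sigma: float = 0.9
    horizon: float = 200.0
    n_steps: int = 2000
    seed: int = 0
    output_dir: str = "."
    pinn: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)

    def resolve(self) -> tuple[ModelParameters, np.ndarray, SolverGrid]:
        if self.preset is not None:
            base, state0 = get_preset(self.preset)
        else:
            base, state0 = ModelParameters(), np.zeros(5)
        params = base.with_updates(**self.params) if self.params else base
        if self.initial_state is not None:
            state0 = np.asarray(self.initial_state, dtype=float)
            if state0.shape != (5,):
                raise ValueError("initial_state must have 5 entries")
        return params, state0, SolverGrid(self.horizon, self.n_steps)

    def as_dict(self) -> dict:
        return {
            "preset": self.preset,
            "params": dict(self.params),
            "initial_state": None if self.initial_state is None else list(map(float, self.initial_state)),
            "sigma": self.sigma,
            "horizon": self.horizon,
            "n_steps": self.n_steps,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "pinn": dict(self.pinn),
            "control": dict(self.control),
            "sensitivity": dict(self.sensitivity),
        }

    def write_snapshot(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML run configuration and apply flag overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _jsonable(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type) and not isinstance(obj, Trajectory):
        if hasattr(obj, "as_dict"):
            return _jsonable(obj.as_dict())
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return [(float(z.real), float(z.imag)) for z in obj.ravel()]
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, complex):
        return (obj.real, obj.imag)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    if isinstance(obj, Trajectory):
        return {"n_nodes": obj.grid.n_nodes, "horizon": obj.grid.horizon}
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis/benchmark report to JSON (matrices
    row-major, eigenvalues as (re, im) pairs)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")
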