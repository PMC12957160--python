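"""Seeded synthetic-data generator.

Produces the reference bundles every other module trains or tests on:
clean GL-solved trajectories of the baseline disease scenario across
fractional orders and horizons, noisy copies at graded intensities,
and a tiny linear-equation fixture whose Mittag-Leffler closed form is
known exactly.  Everything is deterministic given the seed; a manifest
records a checksum per file (computed on the decimal text, which is
rendered at 17 significant digits and therefore platform-stable).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .glsolver import SolverGrid, Trajectory, integrate_caputo_gl, mittag_leffler
from .io import write_trajectory
from .model import ModelParameters, get_preset
from .pinn import add_noise
from .simulate import simulate

__all__ = ["reference_trajectory", "linear_fixture", "generate_fixtures"]

REFERENCE_SIGMAS = (0.7, 0.8, 0.9, 1.0)
REFERENCE_HORIZONS = (200.0, 500.0)
NOISE_LEVELS = (0.0, 0.05, 0.10, 0.15, 0.20)


def reference_trajectory(
    preset: str = "table1",
    sigma: float = 0.9,
    horizon: float = 200.0,
    h: float = 0.5,
    method: str = "stable",
) -> Trajectory:
    """Clean GL reference trajectory for a named preset.

    The trajectory carries the generating :class:`ModelParameters` on
    its ``params`` attribute so downstream consumers (the PINN
    residual) use the exact same rates.
    """
    params, state0 = get_preset(preset)
    n_steps = int(round(horizon / h))
    traj = simulate(params, state0, sigma, SolverGrid(horizon, n_steps), method=method)
    traj.params = params
    return traj


def linear_fixture(sigma: float = 0.5, lam: float = 1.0, horizon: float = 1.0, n_steps: int = 10):
    """Tiny scalar fixture: D^sigma u = -lam*u, u0 = 1, 11 nodes.

    Returns ``(trajectory, closed_form)`` where the closed form is
    E_sigma(-lam * t^sigma) on the same nodes.
    """
    grid = SolverGrid(horizon, n_steps)
    traj = integrate_caputo_gl(lambda t, u: -lam * u, np.array([1.0]), sigma, grid)
    exact = mittag_leffler(sigma, -lam * grid.times**sigma)
    return traj, exact


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the full seeded fixture bundle and its manifest.

    Contents: clean references for sigma in {0.7, 0.8, 0.9, 1.0} and
    horizons {200, 500} days (h = 0.5); noisy copies of the sigma=0.9,
    T=200 reference at intensities {0, 0.05, 0.1, 0.15, 0.2}; and the
    11-node linear fixture with its Mittag-Leffler closed form.
    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "files": {}}

    for sigma in REFERENCE_SIGMAS:
        for horizon in REFERENCE_HORIZONS:
            traj = reference_trajectory("table1", sigma, horizon)
            name = f"reference_table1_sigma{sigma:g}_T{horizon:g}.csv"
            write_trajectory(traj, out / name)
            manifest["files"][name] = _checksum(out / name)

    base = reference_trajectory("table1", 0.9, 200.0)
    for i, level in enumerate(NOISE_LEVELS):
        noisy = add_noise(base, level, seed + i)
        name = f"noisy_table1_sigma0.9_T200_level{level:g}.csv"
        write_trajectory(noisy, out / name)
        manifest["files"][name] = _checksum(out / name)

    traj, exact = linear_fixture()
    rows = np.column_stack([traj.times, traj.states[:, 0], exact])
    lin = out / "linear_sigma0.5.csv"
    with open(lin, "w") as fh:
        fh.write("time,u_gl,u_exact\n")
        for row in rows:
            fh.write(",".join(f"{x:.17g}" for x in row) + "\n")
    manifest["files"][lin.name] = _checksum(lin)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
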