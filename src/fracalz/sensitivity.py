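"""Logarithmic (elasticity) sensitivity and perturbation sweeps.

The time-resolved elasticity of a model output y with respect to a
parameter p is estimated by the centered two-run formula

    S_log(t) = (ln y_+(t) - ln y_-(t)) / (2 * ln(1 + delta)),

where y_+/y_- are the outputs with p replaced by p*(1 + delta) and
p*(1 - delta), everything else held fixed.  For an output that is a
pure power law y = C * p^k the statistic returns exactly k (up to a
delta-dependent bias of order delta^2 when y is not a power law).
Nodes where either perturbed output is non-positive are masked as
undefined rather than silently zeroed — the logarithm does not exist
there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glsolver import SolverGrid, Trajectory
from .model import STATE_NAMES, ModelParameters
from .simulate import simulate

__all__ = ["SensitivityCurve", "elasticity_curve", "log_sensitivity", "parameter_sweep"]


@dataclass
class SensitivityCurve:
    """Elasticity S_log(t) of one output w.r.t. one parameter.

    ``values`` is a float array with NaN at undefined (non-positive
    output) nodes; ``defined`` marks the valid nodes.
    """

    parameter: str
    output: str
    delta: float
    grid: SolverGrid
    values: np.ndarray
    defined: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def max_abs(self) -> float:
        """max_t |S_log| over the defined nodes."""
        if not self.defined.any():
            raise ValueError("curve is undefined everywhere")
        return float(np.nanmax(np.abs(self.values)))


def elasticity_curve(y_plus: np.ndarray, y_minus: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered log-sensitivity from two perturbed output series.

    Returns ``(values, defined)``; values are NaN where either series
    is non-positive.
    """
    if not (0.0 < delta <= 0.5):
        raise ValueError("delta must lie in (0, 0.5]")
    y_plus = np.asarray(y_plus, dtype=float)
    y_minus = np.asarray(y_minus, dtype=float)
    defined = (y_plus > 0) & (y_minus > 0)
    values = np.full(y_plus.shape, np.nan)
    values[defined] = (np.log(y_plus[defined]) - np.log(y_minus[defined])) / (
        2.0 * np.log1p(delta)
    )
    return values, defined


def log_sensitivity(
    params: ModelParameters,
    state0: np.ndarray,
    sigma: float,
    grid: SolverGrid,
    parameter: str,
    output: str,
    delta: float = 0.1,
    method: str = "stable",
    initial_state_parameter: bool = False,
) -> SensitivityCurve:
    """Elasticity of one state series w.r.t. one parameter.

    Runs the GL solver twice, at p*(1+delta) and p*(1-delta).  With
    ``initial_state_parameter=True``, ``parameter`` names a state (one
    of F_N, I_N, A_beta, T_mu, M_rho) and the multiplicative
    perturbation applies to its initial value instead of a rate.
    """
    if output not in STATE_NAMES:
        raise ValueError(f"output must be one of {STATE_NAMES}")
    out_idx = STATE_NAMES.index(output)
    runs = []
    for sign in (+1.0, -1.0):
        factor = 1.0 + sign * delta
        if initial_state_parameter:
            if parameter not in STATE_NAMES:
                raise ValueError(f"initial-state parameter must be one of {STATE_NAMES}")
            s0 = np.asarray(state0, dtype=float).copy()
            s0[STATE_NAMES.index(parameter)] *= factor
            traj = simulate(params, s0, sigma, grid, method=method)
        else:
            if parameter not in ModelParameters.field_names():
                raise ValueError(f"unknown parameter {parameter!r}")
            perturbed = params.with_updates(**{parameter: getattr(params, parameter) * factor})
            traj = simulate(perturbed, state0, sigma, grid, method=method)
        runs.append(traj.states[:, out_idx])
    values, defined = elasticity_curve(runs[0], runs[1], delta)
    if not defined.any():
        raise ValueError(
            f"S_log({output}; {parameter}) undefined at every node (non-positive output)"
        )
    return SensitivityCurve(parameter, output, delta, grid, values, defined)


def parameter_sweep(
    params: ModelParameters,
    state0: np.ndarray,
    sigma: float,
    grid: SolverGrid,
    parameters: list[str],
    delta: float = 0.1,
    method: str = "stable",
) -> dict[str, dict[str, Trajectory]]:
    """(nominal, +delta, -delta) trajectories for each listed parameter.

    Returns ``{param: {"nominal": Trajectory, "plus": ..., "minus": ...}}``;
    each trajectory carries all five state series.
    """
    if not parameters:
        raise ValueError("parameter list must be nonempty")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    nominal = simulate(params, state0, sigma, grid, method=method)
    bundle: dict[str, dict[str, Trajectory]] = {}
    for name in parameters:
        if name not in ModelParameters.field_names():
            raise ValueError(f"unknown parameter {name!r}")
        runs = {"nominal": nominal.copy()}
        for tag, sign in (("plus", +1.0), ("minus", -1.0)):
            perturbed = params.with_updates(**{name: getattr(params, name) * (1.0 + sign * delta)})
            try:
                runs[tag] = simulate(perturbed, state0, sigma, grid, method=method)
            except Exception as exc:
                raise RuntimeError(f"sweep failed for parameter {name!r} ({tag})") from exc
        bundle[name] = runs
    return bundle
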