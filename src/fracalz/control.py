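"""Therapeutic-intervention scenarios for the fractional model.

Three strategies are compared on the same grid: no control, constant
control, and a time-varying control optimized directly.  The cost
functional is a quadratic-effort burden integral

    J = ∫ ( w_I*I_N + w_A*A_beta + w_T*T_mu + c1*z1^2 + c2*z2^2 ) dt,

evaluated by the trapezoid rule.  Because no canonical cost is
attached to this model in the literature, every weight is configurable
and the defaults below are documented as this package's own choice.

Optimization is direct: the controls are piecewise constant on a small
number of equal windows, squashed into [0, 1] through a logistic, and
the window values are optimized by Nelder-Mead from the best of a few
canonical starting schedules (including the all-zero and the constant
0.5 schedules, so the optimized cost can never exceed those).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .glsolver import SolverGrid, Trajectory
from .model import ModelParameters
from .simulate import simulate

__all__ = [
    "ControlSchedule",
    "ControlObjective",
    "simulate_with_control",
    "evaluate_objective",
    "optimize_control",
    "compare_strategies",
]


@dataclass
class ControlSchedule:
    """Per-node (z1, z2) series on a solver grid, each in [0, 1]."""

    grid: SolverGrid
    z1: np.ndarray
    z2: np.ndarray

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        for name, z in (("z1", self.z1), ("z2", self.z2)):
            if z.shape != (self.grid.n_nodes,):
                raise ValueError(f"{name} must have one value per grid node")
            if np.any((z < 0) | (z > 1)):
                raise ValueError(f"{name} must lie in [0, 1] at every node")

    @classmethod
    def constant(cls, grid: SolverGrid, z1: float, z2: float) -> "ControlSchedule":
        ones = np.ones(grid.n_nodes)
        return cls(grid, z1 * ones, z2 * ones)

    @classmethod
    def piecewise(cls, grid: SolverGrid, z1_windows: np.ndarray, z2_windows: np.ndarray) -> "ControlSchedule":
        """Piecewise-constant schedule from per-window values in [0, 1]."""
        z1_windows = np.asarray(z1_windows, dtype=float)
        z2_windows = np.asarray(z2_windows, dtype=float)
        n_win = z1_windows.size
        if z2_windows.size != n_win or n_win < 1:
            raise ValueError("window arrays must be nonempty and equal length")
        idx = np.minimum((grid.times / grid.horizon * n_win).astype(int), n_win - 1)
        return cls(grid, z1_windows[idx], z2_windows[idx])

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.z1, self.z2])


@dataclass(frozen=True)
class ControlObjective:
    """Weights of the burden + effort cost functional (all >= 0)."""

    w_I: float = 1.0
    w_A: float = 1.0
    w_T: float = 1.0
    c1: float = 0.01
    c2: float = 0.01

    def __post_init__(self) -> None:
        for name in ("w_I", "w_A", "w_T", "c1", "c2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_with_control(
    params: ModelParameters,
    state0: np.ndarray,
    sigma: float,
    grid: SolverGrid,
    schedule: ControlSchedule,
    method: str = "stable",
) -> Trajectory:
    """Integrate the controlled model with a per-node schedule."""
    if schedule.grid != grid:
        raise ValueError("schedule grid does not match solver grid")
    return simulate(params, state0, sigma, grid, controls=schedule.as_array(), method=method)


def evaluate_objective(traj: Trajectory, objective: ControlObjective) -> float:
    """Trapezoidal cost of a controlled trajectory."""
    if traj.controls is None:
        raise ValueError("trajectory carries no controls")
    s = traj.states
    z = traj.controls
    integrand = (
        objective.w_I * s[:, 1]
        + objective.w_A * s[:, 2]
        + objective.w_T * s[:, 3]
        + objective.c1 * z[:, 0] ** 2
        + objective.c2 * z[:, 1] ** 2
    )
    return float(np.trapezoid(integrand, traj.times))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def optimize_control(
    params: ModelParameters,
    state0: np.ndarray,
    sigma: float,
    grid: SolverGrid,
    objective: ControlObjective,
    basis_size: int = 10,
    seed: int = 0,
    iterations: int = 200,
    method: str = "stable",
) -> tuple[ControlSchedule, np.ndarray]:
    """Optimize a piecewise-constant control schedule.

    Window values live on a logit scale, so the [0, 1] bounds hold by
    construction.  The search starts from the best of the canonical
    schedules {all-0, all-0.5, all-1, and a seeded random draw} and
    runs Nelder-Mead on the window parameters; the returned cost
    history tracks the best-so-far (accepted) cost, which is
    non-increasing.  Returns ``(best_schedule, cost_history)``.
    """
    if basis_size < 1:
        raise ValueError("basis_size must be >= 1")
    rng = np.random.default_rng(seed)

    def cost_of(x: np.ndarray) -> float:
        win = _sigmoid(x.reshape(2, basis_size))
        sched = ControlSchedule.piecewise(grid, win[0], win[1])
        traj = simulate_with_control(params, state0, sigma, grid, sched, method)
        c = evaluate_objective(traj, objective)
        if not np.isfinite(c):
            raise ArithmeticError(f"non-finite cost for window values {win}")
        return c

    starts = [
        np.full(2 * basis_size, _logit(0.0)),
        np.full(2 * basis_size, _logit(0.5)),
        np.full(2 * basis_size, _logit(1.0)),
        rng.normal(scale=1.0, size=2 * basis_size),
    ]
    best_x = min(starts, key=cost_of)

    history: list[float] = [cost_of(best_x)]

    def track(x: np.ndarray) -> float:
        c = cost_of(x)
        history.append(min(c, history[-1]))
        return c

    res = minimize(
        track,
        best_x,
        method="Nelder-Mead",
        options={"maxiter": iterations, "xatol": 1e-4, "fatol": 1e-10},
    )
    x_final = res.x if cost_of(res.x) <= history[-1] else best_x
    if cost_of(x_final) > cost_of(best_x):
        x_final = best_x
    win = _sigmoid(x_final.reshape(2, basis_size))
    schedule = ControlSchedule.piecewise(grid, win[0], win[1])
    hist = np.minimum.accumulate(np.asarray(history))
    return schedule, hist


def compare_strategies(
    params: ModelParameters,
    state0: np.ndarray,
    sigma: float,
    grid: SolverGrid,
    objective: ControlObjective | None = None,
    constant_levels: tuple[float, float] = (0.5, 0.5),
    basis_size: int = 10,
    seed: int = 0,
    iterations: int = 200,
    method: str = "stable",
) -> dict:
    """Run none/constant/optimized control and report the comparison.

    The report maps each strategy to its trajectory, terminal
    functional-neuron level, burden integrals of I_N/A_beta/T_mu, and
    cost under ``objective``.
    """
    objective = objective or ControlObjective()
    report: dict = {"objective": objective, "strategies": {}}

    def burden(traj: Trajectory, col: int) -> float:
        return float(np.trapezoid(traj.states[:, col], traj.times))

    def entry(traj: Trajectory, cost: float | None) -> dict:
        return {
            "trajectory": traj,
            "terminal_F_N": float(traj.states[-1, 0]),
            "burden_I_N": burden(traj, 1),
            "burden_A_beta": burden(traj, 2),
            "burden_T_mu": burden(traj, 3),
            "cost": cost,
        }

    none_sched = ControlSchedule.constant(grid, 0.0, 0.0)
    traj_none = simulate_with_control(params, state0, sigma, grid, none_sched, method)
    report["strategies"]["none"] = entry(traj_none, evaluate_objective(traj_none, objective))

    const_sched = ControlSchedule.constant(grid, *constant_levels)
    traj_const = simulate_with_control(params, state0, sigma, grid, const_sched, method)
    report["strategies"]["constant"] = entry(traj_const, evaluate_objective(traj_const, objective))

    opt_sched, history = optimize_control(
        params, state0, sigma, grid, objective, basis_size, seed, iterations, method
    )
    traj_opt = simulate_with_control(params, state0, sigma, grid, opt_sched, method)
    report["strategies"]["optimized"] = entry(traj_opt, evaluate_objective(traj_opt, objective))
    report["optimizer_history"] = history
    return report
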