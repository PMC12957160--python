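"""Physics-informed neural networks with Grünwald-Letnikov residuals.

Three learning frameworks share one architecture — a fully connected
tanh network mapping normalized time t/T in [0, 1] to seven outputs
(the five model states followed by the two therapeutic controls,
squashed into [0, 1] by a logistic):

* the *fractional* PINN penalizes the residual of the Caputo system,
  with the fractional derivative discretized by the GL convolution
  (weights w_k(sigma), step h) on the collocation grid;
* the *integer* PINN is the identical construction with the derivative
  order forced to 1 (the GL weights collapse to a backward
  difference);
* the *baseline* network drops the physics term entirely
  (lambda_phys = 0) and fits the observations alone; its control
  outputs receive no gradient.

The total loss is  L = L_data + lambda_phys * L_phys,  where L_data is
the mean squared prediction-observation discrepancy over the data
nodes and L_phys the mean squared residual norm over the collocation
nodes (t_1..t_N; at t_0 the memory convolution is empty, so the
residual is not defined there).

No autodiff framework is used: the network is small and the gradient
of the GL convolution is itself a (transposed) convolution, so
backpropagation is written out analytically and driven by Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .glsolver import SolverGrid, Trajectory, gl_weights
from .model import (
    ModelParameters,
    controlled_rhs,
    rhs_jacobian_controls,
    rhs_jacobian_state,
)

__all__ = [
    "PINNConfig",
    "LossBreakdown",
    "TrainingResult",
    "NoiseBenchmarkResult",
    "MLP",
    "build_network",
    "fractional_residual",
    "total_loss",
    "add_noise",
    "train_variant",
    "noise_benchmark",
    "robustness_ratio",
]

VARIANTS = ("fractional", "integer", "baseline")


@dataclass(frozen=True)
class PINNConfig:
    """Training configuration shared by the three variants.

    ``sigma`` is the residual's fractional order (forced to 1 for the
    integer variant); ``data_stride`` subsamples the reference grid to
    form the data nodes (stride 1 uses every node, t = 0 included, so
    the initial condition is supervised softly).
    """

    sigma: float = 0.9
    hidden_layers: int = 4
    width: int = 64
    lambda_phys: float = 1.0
    learning_rate: float = 2e-3
    iterations: int = 2000
    seed: int = 0
    data_stride: int = 1
    use_controls: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError("sigma must lie in (0, 1]")
        if self.lambda_phys < 0:
            raise ValueError("lambda_phys must be >= 0")
        if self.hidden_layers < 1 or self.width < 1:
            raise ValueError("network must have at least one hidden unit")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.data_stride < 1:
            raise ValueError("data_stride must be >= 1")


@dataclass(frozen=True)
class LossBreakdown:
    """Loss components at one iterate; total = data + lambda*physics."""

    data_loss: float
    physics_loss: float
    lambda_phys: float
    total: float
    per_state_mse: np.ndarray

    @staticmethod
    def build(data_loss: float, physics_loss: float, lambda_phys: float,
              per_state_mse: np.ndarray) -> "LossBreakdown":
        return LossBreakdown(
            float(data_loss), float(physics_loss), float(lambda_phys),
            float(data_loss + lambda_phys * physics_loss),
            np.asarray(per_state_mse, dtype=float),
        )


@dataclass
class TrainingResult:
    """Outcome of one training run."""

    variant: str
    config: PINNConfig
    seed: int
    noise_level: float
    history: np.ndarray
    final: LossBreakdown
    predicted: Trajectory
    wall_time: float


@dataclass
class NoiseBenchmarkResult:
    """Aggregated loss statistics per variant and noise level.

    ``stats[variant][level]`` is a dict with mean/sd/min/max of the
    final total loss and the per-state MSE mean; ``ratios[variant]`` is
    the robustness ratio (mean loss at the highest level over mean
    loss at level 0).
    """

    levels: tuple[float, ...]
    replicates: int
    stats: dict
    ratios: dict
    seeds: dict
    failures: list


class MLP:
    """Small tanh multilayer perceptron with analytic backprop.

    Maps (n, 1) normalized times to (n, 7) raw outputs.  The state
    columns are scaled by ``state_scale`` on the way out; the control
    columns pass through a logistic.  Deterministic given ``seed``.
    """

    N_OUT = 7

    def __init__(self, config: PINNConfig, state_scale: np.ndarray | None = None):
        rng = np.random.default_rng(config.seed)
        sizes = [1] + [config.width] * config.hidden_layers + [self.N_OUT]
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.state_scale = (
            np.ones(5) if state_scale is None else np.asarray(state_scale, dtype=float)
        )
        if np.any(self.state_scale <= 0):
            raise ValueError("state_scale must be positive")

    # -- forward ---------------------------------------------------------
    def forward(self, t_norm: np.ndarray):
        """Return (states, controls, cache) at normalized times (n,)."""
        a = np.asarray(t_norm, dtype=float).reshape(-1, 1)
        cache = [a]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ W + b)
            cache.append(a)
        raw = a @ self.weights[-1] + self.biases[-1]
        states = raw[:, :5] * self.state_scale
        controls = expit(raw[:, 5:7])
        return states, controls, (cache, controls)

    def predict(self, t_norm: np.ndarray):
        states, controls, _ = self.forward(t_norm)
        return states, controls

    # -- backward --------------------------------------------------------
    def backward(self, cache, g_states: np.ndarray, g_controls: np.ndarray):
        """Gradients of all weights given dL/d(states), dL/d(controls)."""
        layers, controls = cache
        g_raw = np.empty((g_states.shape[0], self.N_OUT))
        g_raw[:, :5] = g_states * self.state_scale
        g_raw[:, 5:7] = g_controls * controls * (1.0 - controls)
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = g_raw
        gW[-1] = layers[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for li in range(len(self.weights) - 2, -1, -1):
            delta = (delta @ self.weights[li + 1].T) * (1.0 - layers[li + 1] ** 2)
            gW[li] = layers[li].T @ delta
            gb[li] = delta.sum(axis=0)
        return gW, gb


def build_network(config: PINNConfig, state_scale: np.ndarray | None = None) -> MLP:
    """Construct the (seeded, deterministic) shared architecture."""
    return MLP(config, state_scale)


def _gl_conv_matrix(sigma: float, n_steps: int) -> np.ndarray:
    """Lower-triangular Toeplitz W with W[i, j] = w_{i-j}, shape (n+1, n+1)."""
    w = gl_weights(sigma, n_steps)
    n = n_steps + 1
    W = np.zeros((n, n))
    idx = np.arange(n)
    for k in range(n):
        W[idx[k:], idx[: n - k]] = w[k]
    return W


def fractional_residual(
    predicted: Trajectory,
    params: ModelParameters,
    sigma: float,
    conv_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """GL residual of the predicted trajectory, shape (n_nodes, 5).

    Row n is  h^(-sigma) * sum_{k=0..n} w_k (u_{n-k} - u_0) - rhs(t_n, u_n);
    the controlled right-hand side is used when the trajectory carries
    controls.  Row 0 reduces to -rhs(t_0, u_0) (empty memory) and is
    excluded from the physics loss.  The grid must be uniform, which
    :class:`SolverGrid` guarantees.
    """
    U = predicted.states
    if U.shape[1] != 5:
        raise ValueError("fractional_residual expects 5 state columns")
    grid = predicted.grid
    W = _gl_conv_matrix(sigma, grid.n_steps) if conv_matrix is None else conv_matrix
    h_sig = grid.h**sigma
    V = U - U[0]
    deriv = (W @ V) / h_sig
    if predicted.controls is not None:
        z1, z2 = predicted.controls[:, 0], predicted.controls[:, 1]
    else:
        z1 = z2 = 0.0
    return deriv - controlled_rhs(U, params, z1, z2)


def total_loss(
    predictions: np.ndarray,
    observations: np.ndarray,
    residuals: np.ndarray,
    lambda_phys: float,
) -> LossBreakdown:
    """Combine data and physics losses (Eq. totals are plain MSEs).

    ``predictions`` and ``observations`` must be aligned arrays over
    the data nodes; ``residuals`` holds the residual rows over the
    collocation nodes.
    """
    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    if predictions.shape != observations.shape:
        raise ValueError(
            f"prediction grid {predictions.shape} does not match "
            f"observation grid {observations.shape}"
        )
    diff = predictions - observations
    data_loss = float(np.mean(np.sum(diff**2, axis=1)))
    residuals = np.asarray(residuals, dtype=float)
    physics_loss = float(np.mean(np.sum(residuals**2, axis=1))) if residuals.size else 0.0
    per_state = np.mean(diff**2, axis=0)
    return LossBreakdown.build(data_loss, physics_loss, lambda_phys, per_state)


def add_noise(traj: Trajectory, level: float, seed: int) -> Trajectory:
    """Additive Gaussian observation noise, per-state scaled.

    Each state series receives independent zero-mean noise with
    standard deviation ``level * max|series|`` (the per-variable
    maximum absolute value anchors the "intensity"); the clean
    trajectory is left untouched.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    noisy = traj.copy()
    if level == 0:
        return noisy
    rng = np.random.default_rng(seed)
    scales = level * np.max(np.abs(traj.states), axis=0)
    noisy.states = traj.states + rng.standard_normal(traj.states.shape) * scales
    return noisy


def _variant_config(variant: str, config: PINNConfig) -> PINNConfig:
    if variant == "fractional":
        return config
    if variant == "integer":
        return replace(config, sigma=1.0)
    if variant == "baseline":
        return replace(config, lambda_phys=0.0, use_controls=False)
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def train_variant(
    variant: str,
    config: PINNConfig,
    reference: Trajectory,
    noise_level: float = 0.0,
    seed: int | None = None,
) -> TrainingResult:
    """Train one variant on a (possibly noise-corrupted) GL reference.

    The reference trajectory defines both the collocation grid (every
    node) and, after subsampling by ``config.data_stride``, the data
    nodes.  Noise is injected into the observations only; the per-state
    MSE in the result is measured against the clean reference, so it
    reflects recovery of the true dynamics rather than fit to noise.
    """
    import time as _time

    cfg = _variant_config(variant, config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    grid = reference.grid
    t_norm = grid.times / grid.horizon
    data_idx = np.arange(0, grid.n_nodes, cfg.data_stride)
    observations = add_noise(reference, noise_level, cfg.seed + 1).states[data_idx]
    clean = reference.states

    # Per-state output scaling anchors the network's linear outputs to
    # the data's dynamic range (recorded on the network itself).
    scale = np.maximum(np.max(np.abs(observations), axis=0), 1e-8)
    net = build_network(cfg, state_scale=scale)

    use_phys = cfg.lambda_phys > 0.0
    W = _gl_conv_matrix(cfg.sigma, grid.n_steps) if use_phys else None
    h_sig = grid.h**cfg.sigma
    n_coll = grid.n_steps  # collocation nodes t_1..t_N
    params_model = _train_params(reference)

    # Adam state
    mW = [np.zeros_like(w) for w in net.weights]
    vW = [np.zeros_like(w) for w in net.weights]
    mb = [np.zeros_like(b) for b in net.biases]
    vb = [np.zeros_like(b) for b in net.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8

    history = np.empty(cfg.iterations)
    final: LossBreakdown | None = None
    t_start = _time.perf_counter()
    for it in range(1, cfg.iterations + 1):
        U, Z, cache = net.forward(t_norm)
        gU = np.zeros_like(U)
        gZ = np.zeros_like(Z)

        diff = U[data_idx] - observations
        data_loss = float(np.mean(np.sum(diff**2, axis=1)))
        gU[data_idx] += (2.0 / data_idx.size) * diff

        if use_phys:
            lam = cfg.lambda_phys
            z1, z2 = (Z[:, 0], Z[:, 1]) if cfg.use_controls else (0.0, 0.0)
            V = U - U[0]
            deriv = (W @ V) / h_sig
            R = deriv - controlled_rhs(U, params_model, z1, z2)
            Rc = R[1:]  # collocation rows t_1..t_N
            physics_loss = float(np.mean(np.sum(Rc**2, axis=1)))
            # conv part: d(lam*Lp)/dV = lam*(2/Nc)/h^s * W^T R
            Rpad = np.zeros_like(R)
            Rpad[1:] = Rc
            gV = (lam * 2.0 / n_coll) * (W.T @ Rpad) / h_sig
            gU += gV
            gU[0] -= gV.sum(axis=0)  # every v_j carries -U[0]
            # rhs part: -lam*(2/Nc) * J^T r at each collocation node
            J = rhs_jacobian_state(U[1:], params_model, _z(z1, 1), _z(z2, 1))
            gU[1:] -= (lam * 2.0 / n_coll) * np.einsum("nij,ni->nj", J, Rc)
            if cfg.use_controls:
                Jz = rhs_jacobian_controls(U[1:], params_model)
                gZ[1:] -= (lam * 2.0 / n_coll) * np.einsum("nij,ni->nj", Jz, Rc)
        else:
            physics_loss = 0.0

        total = data_loss + cfg.lambda_phys * physics_loss
        if not np.isfinite(total):
            raise ArithmeticError(f"{variant} training diverged at iteration {it}")
        if it >= 2:
            # the loss evaluated here is the post-update loss of the
            # previous iteration
            history[it - 2] = total

        gW_, gb_ = net.backward(cache, gU, gZ)

        for li in range(len(net.weights)):
            for g, m, v, p in ((gW_[li], mW[li], vW[li], net.weights[li]),
                               (gb_[li], mb[li], vb[li], net.biases[li])):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g**2
                mhat = m / (1 - b1**it)
                vhat = v / (1 - b2**it)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # final post-update evaluation; fills the last history entry so that
    # the breakdown's total equals history[-1] exactly
    U2, Z2, _ = net.forward(t_norm)
    diff2 = U2[data_idx] - observations
    d2 = float(np.mean(np.sum(diff2**2, axis=1)))
    if use_phys:
        z1b, z2b = (Z2[:, 0], Z2[:, 1]) if cfg.use_controls else (0.0, 0.0)
        R2 = ((W @ (U2 - U2[0])) / h_sig - controlled_rhs(U2, params_model, z1b, z2b))[1:]
        p2 = float(np.mean(np.sum(R2**2, axis=1)))
    else:
        p2 = 0.0
    per_state = np.mean((U2 - clean) ** 2, axis=0)
    final = LossBreakdown.build(d2, p2, cfg.lambda_phys, per_state)
    history[-1] = final.total

    U_fin, Z_fin = net.predict(t_norm)
    predicted = Trajectory(grid, U_fin, Z_fin if cfg.use_controls else None)
    wall = _time.perf_counter() - t_start
    result = TrainingResult(variant, cfg, cfg.seed, noise_level, history, final, predicted, wall)
    result.network = net
    return result


def _z(z, start):
    return z if np.isscalar(z) else z[start:]


def _train_params(reference: Trajectory) -> ModelParameters:
    """Model parameters attached to the reference (default Table-1)."""
    p = getattr(reference, "params", None)
    return p if p is not None else ModelParameters()


def robustness_ratio(loss_high: float, loss_zero: float) -> float:
    """Mean final loss at the highest noise level over the zero-noise one."""
    if loss_zero == 0:
        raise ZeroDivisionError("robustness ratio undefined: zero-noise loss is 0")
    return float(loss_high / loss_zero)


def noise_benchmark(
    config: PINNConfig,
    reference: Trajectory,
    levels: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20),
    replicates: int = 3,
    variants: tuple[str, ...] = VARIANTS,
    base_seed: int = 0,
) -> NoiseBenchmarkResult:
    """Monte-Carlo noise-injection benchmark across the three variants.

    Every (variant, level, replicate) cell trains from scratch with a
    distinct recorded seed.  Statistics use the n-1 (sample) standard
    deviation.  Individual failures are recorded and skipped; a cell
    with no successful replicate raises.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    stats: dict = {}
    seeds: dict = {}
    failures: list = []
    for vi, variant in enumerate(variants):
        stats[variant] = {}
        seeds[variant] = {}
        for li, level in enumerate(levels):
            finals, mses = [], []
            cell_seeds = []
            for rep in range(replicates):
                seed = base_seed + 1000 * vi + 100 * li + rep
                cell_seeds.append(seed)
                try:
                    res = train_variant(variant, config, reference, level, seed)
                except ArithmeticError as exc:
                    failures.append({"variant": variant, "level": level, "seed": seed,
                                     "error": str(exc)})
                    continue
                finals.append(res.final.total)
                mses.append(res.final.per_state_mse)
            if not finals:
                raise RuntimeError(f"all replicates failed for {variant} at level {level}")
            finals = np.asarray(finals)
            mses = np.asarray(mses)
            stats[variant][level] = {
                "mean": float(finals.mean()),
                "sd": float(finals.std(ddof=1)) if finals.size > 1 else 0.0,
                "min": float(finals.min()),
                "max": float(finals.max()),
                "per_state_mse_mean": mses.mean(axis=0).tolist(),
                "per_state_mse_sd": (mses.std(axis=0, ddof=1).tolist()
                                     if mses.shape[0] > 1 else [0.0] * 5),
                "n": int(finals.size),
            }
            seeds[variant][level] = cell_seeds
    ratios = {}
    top = max(levels)
    for variant in variants:
        ratios[variant] = robustness_ratio(
            stats[variant][top]["mean"], stats[variant][0.0]["mean"]
        )
    return NoiseBenchmarkResult(tuple(levels), replicates, stats, ratios, seeds, failures)
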