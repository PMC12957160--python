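"""Fractional Alzheimer's disease model: states, parameters, right-hand side.

The model tracks five interacting compartments in brain tissue (all in
g/ml): functional neurons ``F_N``, infected (amyloid-compromised) neurons
``I_N``, amyloid-beta peptide ``A_beta``, tau protein ``T_mu``, and
microglia ``M_rho``.  Time derivatives are Caputo-fractional of order
``sigma`` in (0, 1]; this module only defines the (order-independent)
right-hand side

    F_N'   = Pi_N + rho*T_mu - alpha*F_N*A_beta - phi1*F_N
    I_N'   = alpha*F_N*A_beta - beta1*I_N*M_rho - (gamma + phi2)*I_N
    A_beta'= gamma*I_N - beta2*A_beta*M_rho - (d_beta + kappa)*A_beta
    T_mu'  = kappa*A_beta - beta3*T_mu*M_rho - (d_mu + rho)*T_mu
    M_rho' = (beta1*I_N + beta2*A_beta + beta3*T_mu)*M_rho - phi3*M_rho

Two optional therapeutic controls enter multiplicatively: z1 in [0, 1]
suppresses amyloid production (the gamma*I_N source) and z2 in [0, 1]
suppresses the amyloid-driven infection of neurons (the alpha*F_N*A_beta
term in both neuron equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "STATE_NAMES",
    "ModelParameters",
    "ControlPair",
    "TABLE1_PARAMS",
    "TABLE1_STATE",
    "CHAOS_PARAMS",
    "PRESETS",
    "get_preset",
    "model_rhs",
    "controlled_rhs",
    "production_loss_split",
    "rhs_jacobian_state",
    "rhs_jacobian_controls",
]

#: Canonical state ordering used by every array in the package.
STATE_NAMES = ("F_N", "I_N", "A_beta", "T_mu", "M_rho")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the compartmental model (all per day except Pi_N).

    Parameters
    ----------
    Pi_N : float
        Neuron production rate (amount/day).
    rho : float
        Tau-driven neurodegeneration feedback rate (1/day).
    alpha : float
        Amyloid-beta cascade (infection) rate (1/day).
    phi1 : float
        Natural neuron death rate (1/day).
    beta1, beta2, beta3 : float
        Microglial clearance rates of infected neurons, amyloid-beta and
        tau, respectively (1/day).
    gamma : float
        Amyloid production rate by infected neurons (1/day).
    phi2 : float
        Infected-neuron death rate (1/day).
    d_beta : float
        Proteolytic amyloid degradation rate (1/day).
    kappa : float
        Amyloid-to-tau initiation rate (1/day).
    d_mu : float
        Natural tau degradation rate (1/day).
    phi3 : float
        Microglial death rate (1/day).
    """

    Pi_N: float = 1.0
    rho: float = 0.025
    alpha: float = 0.08
    phi1: float = 0.02
    beta1: float = 0.06
    gamma: float = 0.00017
    phi2: float = 0.00019
    beta2: float = 0.002
    d_beta: float = 9.51
    kappa: float = 0.025
    beta3: float = 0.001
    d_mu: float = 0.277
    phi3: float = 0.015

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v!r} must be finite and >= 0")
        if self.phi1 <= 0:
            raise ValueError("phi1 must be > 0 (disease-free equilibrium requires it)")
        if self.d_beta + self.kappa <= 0:
            raise ValueError("d_beta + kappa must be > 0")
        if self.d_mu + self.rho <= 0:
            raise ValueError("d_mu + rho must be > 0")

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class ControlPair:
    """Constant therapeutic control levels, each in [0, 1].

    z1 targets amyloid accumulation (scales the gamma*I_N source by
    ``1 - z1``); z2 targets neurodegeneration (scales alpha*F_N*A_beta
    by ``1 - z2``).
    """

    z1: float = 0.0
    z2: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("z1", self.z1), ("z2", self.z2)):
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"control {name}={v!r} must lie in [0, 1]")


# Baseline parameterization and initial state (early-stage pathology).
TABLE1_PARAMS = ModelParameters()
TABLE1_STATE = np.array([0.14, 0.0, 1e-6, 1e-6, 0.02])

# Alternative regime used for the gain-stabilization worked example:
# very slow natural neuron death with a large production rate.
CHAOS_PARAMS = ModelParameters(
    Pi_N=700.0,
    rho=0.025,
    alpha=0.08,
    phi1=0.00003,
    gamma=0.00017,
    phi2=0.00019,
    d_beta=9.51,
    kappa=0.025,
    d_mu=0.277,
)

PRESETS: dict[str, tuple[ModelParameters, np.ndarray]] = {
    "table1": (TABLE1_PARAMS, TABLE1_STATE),
    "chaos": (CHAOS_PARAMS, TABLE1_STATE),
}


def get_preset(name: str) -> tuple[ModelParameters, np.ndarray]:
    """Return ``(params, initial_state)`` for a named preset."""
    try:
        params, state = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return params, state.copy()


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != 5:
        raise ValueError(f"state must have 5 components, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite components")
    return state


def model_rhs(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Evaluate the uncontrolled right-hand side.

    ``state`` may be a 5-vector or an (n, 5) array; the result has the
    same shape.
    """
    return controlled_rhs(state, params, z1=0.0, z2=0.0)


def controlled_rhs(
    state: np.ndarray,
    params: ModelParameters,
    z1: float | np.ndarray = 0.0,
    z2: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Right-hand side with multiplicative therapeutic controls.

    z1 scales the amyloid source gamma*I_N by (1 - z1); z2 scales the
    infection term alpha*F_N*A_beta by (1 - z2) in both neuron
    equations.  z1 = z2 = 0 recovers :func:`model_rhs` exactly.
    Controls may be scalars or arrays broadcastable against the leading
    state dimensions.
    """
    state = _check_state(state)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any((z1 < 0) | (z1 > 1)) or np.any((z2 < 0) | (z2 > 1)):
        raise ValueError("controls must lie in [0, 1]")

    p = params
    F, I, A, T, M = (state[..., i] for i in range(5))
    infection = (1.0 - z2) * p.alpha * F * A
    production = (1.0 - z1) * p.gamma * I
    out = np.empty_like(state)
    out[..., 0] = p.Pi_N + p.rho * T - infection - p.phi1 * F
    out[..., 1] = infection - p.beta1 * I * M - (p.gamma + p.phi2) * I
    out[..., 2] = production - p.beta2 * A * M - (p.d_beta + p.kappa) * A
    out[..., 3] = p.kappa * A - p.beta3 * T * M - (p.d_mu + p.rho) * T
    out[..., 4] = (p.beta1 * I + p.beta2 * A + p.beta3 * T) * M - p.phi3 * M
    return out


def production_loss_split(
    state: np.ndarray,
    params: ModelParameters,
    z1: float | np.ndarray = 0.0,
    z2: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the right-hand side as ``rhs_i = P_i - D_i * state_i``.

    For non-negative states both P (production) and D (loss rate) are
    non-negative, which is what the semi-implicit GL stepper needs to
    preserve positivity.  The microglial growth term is assigned to P
    (evaluated explicitly) with only the death rate phi3 in D.
    """
    state = _check_state(state)
    p = params
    F, I, A, T, M = (state[..., i] for i in range(5))
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any((z1 < 0) | (z1 > 1)) or np.any((z2 < 0) | (z2 > 1)):
        raise ValueError("controls must lie in [0, 1]")
    P = np.empty_like(state)
    D = np.empty_like(state)
    P[..., 0] = p.Pi_N + p.rho * T
    D[..., 0] = (1.0 - z2) * p.alpha * A + p.phi1
    P[..., 1] = (1.0 - z2) * p.alpha * F * A
    D[..., 1] = p.beta1 * M + p.gamma + p.phi2
    P[..., 2] = (1.0 - z1) * p.gamma * I
    D[..., 2] = p.beta2 * M + p.d_beta + p.kappa
    P[..., 3] = p.kappa * A
    D[..., 3] = p.beta3 * M + p.d_mu + p.rho
    P[..., 4] = (p.beta1 * I + p.beta2 * A + p.beta3 * T) * M
    D[..., 4] = p.phi3
    return P, D


def rhs_jacobian_state(
    state: np.ndarray,
    params: ModelParameters,
    z1: float | np.ndarray = 0.0,
    z2: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Analytic Jacobian d(rhs)/d(state), shape (..., 5, 5)."""
    state = _check_state(state)
    p = params
    F, I, A, T, M = (state[..., i] for i in range(5))
    z1 = np.broadcast_to(np.asarray(z1, dtype=float), F.shape)
    z2 = np.broadcast_to(np.asarray(z2, dtype=float), F.shape)
    J = np.zeros(state.shape[:-1] + (5, 5))
    aF = (1.0 - z2) * p.alpha * F
    aA = (1.0 - z2) * p.alpha * A
    J[..., 0, 0] = -aA - p.phi1
    J[..., 0, 2] = -aF
    J[..., 0, 3] = p.rho
    J[..., 1, 0] = aA
    J[..., 1, 1] = -p.beta1 * M - (p.gamma + p.phi2)
    J[..., 1, 2] = aF
    J[..., 1, 4] = -p.beta1 * I
    J[..., 2, 1] = (1.0 - z1) * p.gamma
    J[..., 2, 2] = -p.beta2 * M - (p.d_beta + p.kappa)
    J[..., 2, 4] = -p.beta2 * A
    J[..., 3, 2] = p.kappa
    J[..., 3, 3] = -p.beta3 * M - (p.d_mu + p.rho)
    J[..., 3, 4] = -p.beta3 * T
    J[..., 4, 1] = p.beta1 * M
    J[..., 4, 2] = p.beta2 * M
    J[..., 4, 3] = p.beta3 * M
    J[..., 4, 4] = p.beta1 * I + p.beta2 * A + p.beta3 * T - p.phi3
    return J


def rhs_jacobian_controls(
    state: np.ndarray,
    params: ModelParameters,
) -> np.ndarray:
    """Analytic Jacobian d(rhs)/d(z1, z2), shape (..., 5, 2).

    The controlled right-hand side is affine in each control, so this
    Jacobian does not depend on the control values themselves.
    """
    state = _check_state(state)
    p = params
    F, I, A = state[..., 0], state[..., 1], state[..., 2]
    J = np.zeros(state.shape[:-1] + (5, 2))
    J[..., 0, 1] = p.alpha * F * A
    J[..., 1, 1] = -p.alpha * F * A
    J[..., 2, 0] = -p.gamma * I
    return J
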