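"""High-level simulation front-end for the Alzheimer's model.

Wraps the GL steppers with the model right-hand side.  The default
method is the positivity-preserving semi-implicit stepper ("stable"):
the model states are concentrations and the amyloid clearance rate
(d_beta + kappa = 9.535/day) makes the system stiff enough that the
fully explicit scheme diverges on the coarse day-scale grids used for
long horizons.  The explicit scheme remains available for oracle
comparisons and non-stiff configurations.
"""

from __future__ import annotations

import numpy as np

from .glsolver import SolverGrid, Trajectory, integrate_caputo_gl
from .model import ModelParameters, controlled_rhs, production_loss_split

__all__ = ["simulate"]


def simulate(
    params: ModelParameters,
    state0: np.ndarray,
    sigma: float,
    grid: SolverGrid,
    controls: np.ndarray | None = None,
    method: str = "stable",
    memory_length: int | None = None,
) -> Trajectory:
    """Integrate the (optionally controlled) model over ``grid``.

    Parameters
    ----------
    params, state0
        Model rates and 5-component initial state.
    sigma : float
        Caputo order in (0, 1].
    controls : ndarray, optional
        Per-node (z1, z2) schedule, shape (n_nodes, 2).
    method : {"stable", "explicit"}
        "stable" (default) uses the semi-implicit production/loss GL
        stepper, which keeps all concentrations non-negative on any
        step size; "explicit" uses the plain explicit GL update.
    """
    if method == "stable":

        def split(t, u, z1=0.0, z2=0.0):
            return production_loss_split(u, params, z1, z2)

        return integrate_caputo_gl(
            None, state0, sigma, grid, controls=controls,
            memory_length=memory_length, split_rhs=split,
        )
    if method == "explicit":

        def rhs(t, u, z1=0.0, z2=0.0):
            return controlled_rhs(u, params, z1, z2)

        return integrate_caputo_gl(
            rhs, state0, sigma, grid, controls=controls, memory_length=memory_length,
        )
    raise ValueError(f"unknown method {method!r}; choose 'stable' or 'explicit'")
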