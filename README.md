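# fracalz

Fractional-order modelling of Alzheimer's disease dynamics: a Caputo
compartmental model of amyloid-beta / tau / microglia–driven
neurodegeneration, with a Grünwald–Letnikov (GL) solver, stability and
reproduction-number analysis, parameter-elasticity tools,
physics-informed neural networks (PINNs) with fractional residuals,
and therapeutic-control scenarios.

It is aimed at computational-neuroscience and mathematical-biology
researchers who want a small, fully reproducible toolchain for
memory-dependent (non-local in time) disease models — where the rate
of change at time *t* depends on the whole history of the state, not
just its present value.

## The model

Five interacting compartments (g/ml): functional neurons $F_N$,
infected neurons $I_N$, amyloid-beta $A_\beta$, tau protein $T_\mu$,
and microglia $M_\rho$.  With $D^\sigma$ the Caputo derivative of
order $\sigma \in (0,1]$:

$$
\begin{aligned}
D^\sigma F_N &= \Pi_N + \rho T_\mu - \alpha F_N A_\beta - \phi_1 F_N\\
D^\sigma I_N &= \alpha F_N A_\beta - \beta_1 I_N M_\rho - (\gamma+\phi_2) I_N\\
D^\sigma A_\beta &= \gamma I_N - \beta_2 A_\beta M_\rho - (d_\beta+\kappa) A_\beta\\
D^\sigma T_\mu &= \kappa A_\beta - \beta_3 T_\mu M_\rho - (d_\mu+\rho) T_\mu\\
D^\sigma M_\rho &= (\beta_1 I_N + \beta_2 A_\beta + \beta_3 T_\mu) M_\rho - \phi_3 M_\rho
\end{aligned}
$$

Amyloid infects neurons at rate $\alpha$, infected neurons produce
amyloid at rate $\gamma$, amyloid seeds tau at rate $\kappa$, and
microglia clear all three at rates $\beta_{1,2,3}$.  Two optional
therapeutic controls enter multiplicatively: $z_1$ scales the amyloid
source $\gamma I_N$ by $(1-z_1)$, $z_2$ scales the infection term
$\alpha F_N A_\beta$ by $(1-z_2)$.

The basic reproduction number from the next-generation matrix
$K = F V^{-1}$ on the infected states $(I_N, A_\beta, T_\mu)$ is

$$
R_0 = \sqrt{\frac{\alpha\,\gamma\,\Pi_N}
  {(d_\beta+\kappa)(\gamma+\phi_2)\,\phi_1}} .
$$

The Caputo derivative is discretized by the GL convolution with
fractional binomial weights $w_k = (-1)^k\binom{\sigma}{k}$ and the
$u - u_0$ shift that distinguishes Caputo from Riemann–Liouville;
`docs/methods.md` details the scheme, its positivity-preserving
semi-implicit variant, and every numerical choice.

## Worked example

```python
from fracalz import (SolverGrid, TABLE1_PARAMS, TABLE1_STATE,
                     ngm_matrices, simulate)

ngm = ngm_matrices(TABLE1_PARAMS)
print(f"R0 = {ngm.R0:.6f}")

grid = SolverGrid(horizon=200.0, n_steps=2000)   # h = 0.1 day
for sigma in (0.7, 0.8, 0.9, 1.0):
    traj = simulate(TABLE1_PARAMS, TABLE1_STATE, sigma, grid)
    print(f"sigma={sigma}: final F_N = {traj.states[-1, 0]:.4f}")
```

prints

```
R0 = 0.445085
sigma=0.7: final F_N = 27.0020
sigma=0.8: final F_N = 35.7251
sigma=0.9: final F_N = 43.6836
sigma=1.0: final F_N = 49.0831
```

$R_0 < 1$: under the baseline rates the pathology cannot sustain
itself, and the neuron population relaxes toward its disease-free
carrying capacity $\Pi_N/\phi_1 = 50$ g/ml — the more memory
(smaller $\sigma$), the slower the approach.  All states remain
non-negative at every node.

The `examples/` directory holds one short script per capability
(fractional dynamics, stability/R0, sensitivity, PINN training,
control strategies); each prints the numbers it computes and one line
on what they mean.  The same functionality is scriptable through the
`fracalz` command-line tool (`fracalz --help`).

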