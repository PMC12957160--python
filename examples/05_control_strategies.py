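"""Compare therapeutic-control strategies.

Simulates the controlled model (z1 suppresses amyloid production, z2
suppresses neuronal infection) under no control, a constant 0.5/0.5
schedule, and a directly optimized piecewise-constant schedule, and
prints the terminal neuron level, the integrated amyloid burden, and
the quadratic-effort cost of each strategy.
"""

from fracalz import SolverGrid, TABLE1_PARAMS, TABLE1_STATE, compare_strategies

grid = SolverGrid(200.0, 400)
report = compare_strategies(TABLE1_PARAMS, TABLE1_STATE, 0.9, grid, seed=0, iterations=200)

print("strategy    terminal F_N    A_beta burden     cost")
for name, entry in report["strategies"].items():
    print(
        f"{name:9s}   {entry['terminal_F_N']:10.5f}   {entry['burden_A_beta']:.6e}"
        f"   {entry['cost']:.6e}"
    )

print()
print("The optimizer keeps effort near zero here: in this low-amyloid")
print("regime the burden terms are tiny, so heavy dosing (the constant")
print("schedule) only pays the z^2 effort penalty without measurable")
print("benefit. Optimized control never does worse than the constant")
print("schedule because that schedule is in its candidate set.")
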