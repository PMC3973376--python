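# neurogen

Compartmental modelling of adult hippocampal neurogenesis: cell-count
dynamics, BrdU pulse-chase label kinetics, knockout sensitivity analysis,
weighted fitting of age-decline data, and an exact stochastic oracle.

## The problem

In the adult dentate gyrus, neural stem cells generate progenitors,
neuroblasts, mature granule neurons and astrocytes, and all proliferating
pools shrink with age.  Inducible knockouts (KOs) that target stem cells
change one kinetic property — the fraction of self-renewal, the
proliferation rate or the division probability — and are read out either
as cell counts or as counts of cells labelled by the division marker
bromodeoxyuridine (BrdU).  Interpreting such readouts is subtle: the same
KO can raise a count at one readout time and lower it at another, and
labelled and unlabelled pools of the same cell type can respond in
opposite directions.  `neurogen` is a toolbox for working through this
bookkeeping quantitatively.  It is aimed at modellers and experimental
groups designing or re-analysing stem-cell-targeting KO and BrdU
experiments.

## The model

Five compartments — stem cells `c1`, progenitors `c2`, neuroblasts `c3`,
neurons `c4`, astrocytes `c5` — follow a linear ODE system

    c1' = λ1 c1
    c2' = k12 c1 + λ2 c2
    c3' = k23 c2 − (p3 + d3) c3
    c4' = p3 c3 − d4 c4
    c5' = k15 c1 − d5 c5

with composite rates built from 12 kinetic parameters: per-cell event
rates `p1, p2` (an event is a division with probability `θ1, θ2`, else a
direct transformation), fractions of self-renewal `a1, a2 ∈ [1/2, 1]`
(so `2a − 1` is the symmetric-division probability), the asymmetric-fate
split `κ` (progenitor vs astrocyte daughter), maturation rate `p3` and
death rates `d2..d5`.  Stem cells have no death term; their pool declines
only through astrocytic transformation, and it shrinks monotonically iff
`a1 θ1 ≤ 1/2` (net stem rate `λ1 = (2 a1 θ1 − 1) p1`).

On top of the counts the package provides:

* **BrdU labelling** — labelled pools at the end of an exposure window of
  length `δ` via exponential-lifetime division fractions
  `F = 1 − e^{−p δ}` (each division labels both daughters; no labelled
  neurons at the end of the window), then chase dynamics identical to the
  unlabelled system.
* **Sensitivity analysis** — exact forward-sensitivity ODEs for `∂c_i/∂p`
  and for labelled pools (instantaneous at `t = 0` for labelled readouts,
  zero at `t = 0` for counts), summarized as *sign sequences* such as
  `(0, −, 0, +)` — the signature of a two-phase KO response — plus
  closed-form coefficients for the analytically tractable quantities.
* **Weighted fitting** — inverse-variance weighted least squares of the
  closed-form stem/progenitor curves against age series (mean ± s.e.m.),
  in the two modes `c1 & c1/c2` and `c1 & c2`, over the identifiable
  composites `(λ1, λ2, n1, n2, K = k12 n1)`.
* **Stochastic oracle** — an exact event-driven branching-process
  simulation (numba-jitted, Philox counter-based streams) whose ensemble
  means validate the ODEs and whose labelled counts quantify the
  first-order error of the labelling formula.
* **Synthetic data** — seeded generators for age series (with an optional
  late-age saturation floor) and paired wild-type/KO datasets.

## Worked example

```python
import numpy as np
from neurogen import S52_PARAMS, S52_INIT, derived_rates, solve_system, table1_report

r = derived_rates(S52_PARAMS)
print(f"lambda1 = {r.lambda1:.3f}, lambda2 = {r.lambda2:.3f}, k12 = {r.k12:.3f}")

traj = solve_system(S52_PARAMS, S52_INIT, np.linspace(0, 30, 301))
print(f"c1(1) = {traj.states[10, 0]:.1f}, c2(1) = {traj.states[10, 1]:.1f}")

rep = table1_report(S52_PARAMS, S52_INIT)
print("sign sequence of dc2/da1:", rep.sequences[("a1", "c2")])
```

prints

```
lambda1 = -0.230, lambda2 = -1.200, k12 = 0.378
c1(1) = 7945.3, c2(1) = 3428.5
sign sequence of dc2/da1: (0, -, 0, +)
```

`λ1 = −0.23` is the net per-capita stem-cell loss rate under the canonical
declining-regime parameter set (`a1 = 0.55, θ1 = 0.7, p1 = 1`, …), so
10 000 stem cells decay to ≈ 7945 after one model time unit, progenitors
track them downward, and the sign sequence says that increasing stem-cell
self-renewal first *depresses* the progenitor count (fewer asymmetric,
progenitor-producing divisions) and later *elevates* it (a larger
preserved stem pool) — a two-phase KO response with a single crossing.

The same analyses are scriptable from the shell:

```sh
neurogen table1 --config src/neurogen/data/paper_s52.yaml --out out/
neurogen simulate --config src/neurogen/data/paper_s52.yaml --out out/
```

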