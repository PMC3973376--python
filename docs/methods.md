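# Methods

This note documents the model, the numerical choices and the design
decisions behind `neurogen`, and states what the synthetic-data-based
tests do and do not demonstrate.

## Model and assumptions

The lineage model is a linear, five-compartment ODE system (stem cells,
progenitors, neuroblasts, neurons, astrocytes) in which each
proliferating cell carries an exponential event clock: with rate `p` an
event fires, it is a division with probability `θ` (else a direct
transformation), a division is symmetric with probability `2a − 1`
(fraction of self-renewal `a ∈ [1/2, 1]`), and the non-stem daughter of
an asymmetric stem division is a progenitor with probability `κ`, else
an astrocyte.  Stem cells have no death term: the only stem-loss channel
is astrocytic transformation, which is why the net stem rate
`λ1 = (2 a1 θ1 − 1) p1` is negative exactly when symmetric gains are
rarer than transformations (`a1 θ1 < 1/2`; the boundary value gives a
constant pool and is reported as "declining with margin 0").
Linearity is deliberate — no feedback or saturation terms — which buys
closed forms for the stem and progenitor compartments and exact forward
sensitivities, at the price of not capturing the late-age saturation
that the fitting module's misfit fixture illustrates.

Counting parameters, the model has 12 kinetic parameters plus 5 initial
counts (17).  Descriptions of this model family sometimes quote 18
parameters; the most plausible 18th is the BrdU exposure length `δ`,
which we treat as a protocol input rather than a model parameter.  Time
units are abstract ("model time units") because the canonical parameter
set is not calibrated to physiological time.

The analytic sign results hold in the *declining regime*: `a1 θ1 < 1/2`
together with a strictly faster net progenitor depletion
(`λ2 = (2 a2 θ2 − 1) p2 − d2 < λ1`).  `check_assumption_3_2` reports
both flags; the sign-sequence table is still produced outside the
regime but flagged.

## BrdU labelling

A cell is labelled iff it divides while the marker is present.  Over an
exposure of length `δ` the fraction of compartment-`i` cells with an
event is `F_i = 1 − e^{−p_i δ}`; a fraction `θ_i` of those events are
divisions, and each division contributes its expected offspring to the
labelled pools (e.g. `2 a1` labelled stem cells per stem division).
Transformations involve no DNA synthesis and never create a label;
hence no labelled neurons at the end of the window.  After the window,
labelled pools evolve under exactly the compartment dynamics (label
dilution is ignored; all progeny of labelled cells remain labelled).

The formula ignores second and higher-order event chains within the
window.  This matters quantitatively: the neglected terms are O(δ²) in
*absolute* counts but the labelled pools are themselves O(δ), so the
formula's *relative* error is first order in `δ` with a coefficient set
by the fastest event rates.  Under the canonical set (`p2 = 2.5`,
`p3 = 1.5`) at `δ = 0.05` the exact stochastic process shows ~2% (l2)
to ~14% (l3) relative deviations — dominated by labelled progenitors
transforming into neuroblasts before the window closes — while the slow,
inflow-free stem pool stays within 2%.  The oracle tests assert exactly
this structure: close agreement for l1, deviations that halve when `δ`
halves for the faster pools, and a handful of labelled neurons (a
three-event chain, second-order small) where the formula has zero.

Default `δ = 0.1` model time units, configurable everywhere a protocol
is accepted.

## Sensitivities and sign sequences

For the linear system `c' = A c` the parameter sensitivity
`s = ∂c/∂p` solves the augmented linear system `s' = A s + (∂A/∂p) c`
with `s(0) = 0` (initial counts are parameter-independent), which is
exact up to solver tolerance; `∂A/∂p` is obtained symbolically (sympy)
and cached.  Labelled-pool sensitivities chain through the
pre-labelling trajectory, the end-of-exposure matrix `B(p, δ)` (labels
`= B c`), and the chase dynamics.  The administration time is protocol
input, never a differentiated variable.  Central finite differences
(`h = 1e−6 · max(1, |p|)`) serve as the independent numerical oracle at
relative tolerance 1e−4.

The analytically tractable quantities (`c1`, `c2`, and the
BrdU-incorporating pools `l1+`, `l2+`, `l5+`, all two-exponential in
time) admit closed-form derivatives `D(t) = (A + B t) e^{λ1 t} +
C e^{λ2 t}`; the coefficients are derived from the model's own partial
derivatives and cross-checked against the ODE route at 1e−6.  In the
declining regime the curves fall into three classes — single positive
phase (P1), positive-then-negative (P2), negative-then-positive (P3),
each with at most one crossing — and the coefficient object reports the
class.  The derivation covers the stem-cell parameters
(`a1, θ1, p1, κ`); other pairs raise an explicit
`ClosedFormUnavailableError` rather than silently falling back.

Sign sequences are extracted from a 3001-point grid on `[0, 30]` (the
default horizon exceeds the slowest intrinsic timescale `1/d4 = 20`):
samples within `1e−6 · max|curve|` of zero count as zero, runs are
collapsed, a zero crossing between opposite signs is always recorded as
a `0` entry, and crossing times are refined with a bracketed
cubic-spline root to ~1e−10.  `crossing_times` holds one refined time
per interior crossing; leading zeros (the `t = 0` point of count
derivatives) carry no crossing time.  Phase counts are the number of
nonzero symbols.

Long-time behaviour: every analysed derivative is the product of the
decaying stem pool and an at-most-affine factor, so KO effects fade;
the neuron-count response is the exception whose fate is set by `d4`
(plateau at `d4 = 0`, slow `e^{−d4 t}` decay otherwise).  Convergence
statements are tested at horizons matched to these timescales
(t ≈ 60–150), since at `t = 30` the slow `d4` mode has decayed by
barely a factor of two.

## Stochastic oracle

The ODE system is the mean of a multitype branching process, simulated
exactly with population-level propensities (all rates are linear, so
per-cell identity is never needed): 14 channels — 7 event types × 2
label states — with next-event sampling from the total propensity.
Competing progenitor risks (event vs death) are independent exponential
clocks, matching the additive ODE terms.  BrdU marks both daughters of
any division inside the window; labels are heritable; transformations
preserve but never create labels.  The kernel is numba-jitted; streams
are `Philox` counter-based generators keyed by `(seed, replicate)`, so
ensembles are reproducible across platforms and replicate order.  An
event cap (default 1e7 per run) guards against parameter regimes with
exploding populations and fails loudly.

## Fitting

Only the composites `(λ1, λ2, n1, n2, K = k12 n1)` are identifiable
from stem/progenitor age series, so the optimizer works on them — rates
free, sizes in log space — and individual kinetic parameters are
recovered downstream only under user-supplied constraints.  The
objective is the sum of squared residuals weighted by inverse-square
s.e.m.; when the stem/progenitor *ratio* is fitted and the data file
carries no ratio errors, the s.e.m. is propagated to first order from
the component errors.  Weighted R² is computed on the same weighted
residuals against the weighted mean of the stacked observations (the
R² variant is a package convention and is stated here because weighted
R² definitions differ between tools).  Optimization is best-of-multi-
start: an informed start from a weighted log-linear regression of the
stem counts plus (by default) 99 random starts, each polished by
trust-region least squares (chosen over derivative-free simplex polish
for much more reliable convergence at equal cost; wild starts that
overflow the exponentials are clipped and rejected by the optimizer).
Identical data, mode, config and seed give bit-identical results.
The degenerate `λ1 = λ2` case is evaluated through a stable
`expm1(x)/x` form that limits to the confluent `t e^{λt}` solution, not
an error.

## Synthetic data

The age-series generator emulates stereological count tables: per age,
`R` replicate draws around the closed-form curves (mean-preserving
multiplicative lognormal, default cv = 5%, R = 4 — plausible scales for
stereological counting), summarized as mean and s.e.m. = SD/√R with a
small floor so inverse-variance weights stay finite; default age grid
10 points on `[0, 24]` model time units (evoking months of adult age).
An optional *saturation floor* clamps the true stem curve from below
(default fixture: 320 cells), producing data a pure exponential cannot
fit and reproducing the qualitative mode disagreement between fitting
`c1 & c1/c2` and `c1 & c2`.  The KO generator emits paired wild-type /
perturbed observations of counts and labelled pools at chosen readout
times.

What passing tests show — and what they do not: the generators draw
from the model itself (plus noise), so round-trip recovery demonstrates
the correctness and identifiability of the fitting machinery, not that
real hippocampal age series follow a two-exponential law; indeed the
saturation fixture exists precisely because real stem-cell counts
level off at late ages in a way the linear model cannot express.  The
noise model is independent across ages and compartments, which real
stereological replicates (shared animals, shared sectioning) are not.

## Numerical choices

* Integrator: LSODA (stiffness-switching), rtol 1e−10, atol 1e−12,
  dense output on the user grid; the exact constant Jacobian is
  supplied.  Tiny negative roundoff excursions are clipped to zero.
* Sign detection: relative zero band 1e−6 (1e−8 in the random-parameter
  lemma tests, where curve scales vary widely); crossing refinement by
  `brentq` on a cubic spline, xtol 1e−10.
* Lemma-test horizon: crossing times are bounded a priori by
  `(|A| + |C|)/|B|` from the closed-form coefficients; the test grid
  extends to three times that bound (min 30, cap 2000).
* Finite differences: central, `h = 1e−6 · max(1, |p|)`; structurally
  zero derivatives are checked absolutely (differencing two ~1e5-cell
  solutions leaves ~1e−4-cell noise).
* CSV I/O: comma-separated, header row, 17 significant digits —
  write/read round trips are lossless beyond 15 digits.

## Known limitations

* No feedback, saturation or spatial structure; exponential lifetimes
  only (real cell-cycle lengths are not exponential).
* No S-phase duration model: the fraction of dividing cells is equated
  with the fraction of DNA-synthesizing cells during the window.
* The end-of-exposure label formula is first-order in `δ` (see above);
  for fast-cycling compartments at `δ ≳ 0.05/p` the exact process
  deviates at the several-percent level.
* Astrocyte-count sensitivities carry no analytic sign guarantee; they
  are computed numerically only.
* Fitted kinetic parameters are reported as composites; disentangling
  e.g. `a1` from `θ1` requires external constraints.
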