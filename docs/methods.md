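# Methods

## Model

Effector T-cell dynamics is modelled as a second-order linear oscillator
driven by antigen and coupled to logistic-free pathogen growth with
mass-action clearance:

    T'' = −k T + λ P,        P' = α P − β T P,      k, λ, α, β > 0.

The second-order term is the point of the model: it endows the population
with inertia, so expansion persists after antigen removal and the onset of
clonal contraction is delayed. `−kT` is a Hooke's-law elasticity restoring
the effector pool to its baseline; `λP` is the antigenic force; the
pathogen equation is standard exponential growth minus mass-action
clearance. The model is a description of one response: it is declared
valid from the instant of activation to the end of clonal contraction
only. Memory formation, re-infection, exhaustion, regulatory T cells and
any spatial or stochastic structure are out of scope.

### Non-dimensionalization

With `τ = √k·t`, `x = T·k/(λP₀)`, `y = P/P₀` the system becomes

    x'' = −x + y,     y' = α* y − β* x y,     y(0) = 1,

with `α* = α/√k` and `β* = βλP₀/k^{3/2}`. This is the unique two-parameter
reduction that pins `y(0) = 1` and absorbs `k` and `λ` into the state
scales; `α*` measures pathogen growth per elastic period and `β*` the
clearance delivered by a unit reduced expansion. The inverse embedding
used throughout (`from_reduced`) is the canonical point `k = λ = P₀ = 1`.
The equivalence of the two forms is verified numerically (seeded random
parameter sets; agreement at integrator tolerance).

### Multi-clone extension

Each clone `i` keeps its own `(kᵢ, λᵢ, βᵢ)`; all are driven by the shared
pathogen through `λᵢ P`, and clearance contributions add in proportion to
clone abundance: `P' = αP − P·Σᵢ βᵢTᵢ`. This is the minimal mass-action
extension. Because each clone's `(Tᵢ, Vᵢ)` subsystem is linear in its own
state with shared forcing `P`, equal-`k` clones have trajectories exactly
proportional to `λᵢ` — immunodominance ordering (peaks ranked by
affinity) is exact, not approximate. An alternative in which clones
*share* (normalize) the antigenic stimulation was considered and not
adopted; the proportional-clearance form already reproduces both
immunodominance and compensatory expansion, and needs no extra rule for
the single-clone limit.

## Event semantics and classification

A run terminates at the **end of clonal contraction** — total `T`
returning to its initial value with negative slope — or at the horizon
`t_max`. Contraction detection is *armed* only after total `T` has
exceeded baseline + `peak_guard_eps` (default 1e−6 reduced units),
preventing spurious detection at `t = 0`; the integration is therefore
staged (expansion stage, terminal arming event; contraction stage,
terminal baseline crossing).

The pathogen-control crossing (`P` falling through `p_min`, default 0.05
of the initial load) is recorded **non-terminally**: with inertia the
clone keeps expanding after control, and terminating there would truncate
the contraction phase. Classification then reads the event order:

* ELIMINATION — control occurred at or before contraction end (including
  the rare case where contraction has not finished by the horizon);
* TOLERANCE — contraction ended with the pathogen still above threshold;
* UNRESOLVED — horizon reached with neither event; a first-class label so
  sweeps never abort. If both events fall at the same instant the
  pathogen-control event wins, making boundary classification
  deterministic.

Peak statistics are refined parabolically through the three dense-output
samples around the maximum, so peak times are resolved far below the
output spacing — needed because the inertia delay `t_peak − t_control`
can be a few 1e−3 near the regime boundary.

## Numerical choices

* Adaptive solver: scipy `solve_ivp` with DOP853, `rtol = 1e−8`,
  `abs_tol = 1e−10`, dense output sampled at `dt_out = 0.01` reduced time
  units (0.2 in parameter sweeps, where only event times matter);
  `t_max = 200` by default.
* Independent oracle: a deliberately simple fixed-step classical RK4
  (pure-Python, no shared code with the adaptive path) with events
  located by sign change and linear interpolation within a step. The two
  integrators agree to ~4e−8 relative max-norm on the preset suite, and
  the RK4 global error shows the expected 16× drop on step halving.
* Closed forms for the uncoupled `β = 0` limits (harmonic oscillator,
  exponential growth, driven oscillator with particular solution
  `C·e^{αt}`, `C = λP₀/(α²+k)`) serve as exact oracles. These limits sit
  on the boundary of the (strictly positive) parameter space and are
  constructed explicitly via `uncoupled_parameters`.
* Bisection for the critical growth rate `α*_c` operates on the
  classification label (the outcome is a step function of `α`, so
  root-bracketing on a continuous residual does not apply), with the
  bracket precondition (TOLERANCE below, ELIMINATION above) checked and
  the result post-verified at ±tol; default tolerance 1e−4.
* The raw ODE can drive `T` negative; no clamping is applied — the model
  is simply terminated at contraction end, before positivity matters.

## Parameter presets

No calibrated parameter values exist for this model (all rates are in
arbitrary consistent units), so the preset registry was built by coarse
grid search over the `(α*, β*)` plane against the qualitative regimes the
model exhibits, then frozen as regression anchors: five acute
(elimination with delayed contraction) and five tolerated points, a
dominant/subdominant clone pair chosen so that both the full and the
depleted repertoire eliminate, a three-clone affinity hierarchy, an
acute-vs-tolerated growth-rate pair straddling the threshold of one
clone, and an affinity sweep whose high-affinity tail has no threshold
(the clone eliminates every growth rate probed — reported explicitly as
undefined, never as a placeholder number).

## Phase-diagram structure

On the default grid (`α*` 0.05–3.00 step 0.05, `β*` 0.1–5.0 step 0.1,
3000 cells, ~15 s) tolerance occupies a contiguous low-`α*`/low-`β*`
region (~10% of cells); within every row the tolerance cells form a
single contiguous block with exactly one tolerance→elimination transition
as `α*` increases — the growth-rate threshold. One subtlety: the row
`β* = 1.0` is tangent to the *nose* of the tolerance region, and its two
leftmost cells (`α* ≤ 0.1`) classify as marginal eliminations (residual
`P` at would-be contraction 0.045–0.049 vs threshold 0.05, confirmed by
the RK4 oracle): at very small `α*` the pathogen barely grows, so net
clearance pushes it below threshold slightly sooner. The tolerance block
in that row therefore starts at `α* = 0.15` rather than at the grid edge.
This is a real, threshold-definition-dependent feature of the region's
boundary, not an integration artifact.

## Inertia and its range of validity

The delayed onset of contraction (`t_peak > t_control`) characterizes
acute responses, not every elimination: near the tolerance boundary a run
can cross `p_min` late, after the peak, and still eliminate. The acute
presets are drawn from the robustly inertial part of the elimination
region (delays 0.2–0.7 reduced time units), which is the phenomenology
they are meant to represent.

## What the tests do and do not show

All verification is against the model's own mathematics (closed forms,
an independent integrator, invariance properties) and the qualitative
regime structure; no biological time series is fitted, and no physical
units are claimed. Passing tests show the simulator solves *this* model
correctly and that the claimed qualitative phenomena (inertia, tolerance
by early contraction, growth-rate thresholds decreasing with affinity,
immunodominance, compensatory expansion) are genuine consequences of the
equations at the frozen presets — not that the model describes any
particular infection quantitatively.
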