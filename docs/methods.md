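# Methods

This note records what `neusim` computes, the choices behind its defaults,
and what the packaged fixtures do and do not emulate.

## Model composition

**Objects and namespaces.** A model is composed of populations and
mechanism instances. Every object's local symbols are prefixed with the
object path joined by underscores: state `m` of mechanism `Na` in
population `pop1` becomes `pop1_Na_m`; a connection mechanism `iGABAa`
from source `I` to target `E` uses the prefix `E_I_iGABAa_`. Collisions
(two distinct objects mapping onto one qualified name) are errors, never
silently renamed. The same qualified names label the output time series.

**Linkers.** Mechanisms export terms into host equations via `@`-prefixed
placeholders paired with compound-assignment statements. Contributions are
accumulated in mechanism-list order (population intrinsics first, then
connection mechanisms in specification order): `+=` appends `+ term`, `-=`
appends `- term`, `*=` multiplies, and `=` replaces (two `=` on one linker
is an ambiguous overwrite and an error). A placeholder with no
contributions becomes `0` — the additive identity, since every packaged
mechanism contributes additively. A mechanism whose linker name appears in
no host equation is recorded as a warning, not an error.

**Symbol binding in mechanisms.** A mechanism references host symbols by
name. The suffixes `_pre`/`_post` select the source/target population of a
connection mechanism. The aliases `v`, `V` and `X` fall back to the host's
first-declared state variable (the conventional voltage), so library
mechanisms written with `v` attach to hosts that name their voltage `V`.
Reserved names: `N` (size of the object's own state arrays: the host
population for intrinsic mechanisms, the source population for connection
mechanisms), `N_pre`, `N_post`, `netcon`, `tspike_pre`, `tspike_post`.

**Connectivity.** `netcon` is a (target × source) matrix, all-to-all ones
unless supplied in the connection's parameters. In expressions, a 2-D
parameter on the left of `*` multiplies by matrix product, so `netcon*s`
is the per-target sum of presynaptic gates. A scipy sparse matrix is
accepted as a storage hint and densified at code-generation time so that
sparse and dense connectivity give bit-identical trajectories; simulation
cost per step is therefore independent of connection density.

**Parameter precedence.** Overrides in a population's or connection's
`parameters` field are pushed down by name to every declaring object
(population equations and listed mechanisms) and take precedence over
inline mechanism definitions, which in turn shadow same-named library
files. An override that matches nothing is an error. Heterogeneous
parameters: a scalar broadcasts over the population; an array must match
the population size exactly.

**Defaults.** A bare equation string becomes population `pop1` of size 1
(a declared parameter `N` sets the size). A state with no declared initial
condition starts at 0. Spike-time buffers hold the last K spike times per
cell (K = 1 by default, configurable at build time), updated at upward
threshold crossings.

## Numerical integration

Fixed-step methods: forward Euler, midpoint (2nd-order Runge-Kutta), and
classic RK4. The integrator is an emitted standalone numpy program (the
solve file); `integrate()` executes exactly the text that
`render_solver_source()` returns, so the saved program reproduces the
in-memory run bit for bit. Model functions are inlined at code generation,
which lets Runge-Kutta stage states substitute cleanly and lets a bare
reference to a function name stand for a call with its resolved formal
arguments.

Per step: (1) state update by the chosen method; (2) conditionals, in
declaration order — each condition is evaluated once as an elementwise
mask, then its actions run left-to-right seeing earlier actions' effects;
(3) spike detection (`v[k-1] < threshold <= v[k]` on post-conditional
values) and buffer updates; (4) recording. Fixed variables are evaluated
once before the loop, in declaration order. Because conditionals quantize
resets to the step grid, a reset period is the ideal value plus up to one
step. Non-finite states abort with the offending variable and step
(checked at the recording cadence). Monitors of functions record
post-conditional values — the pre/post choice is a convention, stated here
because either is defensible.

Defaults: dt = 0.01 ms, tspan = (0, 100) ms, spike threshold 0 mV —
chosen to resolve conductance-based (Hodgkin-Huxley-type) spikes; models
with faster events need a smaller dt.

**Randomness.** One seeded generator per simulation owns every draw:
initial conditions, fixed variables, and per-step noise. Random builtins
(`rand`, `randn`) take explicit population-size arguments; calls inside
dynamics are hoisted and drawn once per time step, and multi-stage methods
reuse the same draw across stages, so noise variance does not depend on
the number of stages. Identical (model, options, seed) are bit-identical;
different seeds differ.

**Adaptive delegate.** The `adaptive` method hands a generated RHS to
scipy's `solve_ivp` (RK45; rtol/atol options). With no conditionals the
whole span is integrated in one call and sampled on the recording grid;
with conditionals the integrator is polled at the grid, applying resets
between segments — reset timing is grid-quantized, a documented caveat.
Stochastic dynamics and spike-time buffers are rejected for this method (a
variable-step integrator evaluates the RHS an unpredictable number of
times, which has no well-defined noise interpretation). Solver-source
emission is fixed-step only.

**Downsampling** keeps every k-th recorded point; spikes are detected at
full integration resolution first and are unaffected.

## Batch management

Sweeps expand to the Cartesian product of the triplets' value lists, first
triplet slowest-varying; a "zipped" form accepts an explicit list of
modification sets. Modifications target parameters or the specifiers
`size` and `equations` of populations (connections: parameters only).
Per-simulation seeds are `(1000003*master + 10007*k + 1) mod 2^31` — an
affine map that depends only on the master seed and the simulation index,
so serial and parallel (joblib) execution agree element-wise. Hook or
simulation failures are recorded per entry and the batch continues. The
study directory is self-describing (`spec.json` + `index.json`); a
`manifest.txt` of one command line per simulation replaces native cluster
submission so any scheduler can drive a study.

## Analyses

* **Firing rate**: whole-window spike count / window length per cell, mean
  over cells; the window defaults to the recording minus a 50 ms onset
  transient; an optional binned mode is provided. The whole-window
  estimator is the simplest unbiased choice for stationary windows.
* **Power spectrum**: rectangular-window periodogram, mean subtracted by
  default, averaged over cells (or computed on the population-mean trace);
  total periodogram power equals signal variance (Parseval). Peak
  frequency is the argmax on a configurable band (default ≥ 1 Hz).
* **Coherence**: Welch magnitude-squared coherence between population-mean
  traces, Hann window, 50% overlap, 8 segments by default. With K
  independent segments the no-coherence bias is ≈ 1/K; interpret small
  values against that floor.
* **Raster**: time-sorted (cell, spike time) pairs.

## Fixtures — the study conditions

All worked-example models are generated by `neusim.fixtures`; none loads
external data.

* **Lorenz** uses the classic chaotic parameters (s = 10, r = 27,
  b = 2.666). Cross-solver agreement is asserted only on a 2-time-unit
  horizon, before chaotic divergence dominates.
* **Izhikevich** uses the regular-spiking parameterization (coefficients
  .01, .7, 40; a = .03, b = −2, c = −50, d = 100, vr = −60, vpeak = 35),
  identical in the equation-string fixture and the library `Izh` object so
  the two specification routes can be compared trajectory-for-trajectory.
* **Intrinsically-bursting neuron** = fast-spiking iNaF/iKDR plus the
  M-current with gm = 2.5 mS/cm² and unit temperature factor (stronger and
  slower than the library's tonic-adaptation default), under 6 µA/cm²
  drive: spike clusters separated by >30 ms pauses, i.e. bimodal
  interspike intervals.
* **Weak PING**: 16 E + 4 I cells with Wang-Buzsáki-style kinetics
  (instantaneous sodium activation, rate factor 5), leak gl = 0.1,
  El = −65; AMPA E→I (rise 0.4 ms, decay 2 ms, reversal 0 mV) and GABA-A
  I→E (rise 0.5 ms, decay tauD = 10 ms, reversal −80 mV), conductances
  scaled by source-population size (gAMPA = 1/NE, gGABAa = 0.5/NI); tonic
  drive 3 µA/cm² to E only; uniform ±5 mV random initial voltages and a
  mild white-noise current on E. These values were fixed once to place the
  rhythm near 40 Hz with the 10 ms inhibitory decay and are the conditions
  under which all reported numbers are computed. Simulated with the
  midpoint method at dt = 0.01 ms for 1 s, recorded at 0.1 ms — sizes
  chosen as the smallest network that shows the population rhythm clearly.
  The fixture emulates rhythm generation, not cortical realism: no
  conduction delays, no heterogeneous cell classes, all-to-all coupling.
  Passing tests show the mechanism is implemented correctly, not that any
  particular cortical circuit oscillates at 40 Hz.
* **Poisson-driven cells** convert input events to spikes one-for-one (a
  fast-decaying voltage kicked over threshold), so recovered firing rates
  can be checked against the Poisson rate analytically.

## Library

The packaged kinetics are canonical forms from the literature cited in
each file header (Hodgkin-Huxley 1952 iNa/iK; Wang-Buzsáki 1996
iNaF/iKDR; Traub 2003 M-current; sigmoid-threshold first-order synapses
after Kopell 2000; Jahr-Stevens-style magnesium block for the simplified
NMDA synapse; ohmic gap junction and axial coupling; Gaussian-noise,
Poisson and tonic inputs; HH, Izhikevich and leaky integrate-and-fire
populations, the last with a parameterized refractory period). iGABAb and
iNMDA are deliberately simplified single-gate variants, marked as such in
their headers. No physical-unit checking is performed anywhere; the
conventional units are mV, ms, µA/cm², mS/cm².

## Known limitations

* Synapses are clock-driven (evaluated every step); there is no
  event-driven path, so very sparse activity pays full per-step cost.
* No physical units, no spatial geometry (compartments are populations
  joined by an axial-current connection mechanism), no GUI, no C
  compilation or GPU backend.
* The expression dialect is intentionally small: no matrix literals, no
  user-defined multi-statement functions, single comparison per
  (sub)expression.
* Conditionals are global to the flattened model and rely on numpy
  broadcasting; a condition mixing states of different populations is not
  meaningful and not detected.
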