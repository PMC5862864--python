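# neusim

Equation-based, modular simulation of neural dynamical systems — with
first-class support for exploring models over parameter spaces.

`neusim` is for computational neuroscientists (and anyone integrating ODE
systems with resets) who want to go from a model written in conventional
mathematical notation, or assembled from reusable components, to simulated,
analyzed data in a few lines — without boilerplate, and with every
simulation reproducible from a seed.

## The model-composition scheme

A model is a set of **populations** (arrays of identical units, e.g.
neurons) and **connections** between them. The dynamics of each object are
given by equations in a small dialect:

```
gna=120; Ena=50                       % parameters
am(v)=.1*(v+40)/(1-exp(-(v+40)/10))   % functions
INa(v,m,h)=-gna*m^3*h*(v-Ena)
dm/dt=am(v)*(1-m)-bm(v)*m; m(0)=.05   % ODEs with initial conditions
if(v>vpeak)(v=c; u=u+d)               % conditional updates (resets)
@current += INa                       % linker statement (mechanisms)
```

Reusable **mechanisms** (ion currents, synapses, inputs) plug into host
equations through *linkers*: the host declares a placeholder (e.g.
`dV/dt = (Iapp + @current)/Cm`) and each mechanism contributes a term via a
compound assignment (`@current += INa`). At build time every symbol gets a
namespace prefix and the placeholders are replaced by the accumulated
contributions, e.g.

```
d(pop1_V)/dt = pop1_Na_INa + pop1_K_IK
```

so an arbitrary set of mechanisms flattens into one well-posed ODE system.
Connection mechanisms additionally see the presynaptic state (`V_pre`), a
connectivity matrix `netcon` (target × source, all-to-all by default), and
spike-time buffers (`tspike_pre`/`tspike_post`).

Fixed-step integration (Euler, midpoint, classic RK4) is performed by a
**generated standalone numpy program** — the solve file — which you can
inspect, save, and re-run; a variable-step delegate (scipy `solve_ivp`) is
available for smooth systems. Conditionals are evaluated elementwise after
every state update; spikes are upward threshold crossings.

Parameter spaces are described by `(object, parameter, values)` triplets
expanded by Cartesian product into a simulation batch with deterministic
per-simulation seeds; built-in analyses (firing rates, power spectra,
coherence, rasters) run as per-simulation hooks, and a study directory on
disk is self-describing and re-loadable.

## Worked example: a gamma rhythm from an E–I network

The packaged weak-PING fixture couples 16 excitatory and 4 inhibitory
conductance-based cells with an AMPA synapse (E→I) and a GABA-A synapse
(I→E, decay constant 10 ms), with tonic drive to E:

```python
import neusim as ns

model = ns.build(ns.fixtures.weak_ping())
data  = ns.integrate(model, ns.fixtures.weak_ping_options(seed=1))

spec = ns.power_spectrum(data, "E_v", transient=100.0,
                         average_cells=False, fmin=5.0, fmax=200.0)
print(spec.peak_frequency)                                  # 41.1 (Hz)
print(ns.firing_rate(data, "E", transient=100.0).mean_rate) # 38.3 (Hz)
print(ns.firing_rate(data, "I", transient=100.0).mean_rate) # 82.2 (Hz)
```

The population voltage oscillates at ~40 Hz — a pyramidal-interneuron
gamma (PING) rhythm whose period is set mainly by the inhibitory decay
time. Sweeping drive and inhibition (`examples/05_parameter_sweep.py`)
shows the expected trade-off: rates rise with `E.Iapp` and fall as
`I->E.tauD` lengthens.

More narrative scripts live in `examples/` (Lorenz from a bare string,
conditional resets with stochastic drive, a bursting neuron assembled from
mechanisms, batch sweeps, coherence analysis and the emitted solve file).

There is also a thin CLI: `neusim run`, `neusim sweep`, `neusim analyze`,
`neusim list-mechanisms`.

## Documentation

* `docs/methods.md` — models, numerical choices, defaults, and limitations
* `docs/file_formats.md` — the equation dialect, mechanism/population
  files, the JSON specification schema, and the study-directory layout
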