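"""An ODE system with a conditional reset and a stochastic drive.

The Izhikevich neuron spikes by running its voltage to a peak and being
reset by the rule if(v>vpeak)(v=c; u=u+d), evaluated after every state
update. The input function uses the uniform random builtin, drawn once per
time step from the engine's seeded stream, so runs are reproducible.
"""

import numpy as np

import neusim as ns

model = ns.build(ns.fixtures.izhikevich(stochastic=True, iapp=100))
opts = ns.fixtures.izhikevich_options(tspan=(0, 1000), seed=8)
data = ns.integrate(model, opts)

spikes = data.spikes["pop1"][0]
isi = np.diff(spikes)
print(f"{len(spikes)} spikes in 1 s "
      f"(mean rate {len(spikes):.0f} Hz)")
print(f"ISI mean {isi.mean():.1f} ms, CV {isi.std() / isi.mean():.2f}")
print(f"same seed reproduces: "
      f"{np.array_equal(ns.integrate(model, opts)['pop1_v'], data['pop1_v'])}")
# The CV > 0 reflects the noisy drive; with stochastic=False the train
# is perfectly regular after the first interval.
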