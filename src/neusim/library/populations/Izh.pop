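% Izhikevich neurons, regular-spiking parameterization (Izhikevich 2007)
% kind: population
a=.03; b=-2; c=-50; d=100; vr=-60; vpeak=35; Iapp=0
dv/dt=.01*(.7*(v-vr)*(v+40)-u+Iapp)
du/dt=a*(b*(v-vr)-u)
v(0)=vr
u(0)=0
if(v>vpeak)(v=c; u=u+d)
monitor v.spikes(0)
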