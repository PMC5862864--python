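% Hodgkin-Huxley neurons with iNa and iK currents plus leak
% (Hodgkin & Huxley 1952)
% kind: population
mechanisms iNa, iK
Cm=1; gl=.3; El=-54.4; Iapp=0
dv/dt=(Iapp-gl*(v-El)+@current)/Cm
v(0)=-65
monitor v.spikes(0)
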