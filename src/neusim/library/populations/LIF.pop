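% Leaky integrate-and-fire neurons with a parameterized refractory period
% kind: population
Cm=1; gl=.1; El=-65; vthresh=-40; vreset=-70; tref=2; Iapp=0
dv/dt=((Iapp-gl*(v-El))/Cm)*((t-tlast)>tref)
dtlast/dt=0
v(0)=-65
tlast(0)=-1e32
if(v>=vthresh)(v=vreset; tlast=t)
monitor v.spikes(-41)
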