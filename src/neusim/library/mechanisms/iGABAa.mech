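% GABA-A synapse: first-order gating with sigmoid presynaptic threshold,
% inhibitory parameters (after Kopell et al. 2000)
% kind: connection
gGABAa=.25; EGABAa=-80; tauD=10; tauR=.5
fpre(v)=(1+tanh(v/10))/2
ds/dt=fpre(V_pre)*(1-s)/tauR-s/tauD
s(0)=0
IGABAa(v)=-gGABAa*(netcon*s)*(v-EGABAa)
@current += IGABAa
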