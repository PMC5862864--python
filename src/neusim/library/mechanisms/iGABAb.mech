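% GABA-B synapse: simplified slow first-order variant of the sigmoid
% threshold synapse (synthetic stand-in for a full two-stage scheme)
% kind: connection
gGABAb=.05; EGABAb=-95; tauD=100; tauR=5
fpre(v)=(1+tanh(v/10))/2
ds/dt=fpre(V_pre)*(1-s)/tauR-s/tauD
s(0)=0
IGABAb(v)=-gGABAb*(netcon*s)*(v-EGABAb)
@current += IGABAb
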