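% AMPA synapse: first-order gating with sigmoid presynaptic threshold,
% excitatory parameters (after Kopell et al. 2000)
% kind: connection
gAMPA=.1; EAMPA=0; tauD=2; tauR=.4
fpre(v)=(1+tanh(v/10))/2
ds/dt=fpre(V_pre)*(1-s)/tauR-s/tauD
s(0)=0
IAMPA(v)=-gAMPA*(netcon*s)*(v-EAMPA)
@current += IAMPA
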