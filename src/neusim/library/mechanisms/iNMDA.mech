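% NMDA synapse: first-order gating with sigmoidal magnesium block
% (block after Jahr & Stevens 1990); simplified single-exponential decay
% kind: connection
gNMDA=.05; ENMDA=0; tauD=95; tauR=2.3; Mg=1.5
fpre(v)=(1+tanh(v/10))/2
BMg(v)=1/(1+exp(-.062*v)*Mg/3.57)
ds/dt=fpre(V_pre)*(1-s)/tauR-s/tauD
s(0)=0
INMDA(v)=-gNMDA*BMg(v)*(netcon*s)*(v-ENMDA)
@current += INMDA
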