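% Fast delayed-rectifier potassium current (Hodgkin & Huxley 1952)
% kind: intrinsic
gk=36; Ek=-77
an(v)=.01*(v+55)/(1-exp(-(v+55)/10))
bn(v)=.125*exp(-(v+65)/80)
IK(v,n)=-gk*n^4*(v-Ek)
dn/dt=an(v)*(1-n)-bn(v)*n
n(0)=.32
@current += IK
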