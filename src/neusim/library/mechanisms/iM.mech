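% Slow, M-type (muscarinic) potassium current (Traub et al. 2003)
% kind: intrinsic
gm=.75; Em=-95; Qs=3.209
aM(v)=Qs*.0001*(v+30)/(1-exp(-(v+30)/9))
bM(v)=-Qs*.0001*(v+30)/(1-exp((v+30)/9))
IM(v,mM)=-gm*mM*(v-Em)
dmM/dt=aM(v)*(1-mM)-bM(v)*mM
mM(0)=0
@current += IM
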