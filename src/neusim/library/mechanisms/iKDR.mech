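% Delayed-rectifier potassium current, fast-spiking kinetics
% (Wang & Buzsaki 1996)
% kind: intrinsic
gkdr=9; Ekdr=-90; phin=5
an(v)=.01*(v+34)/(1-exp(-(v+34)/10))
bn(v)=.125*exp(-(v+44)/80)
IKDR(v,n)=-gkdr*n^4*(v-Ekdr)
dn/dt=phin*(an(v)*(1-n)-bn(v)*n)
n(0)=.09
@current += IKDR
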