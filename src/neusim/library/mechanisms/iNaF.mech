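% Fast spike-generating sodium current, fast-spiking kinetics with
% instantaneous activation (Wang & Buzsaki 1996)
% kind: intrinsic
gnaf=35; Enaf=55; phih=5
am(v)=.1*(v+35)/(1-exp(-(v+35)/10))
bm(v)=4*exp(-(v+60)/18)
minf(v)=am(v)/(am(v)+bm(v))
ah(v)=.07*exp(-(v+58)/20)
bh(v)=1/(1+exp(-(v+28)/10))
INaF(v,h)=-gnaf*minf(v)^3*h*(v-Enaf)
dh/dt=phih*(ah(v)*(1-h)-bh(v)*h)
h(0)=.78
@current += INaF
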