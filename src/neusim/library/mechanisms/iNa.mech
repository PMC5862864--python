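% Fast sodium current (Hodgkin & Huxley 1952)
% kind: intrinsic
gna=120; Ena=50
am(v)=.1*(v+40)/(1-exp(-(v+40)/10))
bm(v)=4*exp(-(v+65)/18)
ah(v)=.07*exp(-(v+65)/20)
bh(v)=1/(1+exp(-(v+35)/10))
INa(v,m,h)=-gna*m^3*h*(v-Ena)
dm/dt=am(v)*(1-m)-bm(v)*m
dh/dt=ah(v)*(1-h)-bh(v)*h
m(0)=.05
h(0)=.6
@current += INa
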