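% Ohmic axial current connecting two compartments
% kind: connection
gCOM=.2
ICOM(v)=gCOM*(netcon*V_pre-rowsum(netcon)*v)
@current += ICOM
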