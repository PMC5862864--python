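% Ohmic gap junction (electrical coupling)
% kind: connection
gGAP=.1
IGAP(v)=gGAP*(netcon*V_pre-rowsum(netcon)*v)
@current += IGAP
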