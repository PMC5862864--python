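% Source of tonic stimulation over [onset, offset)
% kind: input
stim_amp=0; onset=0; offset=1e32
Istim(t)=stim_amp*(t>=onset)*(t<offset)
@current += Istim
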