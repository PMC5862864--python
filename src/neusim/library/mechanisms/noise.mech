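% Source of additive Gaussian current noise; amplitude scales with
% 1/sqrt(dt) so the integrated variance is step-size independent
% kind: input
noise_amp=0
Inoise(t)=noise_amp*.01*randn(1,N)/sqrt(dt)
@current += Inoise
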