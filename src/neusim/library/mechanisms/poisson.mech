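% Non-homogeneous Poisson input: per-step thinning of a rate (events/s);
% each event delivers an impulse of strength gpsn (charge per event)
% kind: input
rate=0; gpsn=100
Ipoisson(t)=gpsn*(rand(1,N)<rate*dt/1000)/dt
@current += Ipoisson
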