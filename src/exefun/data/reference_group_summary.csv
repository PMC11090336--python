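variable,younger_mean,younger_sd,older_mean,older_sd,n_younger,n_older,published_t
education,14.55,1.87,14.49,3.15,55,45,0.11
raven,84.3,9.64,68.15,12.25,55,45,7.38
mill_hill,70.75,10.04,83.79,10.67,55,45,-6.28
processing_speed,69.06,11.07,48.35,8.11,55,45,10.45
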