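# Laboratory-like recording regime: structured walking protocol, dual
# ankle+thigh sensing at 64 Hz, ~60% freeze prevalence, clean signals,
# video-precise labels, stereotyped subjects.
name: lab
prevalence_target: 0.598
sample_rate_hz: 64
n_channels: 6
noise_sd: 0.3
label_jitter_sd_s: 0.0
subject_heterogeneity: 0.10
confounder_rate: 0.0
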