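# Daily-living-like recording regime: unscripted home activity, single-site
# sensing at 128 Hz, ~18% freeze prevalence, noisier signals, jittered
# labels from asynchronous expert review, confounder pauses, and larger
# between-subject variability.
name: daily_living
prevalence_target: 0.179
sample_rate_hz: 128
n_channels: 6
noise_sd: 0.8
label_jitter_sd_s: 0.5
subject_heterogeneity: 0.35
confounder_rate: 2.0
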