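# AM input driving the transcription rate k_b (upper/lower 0.8/0.1),
# output mean calibrated to 15 copies; variance levels 0, 0.001, 0.01.
kind: on_off_sweep
regulation: transcription
modulation: am
T: 200.0
on_times: [20, 40, 60, 80, 100, 120, 140, 160, 180]
noise_levels: [0.0, 0.001, 0.01]
duration: 3.0
fix_mean: 15.0
n_replicates: 200
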