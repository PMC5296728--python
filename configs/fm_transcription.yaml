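# FM input driving k_b: amplitude fixed at 0.8/0.1, branch-width CV^2
# ("Noise") levels 0, 0.1, 1, 3; output mean fixed at 15.
kind: on_off_sweep
regulation: transcription
modulation: fm
T: 200.0
on_times: [20, 40, 60, 80, 100, 120, 140, 160, 180]
noise_levels: [0.0, 0.1, 1.0, 3.0]
fix_mean: 15.0
n_replicates: 200
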