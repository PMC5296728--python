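# Amplitude-noise refresh interval D in {3, 10, 30} s at Var = 0.01,
# degradation-regulated, output mean fixed at 15.
kind: duration_sweep
regulation: degradation
durations: [3.0, 10.0, 30.0]
variance: 0.01
on_times: [20, 40, 60, 80, 100, 120, 140, 160, 180]
fix_mean: 15.0
n_replicates: 200
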