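# Stochastic-focusing scan: FM width noise on k_d, ON/OFF ratio 1.
kind: sf_curve
regulation: degradation
modulation: fm
T_values: [20, 50, 100, 200, 400]
noise_levels: [0.0, 0.1, 1.0, 3.0]
on_off_ratio: 1.0
n_signal_draws: 200
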