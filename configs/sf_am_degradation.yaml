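# Stochastic-focusing scan: AM noise on k_d, ON/OFF ratio 0.25, varying T.
kind: sf_curve
regulation: degradation
modulation: am
T_values: [20, 50, 100, 200, 400]
noise_levels: [0.0, 0.001, 0.01]
on_off_ratio: 0.25
n_signal_draws: 200
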