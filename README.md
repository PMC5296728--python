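# pulsedecode

How much does a downstream gene learn from a pulsing, noisy transcription
factor — and what does that information cost thermodynamically?

`pulsedecode` simulates a stochastic transcription model in which a
two-level pulsatile input signal drives either the transcription rate
k_b(t) or the mRNA degradation rate k_d(t) of a birth-death gene

    DNA --k_b(t)--> mRNA --k_d(t) per molecule--> 0,

with the input fluctuating either in amplitude (AM: levels re-sampled from
a log-normal every D seconds) or in frequency (FM: branch widths drawn
with a chosen CV²).  On top of the exact non-homogeneous stochastic
simulation it estimates

* **mutual information** MI(X;Y) = Σ P(x,y) log₂[P(x,y)/(P(x)P(y))]
  between the instantaneous input level and the mRNA copy number (bits),
* **energetic cost** — the Schnakenberg entropy production rate
  σ = Σ_m (k_b P(m) − k_d(m+1)P(m+1)) ln[k_b P(m)/(k_d(m+1)P(m+1))],
  zero at detailed balance and positive under driving,
* **stochastic focusing** — the noise-induced shift of the cycle-averaged
  mean output, scored as noisy/noiseless mean ratio.

The closed-form solution of the master equation for deterministic rates —
P(m,t) is Poisson(μ(t)) with dμ/dt = k_b(t) − k_d(t)μ, μ(0) = 0 — and a
matrix-exponential master-equation integrator serve as exact oracles for
the simulator throughout the test suite.

Intended users: systems-biology modellers studying information
transmission, thermodynamic cost and noise effects in gene regulation.

## Worked example

The central experiment sweeps the signal's ON-time at fixed period
T = 200 s and scores MI and EC per grid point:

```python
from pulsedecode.experiments import sweep_on_off, mi_ec_correlation

sweep = sweep_on_off(
    "transcription", "am",                  # k_b driven, amplitude noise
    on_times=range(20, 200, 20),            # OFF-time = 200 - ON-time
    noise_levels=[0.0, 0.001, 0.01],        # amplitude variance "Var"
    n_replicates=200, seed=0, n_signal_draws=2,
)
zero = sweep.frame.query("noise == 0.0")
best = zero.loc[zero.mi.idxmax()]
print(f"zero-noise MI max {best.mi:.3f} bits at ON={best.on_time:.0f}s")
print(f"Pearson r(MI, EC) = {mi_ec_correlation(sweep):+.3f}")
```

Output:

```
zero-noise MI max 0.269 bits at ON=120s
Pearson r(MI, EC) = +0.648
```

The noise-free input transmits at most ~0.27 bits per sampled instant to
the mRNA level, the MI curve peaks at an asymmetric ON/OFF split, and grid
points that transmit more information also dissipate more entropy
(positive MI–EC correlation).  Running the degradation-regulated variant
shows EC rising steeply with input variance (0.27 → 1.02 from Var = 0 to
0.01 at ON = 100 s) and a stochastic-focusing index of ≈ 1.13.

The numbered drivers under `analysis/` run the full study — simulator
validation, AM and FM sweeps, the signal-duration sweep and the
stochastic-focusing scans — and write tables under `results/`:

```bash
python analysis/01_validate_model.py
python analysis/02_am_information_energy.py
...
```

Equivalent runs are available from the command line via shipped configs:

```bash
pulsedecode mi-sweep --config configs/am_transcription.yaml --seed 0 --out results
pulsedecode sf-curve --config configs/sf_fm_degradation.yaml --out results
pulsedecode validate
```

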