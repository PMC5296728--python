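# Methods

## Model

A single gene is transcribed and its mRNA degraded,

    DNA --k_b(t)--> mRNA,    mRNA --k_d(t) per molecule--> 0,

where exactly one of the two rates is driven by a pulsatile
transcription-factor signal: a two-level square wave with upper/lower
branch means (0.8/0.1 for transcription regulation, 0.1/0.025 for
degradation regulation, dimensionless rate units per second) and nominal
period T = ON-time + OFF-time.  The ON state is always the branch that
produces *high* mRNA, so for degradation regulation ON is the lower k_d
branch.  mRNA is an integer copy number; rate values quoted in
concentration units are used as dimensionless numbers (a target mean of
"15" means 15 copies).

Input noise takes two forms:

* **AM** — branch widths fixed; within a branch the level is re-sampled
  every D seconds (default D = 3 s, the "duration") from a log-normal
  matched to the branch mean and variance Var.  "Duration" is read as the
  refresh interval of the amplitude noise: larger D means slower input
  fluctuations.  This is a reconstruction of a verbally specified
  mechanism and is the single most consequential interpretation choice in
  the package (see "Known limitations").
* **FM** — levels fixed at the branch means; successive branch widths are
  drawn from a log-normal with the branch-width mean and squared
  coefficient of variation Noise.  Widths are free (cycles drift); the
  alternative convention that each cycle is constrained to sum to T is not
  used.

Log-normal samplers are moment-matched on the natural scale
(sigma^2 = ln(1 + Var/mean^2)); a gamma family with the same two moments
is available and leaves all qualitative results unchanged.

## Simulation

Because the driven rates are piecewise constant, the non-homogeneous
process is sampled exactly: within a segment, waiting times are
exponential with total propensity k_b + k_d m; a waiting time that would
cross the next rate breakpoint is discarded, the clock advanced to the
breakpoint, and a fresh time drawn — exact by memorylessness.  The
ensemble kernel is numba-compiled; replicate streams are spawned from a
root `numpy.random.SeedSequence`, so every result is reproducible from
(configuration, seed).

Two independent oracles check the simulator: the closed-form solution of
the master equation for deterministic rates — P(m,t) is Poisson with
parameter mu(t) solving d(mu)/dt = k_b(t) − k_d(t) mu, mu(0) = 0, advanced
exactly per segment — and direct integration of the truncated master
equation by per-segment matrix exponentials (m ≤ 60; the two agree to
machine precision, and the simulator agrees with both to Monte-Carlo
accuracy).  For random rates the marginal law is the Poisson mixture over
signal draws.

## Estimators

**Mutual information** is the plug-in estimate (base 2) on pooled pairs of
(instantaneous input level, copy number) sampled every 1 s after burn-in,
over replicates and — where requested — over independent signal
realizations.  Continuous AM levels are quantile-binned into 8 bins fitted
on the pooled levels; inputs with at most 8 distinct values (zero-noise
and FM signals) keep their exact symbols.  Pairing is instantaneous by
default; a `lag` option pairs y(t) with x(t − lag) for sensitivity
analysis (the MI maximum moves toward longer OFF-times as the lag
approaches 1/k_d).  An optional Miller–Madow correction exists but is off
by default; the pooled sample sizes (≥ 10^5) keep the plug-in bias at the
10^-3-bit level.

**Energetic cost** is the Schnakenberg entropy production rate of the
nearest-neighbour chain, natural-log units,

    sigma = sum_m (k_b P(m) − k_d (m+1) P(m+1)) ln[k_b P(m) / (k_d (m+1) P(m+1))],

evaluated with the rates in force at each grid time and the empirical
ensemble law conditional on the signal realization, then averaged over an
integer number of periods and over signal draws.  Terms with an empty cell
on either side are skipped (no pseudo-counts): a zero cell carries no flux
evidence and would otherwise diverge.  Every term is (a − b) ln(a/b) ≥ 0,
so the estimator is non-negative and carries a positive finite-sampling
bias of order (states)/(replicates); trends across conditions are
therefore compared at matched replicate counts.

**Calibration.**  Where an experiment fixes the mean output at 15 copies,
the free constant rate is set on the noise-free skeleton signal: for
transcription regulation k_d = <k_b>/15 exactly; for degradation
regulation the periodic-steady-state cycle mean is linear in k_b, so one
evaluation at k_b = 1 determines it (no iteration needed).  Calibration is
shared across noise levels so noise-induced mean shifts remain visible.

**Stochastic focusing** is scored as the ratio of the noisy to the
noise-free cycle-averaged mean output.  Conditional on the rate path the
mean is the exact mu(t), so the scan averages exact time-averaged means
over signal draws rather than sampling copy numbers — the estimator is
unbiased and far tighter than a trajectory-based one.

## Problem sizes and defaults

Sweeps default to ON-time 20..180 s in 20 s steps at T = 200 s, 200–500
replicates per point, 5 periods of burn-in, 2–4 measurement periods, and
1–8 signal draws per point (more draws where EC comparisons across
conditions must beat realization-to-realization scatter).  These desk-scale
sizes resolve every trend the package asserts; the full-scale setting
(1000 replicates, finer grids) only shrinks error bars.

## Findings the tests encode, and where the model disagrees with the claims

* Exactness: simulated ensembles match Poisson(mu(t)) and the
  master-equation integrator (TV ≲ 0.05 at 2000 replicates); equilibrium
  EC vanishes (≈ 2×10^-4 at 10^5 samples, pure estimator bias) and any
  periodic drive gives EC > 0.
* The zero-noise MI versus OFF-time is upward-convex with an interior
  maximum; MI and EC are positively correlated across the
  transcription-regulated AM grid (r ≈ +0.6).
* Degradation-regulated AM: EC grows monotonically with Var (the low-k_d
  log-normal tail is strongly dissipative), and the mean output rises
  (stochastic focusing, index ≈ 1.13 at Var = 0.01) because the
  conditional mean is convex in k_d.  Transcription-regulated AM shows
  neither effect in the mean: with constant k_d the cycle mean is
  <k_b>/k_d, linear in the input, so mean-preserving amplitude noise
  cannot shift it.
* FM width noise raises MI in both regulation modes (width fluctuations
  persist on the branch timescale, so the output resolves them) and
  induces focusing only in the degradation mode, where the conditional
  mean is nonlinear in the k_d path.  In the transcription mode the
  stationary upper-branch occupancy is E[w_on]/(E[w_on] + E[w_off]) = 1/2
  for any width CV^2, so the marginal mean is provably noise-independent
  (measured index 1.000 ± 0.004); the corresponding test states the
  claimed raise and is expected to fail.
* Slower amplitude noise (larger D) raises MI in both modes.  EC falls
  from D = 3 to D = 30 but is non-monotone in between — entropy production
  peaks when the driving timescale resonates with the relaxation time
  1/k_d — so the duration test compares the endpoints of the log-spaced
  grid {3, 10, 30} s on the degradation-regulated configuration, where
  both trends are resolvable at desk scale.
* Two further stated trends are not reproduced under this package's
  reading and their tests are expected to fail: (i) MI at fixed OFF-time
  is flat-to-slightly-decreasing in Var (with D = 3 s ≪ 1/k_d the output
  low-pass filters the amplitude noise, and noisy branch levels overlap),
  and (ii) the zero-noise transcription-regulated MI maximum sits near
  ON ≈ 120 s of 200 (OFF/ON ≈ 0.67, the mirror of the stated
  OFF ≈ 2×ON), moving toward the stated ratio only under lagged pairing.

## Known limitations

The synthetic signals are idealized two-level processes: no rise times, no
more than two branches, no coupling between amplitude and width noise, and
no extrinsic variability between replicates beyond the shared signal.
Passing tests therefore certify the simulator, the estimators and the
stated trends of this model — not the behaviour of any real promoter.
The "duration" mechanism and the MI pairing are reconstructions of
under-specified procedures; both are exposed as parameters (`duration`,
`lag`) so their influence can be audited.  EC from empirical ensembles is
bias-dominated below ~10^-1 at 200 replicates; exact-pmf EC (via the
master-equation integrator) is available for small state spaces.
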