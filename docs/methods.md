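# Methods

## Model

The system state is the scalar daily activity `x(n)` of a frontal-cortex
population, `n` counted in days. The uncontrolled dynamics are the odd map
`F(x) = B·tanh(w2·x) − A·tanh(w1·x)`; the controlled dynamics add RRO
feedback and a sinusoidal drive,

```
x(n+1) = F(x(n)) + K·u(x(n)) + S(n),
u(x)   = −(x − x_d)·exp(−(x − x_d)²/(2σ²)),
S(n)   = α·sin(2πn/p).
```

Assumptions inherited from the model family: the diurnal firing-rate
dynamics are captured by a single scalar map (no hypothalamic stage, no
spatial structure, no noise); the map is point-symmetric about the origin,
so the two chaotic attractors are mirror images and a single merging point
`x_d = 0` suffices; the feedback region width `σ = 1` covers the map's
interior extrema (located at |x| ≈ 0.9).

Parameters, units dimensionless throughout:

| parameter | meaning | default |
|---|---|---|
| `w1`, `w2` | input weights, inhibitory / excitatory | 0.2223 / 1.487 |
| `A` | inhibitory output weight (bifurcation parameter) | required, ≥ 0 |
| `B` | excitatory output weight | 5.82 |
| `K` | RRO feedback gain | 0 |
| `x_d`, `σ` | merging point, feedback-region width | 0, 1.0 |
| `α`, `p` | drive amplitude, period (steps, int ≥ 2) | 0, 32 |
| `n_transient`, `n_measure` | discarded / recorded steps | 10³, 10⁴ |
| `n_trials` | ensemble size | 10 |

Orbit lengths are our choice (no published values exist): 10³ transient +
10⁴ measured steps makes time-averaged quantities (λ, C(τ), Ξ) stable to
roughly 10⁻³–10⁻² while keeping every full experiment below a minute of CPU;
the test suite checks explicitly that doubling `n_measure` moves ensemble
means by < 0.02.

## Attractor merging

With `f_max`/`f_min` the local maximum/minimum **values** of the composite
map `g = F + K·u`, the attractors are merged iff `g(f_max) < x_d` and
`g(f_min) > x_d`. The "value" reading (apply the map to the extreme value,
not to the critical point's abscissa) is deliberate: `f_max` is the highest
point an orbit on the positive side can reach, so `g(f_max)` is the lowest
point of its image; only this reading makes the condition equivalent to the
orbit being able to cross sides, and the test suite verifies that hopping in
long driven-free orbits starts/stops exactly at the condition root.

Numerics: critical points are bracketed by sign changes of the analytic
derivative `g'` on a 4001-point grid over `[−4, 4]` (orbits are confined to
|x| < 4 in the studied regimes) and refined by Brent's method to ~1e-13;
with several maxima on one side (possible at large K) the largest map value
wins, ties broken by smaller |x − x_d|. The bifurcation gain `K*` is the
Brent root of `K ↦ g(f_max(K)) − x_d`, which the suite verifies is strictly
increasing near the root; a missing sign change on `[0, k_hi]` raises a
bracketing error rather than returning a default.

## Lyapunov exponent

Primary estimator: M perturbation segments of length τ along a reference
orbit; the displaced copy gets the same drive sequence (state perturbation
only); λ is the mean log separation growth per step. Defaults `d0 = 1e-8`,
`τ = 1`, `M = 10⁴`; with τ = 1 the estimator converges (d0 → 0) to the
exact 1-D identity λ = ⟨ln|g'(x(n))|⟩, which is implemented independently
as the derivative-based oracle; the suite requires agreement within 0.02 in
the chaotic regimes and invariance (±0.01) under halving d0. Segments with
exactly zero separation, or samples exactly at a critical point, are
excluded with a warning.

## Synchronization metrics

`C(τ)` is the Pearson correlation between `S(n+τ)` and `x(n)` over the
measurement window, with `n+τ` wrapped inside the window. Wrapping keeps
every lag a true correlation of the same sample multiset (|C| ≤ 1 exactly,
no edge truncation); for windows that are whole multiples of p it is an
exact phase shift, otherwise the bias is O(p/n_measure) ≈ 3·10⁻³. Lags
0…p−1 suffice because S is p-periodic; the suite checks that extending to
4p adds nothing. The reported score is maxτ C(τ).

Ξ is the plain time-mean of `(K·u(x(n)))² + (S(n))²`. At K = 0 and whole
periods this equals α²/2 exactly (tested to 1e-12).

Trial ensembles: `n_trials` orbits with common drive phase, differing only
in x(0) drawn uniformly from [−2.5, 2.5] (the attractor span) excluding the
unstable fixed point 0. Each trial's x(0) comes from an own RNG substream
keyed (seed, trial-index), so enlarging a grid or an ensemble never
reshuffles existing trials; this also makes K-profiles use common random
numbers across grid points. Reported spread is the population SD across
trials. There is no other stochasticity: the model is deterministic, and
these initial conditions are the only thing the seed controls, so the
ensemble emulates repeated observations of the same subject started on
different days — not measurement noise, parameter heterogeneity, or
any feature of real EEG/fMRI data.

## Experiments

* A-sweep (K = 0, α = 0): per grid point one orbit from x0 = +0.5 and one
  from −0.5 (the two-branch convention of bifurcation diagrams), λ by the
  derivative estimator, the merging condition values, detected period
  (tolerance 1e-6, max period 64), and hopping counts. Landmarks: chaos
  onset = first λ > 0; merging onset = first merged verdict; periodic
  window = the **longest** contiguous non-chaotic run (λ < 0 or period
  detected) above the chaos onset — small one-point windows (e.g. near
  A = 10.0 at step 0.1) are listed separately as minor windows rather than
  being allowed to masquerade as the healthy window.
* K-sweeps at A = 9.8 (grid to 0.3) and A = 12.0 (grid to 0.9), with and
  without drive; with drive the sweep records how far hopping persists.
* Resonance profiles: ensemble summaries over the K grid (step 0.01, 10
  trials) for each (α, p); annotated with the correlation-peak gain
  `K_peak` and the condition root `K*`.
* Forced baseline: α sweep at K = 0 (step 0.01); the threshold is the
  smallest grid α whose ensemble-mean maxτC(τ) strictly exceeds the
  reference level (by default the RRO-assisted peak at the same A); an
  unreached threshold is flagged, not raised.

## Known discrepancies and limitations

* The correlation peak sits slightly **below** the merging bifurcation: at
  A = 9.8 the profile peaks near K ≈ 0.05–0.07 against K* = 0.1058, at
  A = 12.0 near K ≈ 0.63 against K* = 0.6846. Quoted gains of ≈ 0.06 and
  ≈ 0.63 for the bifurcation itself match the measured correlation peaks,
  not the condition root; the condition root instead matches where hopping
  actually ceases (K ≳ 0.1 and ≳ 0.7), which this package treats as the
  bifurcation proper.
* At the A = 12.0 resonance gain the measured budget is Ξ ≈ 0.068
  (converged; 10⁵-step runs move it by < 1e-3), noticeably above the
  commonly quoted ≈ 0.049; the feedback term ⟨(Ku)²⟩ at that gain cannot be
  made consistent with the smaller figure under the stated formula.
* The exact merging onset in A at K = 0 is 9.546 (first merged grid point
  9.6 at step 0.1), slightly below the conventionally quoted ≈ 9.8.
* The forced-entrainment threshold at A = 9.8 measures α ≈ 0.24–0.25 for a
  0.3 reference correlation (Ξ = α²/2 ≈ 0.029–0.031). The qualitative
  claim — RRO-assisted resonance is several times cheaper than forcing —
  holds with wide margin at both A values and is asserted by the suite.
* Orbit confinement |x| < 4 holds in the studied regimes (α = 0 across
  A ∈ [5, 15], K ∈ [0, 1]; weak drive α ≤ 0.3; the strongest forced case
  A = 12, α = 1.2) but not universally: at small A (≈ 5) a strong drive
  α ≈ 1 can push orbits past 4, so the property tests cover exactly the
  regimes the analyses use.
* Out of scope: the hypothalamic circadian-pacemaker stage, coupled-map
  networks, continuous-time or spiking dynamics, noise-driven (stochastic
  resonance) baselines, and any claim about real neural recordings.
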