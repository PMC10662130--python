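# whittlemle

Whittle maximum-likelihood estimation of the monofractal exponent of
univariate time series, with exact surrogate generators and a detrended
fluctuation analysis (DFA) baseline.

Physiological signals — stride intervals, heartbeat series, postural
sway — often show scale-invariant (fractal) temporal structure whose
strength is summarized by a single exponent. This package estimates that
exponent on the unified scale α ∈ (0, 2): stationary "noises" live in
(0, 1) (α = 0.5 is white noise), non-stationary "motions" in (1, 2)
(α = 1.5 is ordinary Brownian motion). Because the Whittle estimator is
a likelihood method, it stays accurate on far shorter series (N ≈ 128–256)
than the rule-of-thumb N > 500 required by DFA — which matters when the
subjects producing the signals, for example older adults walking, cannot
sustain long recordings.

## The estimator

Let x be the z-scored series of length N, P(ω_j) its one-sided
periodogram on the Fourier frequencies ω_j = 2πj/N, j = 1..m,
m = ⌊(N−1)/2⌋, and T′(ω; θ) a model spectral density — either
fractional Gaussian noise (fGn),

    T′(ω; H) = sin(Hπ) Γ(2H+1) ω^(1−2H),        0 < H < 1,

or ARFIMA(0, d, 0) with d = H − ½,

    T′(ω; d) = (1/2π) (2 sin(ω/2))^(−2d),       −½ < d < ½.

With c = ΣP/ΣT′ matching total power, the estimate minimizes the negated
Whittle log-likelihood

    α̂ = argmin_{0<H<1} (2/N) Σ_j [ ln(c T′(ω_j; H)) + P(ω_j)/(c T′(ω_j; H)) ]

by bounded golden-section/parabolic search. A minimizer pinned to the
upper bound (≥ 0.9998 at the default tolerance 1e-4) classifies the
series as non-stationary: the first difference is re-estimated and 1 is
added, so a motion with α = 1.5 is recovered via its increments.

Also included:

* **Generators** — exact fGn via Cholesky factorization of the fGn
  autocovariance, ARFIMA(0, d, 0) via the truncated MA(∞) fractional
  filter, ARFIMA(p, d, q) with short-memory AR/MA components, and
  cumulative summation for motion-range targets.
* **DFA** — the log₂-evenly-spaced-windows variant with linear
  detrending, as the comparison baseline.
* **Benchmark** — the full simulation study (42 α levels × 120
  replicates, N = 1024, both generators, all three estimators) and the
  signal-length study.

## Worked example

Generate an ARFIMA(0, 0.3, 0) surrogate (true α = d + ½ = 0.8) and
estimate its exponent:

```sh
$ whittlemle generate --kind arfima --alpha 0.8 --n 1024 --seed 42 --out demo.txt
$ whittlemle estimate demo.txt --json
[
  {
    "family": "fgn",
    "alpha": 0.801288078981482,
    "differenced": false,
    "objective": -0.44056831825210874,
    "n": 1024
  },
  {
    "family": "arfima",
    "alpha": 0.8317899402214226,
    "differenced": false,
    "objective": -0.44723838417007616,
    "n": 1024
  }
]
$ whittlemle dfa demo.txt
alpha,0.7824934779816155
```

Both Whittle fits land near the true 0.8 within single-realization
sampling error (SD ≈ 0.025 at N = 1024); `differenced: false` says the
series was classified stationary, and `objective` is the minimized
negated log-likelihood. The DFA baseline agrees but is noisier.

The same operations are available as library calls
(`whittlemle.estimate`, `whittlemle.dfa_alpha`,
`whittlemle.arfima_filter`, ...), and `whittlemle benchmark full --out DIR`
writes the complete simulation-study records and summary.

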