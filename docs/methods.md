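# Methods

This note documents the generative model behind the synthetic data, the
signal-processing and learning procedures, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Acoustic generative model

Each A-scan is a sum of three Gaussian-windowed 2 MHz tonebursts plus white
Gaussian noise:

    x0(t) = Σᵢ Aᵢ · exp(−(t−tᵢ)²/(2σ²)) · sin(2π f₀ (t−tᵢ)) + ε(t),
    ε(t) ~ N(0, noise_std²) i.i.d. per sample.

The echo parameters follow a thin layer of suspension physics:

- **Sound velocity** `c = c₀ + k_w·(wort−12) + k_y[strain]·yeast`, with
  c₀ = 1482 m/s (water-like medium at 20 °C), k_w = 4 m/s per wt% extract
  and strain-specific yeast slopes of 8/12/5 m/s per wt%
  (S. cerevisiae / WB-06 / W 34/70). Both dissolved extract and suspended
  cells raise the effective sound velocity, moving E₂ earlier.
- **Attenuation** `α = α₀[wort] + k_α[strain]·yeast` in Np/m, with
  α₀ = 4/5/6 Np/m at 10/12/14 wt% extract and strain slopes
  18/24/12 Np/m per wt% yeast.
- **Echo amplitudes** `A₁ = A₀·r₁` (interface reflection, never enters the
  sample), `A₂ = A₀·g₂[strain]·exp(−2αd)` and `A₃ = A₀·g₃·exp(−4αd)`,
  where d = 37.5 mm is the vessel diameter; E₂ and E₃ shrink exponentially
  with yeast load.
- **Echo times** `t₁ = 12 500 ns` (buffer-rod delay), `t₂ = t₁ + 2d/c`
  (≈ 63 µs), and `t₃ = t₂ + Δ_rev` with an explicit reverberation delay
  Δ_rev = 12 000 ns. The E₃ gate at [72 000, 77 000] ns sits ≈ 12 µs after
  E₂ — far less than a literal extra 2d/c ≈ 50 µs round trip — so the E₃
  arrival is parameterized directly by Δ_rev while its amplitude keeps the
  4d attenuation path. The gating windows are treated as the authoritative
  constraint; the simulator rejects any parameter set that places an echo
  center outside its window.

**Strain separability.** The three strains differ in attenuation slope,
velocity slope, *and* the E₂ interface gain g₂ (0.50/0.55/0.45). The
per-strain gain is an artifact choice, not measured physics: it encodes
strain-dependent acoustic-impedance contrast (cell size/morphology
differences) and, importantly, keeps blank (0.0 wt%) samples classifiable.
Without it, one sixth of the dataset would be strain-agnostic by
construction and no classifier could exceed ≈ 89 % accuracy.

**Labels.** The hemocytometer surrogate is linear in the weight fraction,
`true = slope[strain]·yeast`, with slopes 245/315/165 × 10⁶ cells/mL per
wt% so the 1.0 wt% level reaches each strain's maximum observed
concentration. Measured counts add multiplicative noise
`measured = true·(1+ε)`, ε ~ N(0, 0.05²), truncated at zero; a blank counts
exactly zero. The 5 % CV is a typical repeatability figure for manual
chamber counts.

**Noise level.** `noise_std = 10⁻³` in units of the excitation amplitude.
The weakest deterministic structure (A₃ at maximum attenuation, ≈ 3×10⁻³)
then stays above the noise floor after fivefold averaging, which matches a
bench setup where echoes are visible in single shots but benefit from
averaging.

**Problem sizes.** The default simulation rate is 100 MHz with an 80 µs
record (8 000 samples); windows and the envelope length are specified in
nanoseconds and converted per rate, so the chain is rate-independent up to
discretization. 1 GHz reproduces the acquisition-rate waveforms at 10×
memory/CPU. One full-design run is 162 measurements × 50 signals, processed
one measurement at a time to bound memory.

## Signal processing

- **Filter**: the eighth-order zero-phase bandpass is realized as a
  fourth-order Butterworth (maximally flat; no family is otherwise implied)
  applied forward and backward via second-order sections — the squared
  magnitude gives the effective order 8, the phase cancels exactly, and SOS
  keeps the narrow normalized band (1.5–2.5 MHz at 1 GHz) numerically
  stable.
- **Averaging** operates on non-overlapping blocks of five consecutive
  filtered signals; partial blocks are an error. Filtering before averaging
  commutes per block (both are linear), but the order is kept explicit.
- **Envelope**: a truncated centered moving maximum of |x| with half-width
  ⌊W/2⌋ samples, W = round(1000 ns · rate). It dominates |x| pointwise by
  construction. Note the moving maximum is a morphological dilation:
  applying it twice widens the effective window rather than being
  idempotent, so the implementation and tests rely on the domination
  property (e(e(x)) ≥ e(x) ≥ |x|), not on idempotence.
- **Features**: window bounds convert ns→index by rounding and are
  inclusive at both ends. A_max/t_max come from the envelope with the
  earliest sample winning argmax ties; A_sum is the rectified sum of the
  filtered-averaged signal itself and is not normalized by window length.

## Learning procedure

The network (input → 5 → 3 → head) is implemented from first principles:
analytic backpropagation (ReLU subgradient at 0 taken as 0), Glorot-uniform
initialization with zero biases, and `scipy.optimize.minimize(method=
"L-BFGS-B")` as the optimization driver with library-default line-search
and convergence tolerances, capped at 500 iterations.

- **Early stopping**: "epoch" is interpreted as one L-BFGS iteration — the
  only meaningful unit for a full-batch optimizer. Before optimization an
  inner 10 % validation subset is removed from the training rows; after
  each iteration the candidate is scored on it, and training halts after 6
  non-improving iterations, returning the best-validation iterate. The CV
  folds stay untouched by this inner split.
- **Regularization** penalizes weights only (biases excluded), the standard
  convention for an L2 penalty on network weights.
- **Target scaling**: regression targets are optimized in units of 10⁶
  cells/mL (`target_scale=1e6`) so the MSE is well-conditioned; predictions
  are reported back in cells/mL.
- **Standardization** (zero mean, unit variance) applies to the nine echo
  features only — one-hot and ordinal covariates pass through — and is
  refit on every training partition, including inside each CV fold, via an
  sklearn `Pipeline`.

## Splitting and evaluation

Ten averaged signals per measurement each form one dataset row sharing the
measurement's label; this keeps the per-signal resolution of the
acquisition (a `collapse_per_measurement` option pools them to one row).
Because rows from one measurement are near-duplicates, the default split is
group-aware: measurements (not rows) are partitioned 80:20 with
stratification by strain, and training measurements are dealt round-robin
into five CV folds, so no measurement straddles train/test or two folds. A
`row` policy provides the literal random row split for comparison; metrics
should be expected to look optimistic under it.

The CV figure is the unweighted mean over the five folds; test metrics come
from a model refit on the full training partition. Classification reports
pool the five fold confusion matrices for the CV view. Percentages are
reported to one decimal in rendered summaries and F1 is computed from
unrounded precision/recall; full precision is retained in JSON.

## Reproducibility

Every run derives all randomness from one root seed through named
`SeedSequence` substreams (simulate, labels, split, train), so reports are
bit-reproducible given config + seed. Estimators are deterministic per
`random_state`, and L-BFGS-B is deterministic per start point.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the pipeline is self-consistent: the
feature extractor recovers the monotone attenuation and velocity structure
the simulator injects, and the compact networks recover labels generated by
that structure (held-out R² above 0.97 for the full-covariate regression,
classification accuracy above 96 %, both asserted in the test suite at the
default configuration). They do not validate the sensing principle on real
suspensions: the simulator has no multiple scattering, no temperature or
compositional (CO₂/ethanol) drift, no transducer impulse-response detail
(the four-cycle square excitation is approximated by a Gaussian toneburst
with σ = 500 ns), no fouling, and echo-to-echo interference is absent by
construction. Real-data performance therefore has to be established on
measured A-scans; the package consumes them through the same HDF5/CSV
interfaces.

## Known limitations

- The reverberation delay of E₃ is a stand-in parameterization, not a
  resolved geometric interpretation.
- The label model is linear in weight fraction; saturation or aggregation
  effects at high cell densities are not represented.
- The strain-specific interface gain makes blanks separable by strain —
  convenient for a well-posed classification benchmark, unrealistic for
  physically identical blank worts.
- With default parameters classification on synthetic data is close to
  ceiling; the synthetic benchmark measures pipeline correctness, not the
  difficulty of the real classification problem.
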