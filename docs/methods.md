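# Methods

## The model

`pemotor` simulates trial-by-trial motor adaptation with a population of
*motor primitives* whose recruitment is driven by the **prospective error**
(PE) — the movement error the learner predicts for the upcoming trial.

Primitive *i* has a Gaussian tuning curve over the PE with preferred value
μᵢ and shared width σ:

    Aᵢ(ê) = exp(−(ê − μᵢ)² / (2σ²))

The motor command is the weighted population readout x = Σᵢ Wᵢ Aᵢ(ê).
On every trial the observed movement error e drives two updates:

    Wᵢ ← λ Wᵢ + η_step · e · Aᵢ(ê)          (forgetting + error-driven learning)
    ê  ← ê + α (e − ê)                      (PE tracking)

The PE update is the steady-state Kalman predictor for an error process
that drifts as a random walk (g_{t+1} = g_t + ζ) and is observed with
sensory noise (e = g + ξ): `pe_kalman_equivalence(σ_ζ, σ_ξ)` returns the
gain for which the constant-α rule is optimal.

Trial modes: **normal** (e = p − x + ξ, with p the imposed rotation and ξ
optional feedback blur of sd σ_G), **channel** (the hand is physically
constrained, so the executed command is forced to 0 while the would-be
command `x_raw` is expressed as force against the channel wall; e = p + ξ),
and **error_clamp** (e ≡ 0). Weights and PE update in every mode.

### Gain convention

The learning rate η is quoted on the *readout* scale. The per-primitive
step is

    η_step = η · ρ₀ / (2π σ² ρ),    ρ = N / (μ_high − μ_low),  ρ₀ = 1000/360°

so that in the dense-population limit the command obeys the reduced
recursion

    x_{t+1} ≈ λ x_t + η · C₀(σ) · exp(−Δ²/(4σ²)) · e_t,
    C₀(σ) = ρ₀ / (2√π σ),  Δ = ê_{t+1} − ê_t = α(e_t − ê_t)

This is exactly the dynamics of a population of density-normalised
(probability-density) Gaussian tuning curves with 1000 primitives spanning
a full circle, and it makes every simulated quantity independent of the
primitive count N in the law-of-large-numbers regime (tests assert <2%
change between N = 1000 and N = 4000). The learning-rate *modulation*
exp(−Δ²/(4σ²)) — learning is fast when the PE is predictable and slow when
it jumps — is the mechanism behind every phenomenon the package reproduces.

### Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| λ | forgetting rate of the weights | 0.9586 | per trial |
| η | learning rate (readout scale) | 2.3913 | – |
| α | PE update gain | 0.8 | – |
| σ | primitive tuning width | 16.434 | deg |
| N | primitive count | 1000 | – |
| μ range | preferred-PE span | (−180, 180) | deg |

These defaults are the best-fit values for naive adaptation to a ±30°
visuomotor rotation; with them the effective zero-lag learning rate is
η·C₀(σ) ≈ 0.114 and the naive learning speed of an exponential fit is
b ≈ 0.15 per trial. Preferred PEs sit on a deterministic even grid
symmetric about 0 (an option for uniform random sampling exists); the grid
removes one source of simulation noise, and because all reported
quantities are ensemble averages the two choices agree. Tuning is a plain
Gaussian on the real line — no angular wrap-around — since simulated PEs
stay well inside ±90°.

## Closed forms

- **Tuning inner product.** Σᵢ Aᵢ(u)Aᵢ(v) → ρσ√π · exp(−(u−v)²/(4σ²)) for a
  dense uniform population; the brute-force sum at N = 4096 matches to
  ~1e-14 relative error over |Δ| ≤ 90°.
- **Single-trial error correction.** From the naive state, observing e once
  yields the next-trial command f(e) = η C₀ e · exp(−(αe)²/(4σ²)) — rising
  for small errors, shrinking for large ones, with its peak at
  √2·σ/α ≈ 29.05°. The same number falls out of an actual two-trial
  simulation (tested to 1e-6).
- **Blur-averaged correction.** With feedback blurred by N(0, σ_G²), the
  expected correction is E[f(e+ξ)] = η C₀ e κ^{−3/2} exp(−βe²/κ) with
  β = α²/(4σ²), κ = 1 + 2βσ_G²; it agrees with numeric quadrature to 1e-6
  and reduces to f(e) at σ_G = 0.

## Protocols and phenomena

Schedules are labelled phase sequences (training / washout / test / initial
/ opposite / relearn / clamp). Block-random schedules redraw the rotation
i.i.d. from the 7-value set (−45°…45°, 15° steps) every k trials; repeats
between consecutive blocks are allowed (the simplest reading of uniform
sampling). Washout between training and test defaults to 10 zero-rotation
trials (configurable; the underlying experiment does not pin the count).
Ensembles derive per-run seeds from a master seed with numpy's splittable
seed sequences, so growing an ensemble never reshuffles earlier runs.
Default ensemble sizes are 100 for the structural and uncertainty sweeps
and 10 for savings/interference/recovery.

- **Structural learning** (k ∈ {1,2,3}; 210 channel training trials — a
  configurable default, chosen as 7 values × 30 exposures — then washout
  and a 30-trial +30° test). Blocked training makes the PE predictable
  within blocks, so memory accumulates at the rotation-valued PEs and the
  test-phase learning speed b (exponential fit) orders b₁ < b₂ ≤ b₃.
  With perturbations redrawn every trial the expected weights are nulled —
  E[pA] factorises and vanishes — which the 200-run ensemble test verifies
  directly.
- **Uncertainty.** 50 trials of +30° with feedback blur
  σ_G ∈ {0, 18, 30, 36, 60}°; the adaptation rate B of a state-space fit
  x_{t+1} = A x_t + B e_t to the ensemble-mean trajectories decreases
  strictly with σ_G. Conditions share a master seed (common random
  numbers), which removes seed-to-seed jitter from the comparison.
- **Savings.** 30 × (+30°), 5 × (−30°), 30 × (+30°); the savings effect is
  the summed first-five-trial difference between relearning and initial
  commands (a discrete sum — the trials are discrete). The washout sweep
  (60 initial, variable washout, 20 relearn) normalises each forgetting
  rate's savings to its maximum; λ close to 1 preserves savings across
  hundreds of washout trials.
- **Anterograde interference.** +30° for 10/30/50 trials, then −30° for 50.
  Progress is the fraction of the −30° rotation compensated, −x/p; reported
  indices are the interpolated trials to 50% compensation and the
  phase-mean compensation. A start-to-final midpoint index would be
  deceived by the steep initial plunge through zero (large error ⇒ large
  first correction), so it is not used.
- **Spontaneous recovery.** 50 × (+30°), 5 × (−30°), then 50 error-clamp
  trials (default length; the clamp phase only needs to be long enough for
  the PE to settle). In the clamp the PE contracts by exactly (1 − α) per
  trial toward 0, re-activating the primitives that stored the initial
  memory: the command climbs from ≈ −5° back above +6°. The recovery
  metric is max clamp-phase x minus end-of-opposite x; `max_clamp_x > 0`
  additionally certifies that the *original* memory re-emerges (an
  opposite phase as long as the initial one overwrites it, and the clamp
  command stays below zero).
- **Perturbation-prediction rival.** Identical learning rule, but
  recruitment follows a predicted perturbation p̂ ← p̂ + α(p − p̂) (noiseless
  p; the rival reuses α since no separate rate is defined for it). During
  clamps p is unobservable, so p̂ is clamped to 0 or −30°. Because p̂ sits at
  the rotation value throughout each phase (rather than drifting to 0 as
  the PE does), the initial memory is stored at p̂ ≈ +30, never revisited,
  and the rival shows weaker recovery under either clamp convention.

## Fitting and statistics

- `exp_fit` fits y_t = a·exp(−bt) + c by profiled least squares: for fixed
  b the model is linear in (a, c), so the search is a dense 1-D grid over
  b ∈ (0, 3] followed by bounded refinement — equivalent to an exhaustive
  multi-start and immune to bad initialisation. Constant series are
  returned flagged with a ≈ 0.
- `state_space_fit` is OLS on x_{t+1} = A x_t + B e_t with B reported so
  that B > 0 means adaptation under the e = p − x error convention. An
  all-zero error series fits A alone and flags B unidentifiable.
- `fit_model_params` follows a two-stage identification. Stage 1 fits
  m·f(e) + n (f the error-correction shape) to channel-trial
  (error, next-force) pairs; only the ratio σ/α is identifiable, with
  (m, n) absorbing force units. Stage 2 ties σ = (σ/α)·α, walks α over the
  grid 0.1…1.0 (α = 0 would force σ = 0 and is excluded), and fits (λ, η)
  per grid point by nonlinear least squares against a *re-simulation of
  each subject's recorded perturbation schedule* (vectorised across
  subjects). Re-simulating the recorded protocol, rather than assuming a
  naive state at test onset, accounts for the memory the training phase
  leaves behind; on noiseless data the inversion is then exact.
  *Identifiability caveat:* with σ tied to α, the learning-rate modulation
  exp(−(e−ê)²/(4(σ/α)²)) is α-invariant, so α acts only through the PE
  tracking lag and the 1/σ readout gain — which the refit (λ, η) absorb
  almost entirely. Best-fit curves at neighbouring grid points differ by
  ~0.1° rms; any realistic motor noise (the generator's default is 5°)
  therefore swamps the α signal, and the grid point is not reliably
  recoverable from noisy data even though λ and η are (λ to ~4 decimals).
  The acceptance suite states this expectation and the corresponding test
  documents the failure mode rather than hiding it.
- `bootstrap_learning_speed` resamples subjects with replacement (3000
  draws by default), averages curves and fits b per resample.
  `randomization_test` permutes the pooled speeds (10⁴ splits by default)
  with an add-one correction so p > 0; the default alternative is the
  fixed-direction one-sided test (mean(a) > mean(b)), which — unlike a
  data-dependent "observed direction" rule — is exactly calibrated
  (uniform p under the null), as is the |difference| two-sided option.
  Sorting the pooled sample before permuting makes two-sided p-values
  exactly label-swap invariant.
- `exclude_outliers` removes values outside mean ± 3 sd computed once on
  the full sample. Note an arithmetic cap: among n values a single point
  can lie at most (n−1)/√n sd from the mean computed with it included
  (≈ 3.18 at n = 12), so the screen only just catches extreme single
  outliers in small samples.
- `moving_average` is a uniform trailing window (default 16), aligned to
  window ends; trailing (causal) alignment is the package's choice where
  centring is unspecified.

## Synthetic behavioural data

`generate_subject` drives the model through the full experiment — 84
block-random channel training trials (12 exposures × 7 values), 10 washout
trials, 30 test trials at ±30° — and records movement angles on free
trials and corrective forces on channel trials. Trial-to-trial motor noise
(default sd 5°, a typical single-trial directional variability for
ballistic reaches) enters the error feedback, so noisy subjects also learn
slightly more slowly, as real subjects do. Groups contain 12 subjects, 6
per rotation sign; `normalize_sign` flips clockwise subjects onto the +30°
convention for pooling.

The recorded channel force is, by default, the *fresh* single-trial
correction m·f(e_prev) + n (+10% peak-force noise): the observable the
stage-1 fit is defined on. A `"full"` mode records the full-dynamics
would-be command instead; its PE-history smearing inflates the identified
σ/α by ~30% (the fitting model assumes a naive state), which is worth
knowing when interpreting fits to real channel forces. Force units default
to m = 1, n = 0.

What the generator does *not* emulate: hand kinematics or manipulandum
dynamics, reaction/velocity criteria, reward effects, subject-to-subject
parameter heterogeneity, or slow drifts (fatigue, attention). Passing
tests therefore certify the analysis pipeline against the model's own
generative assumptions, not against every property of real behavioural
data.

## Numerical choices

- Simulation loops are plain per-trial updates over numpy vectors;
  problem sizes (100-run ensembles of ~250 trials at N = 1000; 50-replicate
  recovery studies at N = 256) keep the full suite and the acceptance
  script in the seconds-to-minutes range.
- Closed-form vs oracle tolerances: 1e-6 relative for quadrature
  identities, 1% for finite-N population sums.
- All stochastic entry points take explicit generators or master seeds;
  ensembles and groups spawn child seeds via `numpy.random.SeedSequence`.
- Optimisers: profiled 1-D searches for exp and ratio fits (grid +
  bounded Brent); Levenberg–Marquardt on (logit λ, log η) for the
  learning-curve stage, which keeps both parameters in their domains
  without constrained solvers.

## Known limitations

- Single reaching target only; generalisation across movement directions
  is outside the model's scope.
- The PE update uses a constant gain; a fully adaptive (Kalman) gain and
  longer PE histories are deliberate non-features.
- α is weakly identified from behavioural learning curves (see above);
  report σ/α when fitting real data.
- The sign conventions assume rotations and compensations measured in
  degrees, counter-clockwise positive.
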