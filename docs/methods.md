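# Methods

## Model and assumptions

The simulator models trial-by-trial adaptation of planar reaching to a
constant perturbation p (a lateral force in a curl field, or a rotation
angle in a visuomotor rotation; p, x and e share those units). The only
state is the learner's memory — a weight vector over N direction-tuned
primitives, or a scalar command for the state-space model. Movements are
reduced to a single scalar per trial (the compensatory command at the
trial's target direction); there is no within-movement dynamics, no
measurement noise on the error, and no multi-rate (fast/slow) memory.

Primitive tuning is Gaussian in the wrapped angular distance with a
single shared width σ; preferred directions are i.i.d. uniform on
[−π, π). Angles use the half-open wrap convention, `wrap(pi) == -pi`.

Within a trial the order of operations is fixed and exact: recruit
(compute A), read out x from the current state, observe e (forced to 0
in error-clamp trials), record, then update. Updates — including the
decay/effort terms — are applied on clamp trials too; that is the entire
mechanism of the decay results. All state persists across phases.

## Parameters

| parameter | default | meaning |
|---|---|---|
| η (primitive models) | 0.5 | population-level learning rate |
| η (state space) | 0.04 | scalar learning rate |
| ηλ₁ (weight decay) | 0.0015 | per-trial weight shrinkage product |
| ηλ₂ (effort, primitive) | 0.03 | per-trial effort product |
| ηλ₂ (effort, state space) | 0.0015 | per-trial effort product |
| N | 100 | number of primitives |
| σ | π/3 rad | tuning width |
| p | π/4 | perturbation magnitude |
| ensemble size | 20 runs | per-run PD resampling |

Forgetting strengths are specified as η·λ products because those
products, not λ alone, set the per-trial decay; the CLI exposes both
forms as mutually exclusive flags.

**Learning-rate normalization.** The per-primitive step uses η/N. With a
raw per-primitive rate of η = 0.5 the command-level error dynamics would
have gain ηG(θ,θ) ≈ 0.5 · N σ/(2√π) ≈ 11 per trial — far beyond the
stability boundary — for any plausible σ at N = 100, so the population
normalization (standard in motor-primitive models, and the same scaling
used to derive the closed-form generalization limit) is applied
throughout. It makes the command-level dynamics independent of N, with
effective error-correction gain ηG/N per trial. Analytic fixed points
are unaffected.

**Choice of σ = π/3.** The tuning width is the one free shape parameter.
With η/N normalization the command-level relearning rate is
ηG/N ≈ η σ/(2√π) ≈ 0.15 per trial at σ = π/3, which (i) lets every
100-trial relearning block of the cycled design reconverge to the
training asymptote to ~1e−7, so the weight-decay control's decay
function is flat to ~1e−11 rather than contaminated by carryover between
cycles, and (ii) keeps the generalization and decay functions clearly
peaked bells over the circle with near-baseline values at ±π. Narrower
tuning (σ ≤ π/8) leaves visible cycle-order carryover in the controls;
much broader tuning flattens the generalization curve. σ is exposed as a
configuration parameter.

## Generalization closed form

For uniformly distributed PDs, the large-N limit of G/N is the
expectation of Aᵢ(θₜ)Aᵢ(θ) over φ. In the narrow-tuning regime the
wrapped distances can be unwrapped and the Gaussian integral gives

    G/N → (σ / (2√π)) · exp(−Δθ² / (4σ²)),

with Δθ the wrapped direction difference. The implementation validates
this against deterministic quadrature of the circular integral (relative
error < 1e−6 for σ = π/8 up to Δθ = 3π/4) and against a Monte-Carlo
population of 1e5 sampled PDs (< 2%). Near the antipode Δθ ≈ π both
great-circle paths contribute and the single-Gaussian form underestimates
the (exponentially tiny) true value by up to a factor of ~2; no result
depends on that regime.

## State-space model semantics

The state-space learner stores one command per practiced direction.
Every stored command decays by (1 − ηλ₂) on **every** trial — forgetting
is context independent, the defining property of the model — and only
the performed direction receives the error increment ηe. Directions
never practiced read out as exactly 0, so the model produces zero
generalization off the trained direction and a decay function that does
not depend on the tested direction.

## Protocols and summary statistics

Simulation 1: 100 training (θ = 0, p), 100 clamp test at θ_test, 50
clamp retest at θ = 0. Simulation 2: 200 training, then K = 16 cycles of
20 clamp test trials at −π + 2πk/K plus 100 relearning trials; the k are
a seeded uniform permutation of {0…K−1}, redrawn per run, so each grid
direction is tested exactly once per run. Relearning trials keep the
training perturbation. Perturbation is constant within a protocol;
user-defined schedules may vary it per phase.

Summary statistics follow the protocols' logic: the generalization
function averages the executed commands of the first 10 test trials of
each cycle (early trials, before within-block decay accumulates); the
decay function averages x(0) over the first 10 relearning trials,
normalized by x₀, the executed command on the final training trial.
Averaging windows are configurable. Ensemble dispersion uses the sample
(n−1) standard deviation; single-run ensembles report SD as NaN.

Per-run variability comes solely from PD resampling and the per-run test
direction permutation. Seed splitting uses `numpy.random.SeedSequence`:
the base seed spawns one child per run, which spawns a basis seed and a
protocol seed, so runs are independent and platform-reproducible.

## Numerical notes

Double precision throughout; no accumulation mitigation is needed at
these scales (weight-space vs. command-space agreement stays below
1e−12 over 250-trial protocols). Clamp-trial weight decay is implemented
as the same three-term update with zero error and effort contributions,
which preserves exact elementwise geometric shrinkage. Activity vectors
are cached per wrapped direction (rounded to 12 decimals) within a run.
The dynamics are linear in p, so curves normalized by the end-of-training
command are invariant to the perturbation magnitude to rounding error.

## What the simulations do and do not show

The synthetic protocols reproduce the qualitative dissociation: effort
minimization in the primitive framework yields both a peaked
generalization function and a decay function dipping at the trained
direction; weight decay yields generalization but direction-independent
decay; the state-space model yields neither. Because the simulated
learner is noiseless and its per-run variability reflects only basis
sampling, passing these checks says nothing about fits to real
behavioral data. Known limitation of the model class: the generalization
and decay functions share one width (both are set by σ through G),
whereas behavioral reports find the decay function wider; reproducing
that difference would require multi-rate memory or error-dependent
recruitment, both outside this package's scope. With N = 100 the retest
ordering across nearby test directions can occasionally invert for an
unlucky basis sample; ensemble averages are stable.
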