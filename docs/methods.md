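# Methods

## Response models

Every family is a mixture of T isotropic bivariate normal densities centred
on the task's target locations, sharing one standard deviation σ (metres).
A trial's log likelihood is `log Σ_j w_j(t) N(r; c_j, σ²I)` where `t` is the
trial's true target, `r` the 2-D response and `w(t)` the family's weight
vector. Components are untruncated over the plane — no arena clipping — so
the log density is finite everywhere and the likelihood surface is smooth.

Weight construction per family:

- Stage tree (single/multi-cue): correct `p1·p2·p3`, local mirror
  `p1·p2·(1−p3)`, each same-landmark wrong-relation target `p1·(1−p2)/2`,
  each other-landmark target `(1−p1)/4`. In layouts without side targets the
  p2 stage does not exist: correct `p1·p3`, mirror `p1·(1−p3)`, others
  `(1−p1)/4`. With three landmarks, a stage-1 failure is read as a uniform
  draw over all four non-correct-landmark targets (not landmark-then-target),
  which keeps per-landmark chance at 1/3 and matches the two-landmark
  reading.
- Correct-Or-Guess: `pc` on the correct target, `(1−pc)/(T−1)` elsewhere.
- Exponential decay: `w_j ∝ exp(−k·d_j)` with `d_j` the Euclidean distance in
  metres between target centres.
- Structured noise: any nested 4+4 / 2+2 / singleton partition of 8 targets;
  at each level the correct branch is taken with `q_level`, otherwise a
  uniform draw over the sibling branch's leaves. There are C(8,4)/2 · 3 · 3 =
  315 distinct hierarchies; the stage tree is the landmark → side/end →
  reflection member.

All three named families coincide at their chance settings (p=0.5 each,
pc=1/T, k=0), which the tests exploit as an equivalence oracle.

σ is a free parameter of every family, fitted jointly: no fixed noise scale
is assumed anywhere.

## Canonical layouts

Exact target coordinates were never published, so the shipped layouts are
reconstructions from stated constraints, kept in versioned YAML files that
users can replace with measured coordinates:

- arctic: 2.5 m arena; two 1 m landmarks (ellipses, semi-minor 0.25 m) at a
  right angle, centres (±0.9, 0), 1.8 m apart (constraint: ≥ 1.5 m); per
  landmark two end targets ±0.6 m along the major axis (end-mirror pairs
  1.2 m apart, the one pinned distance) and two side targets ±0.6 m along
  the minor axis. The side offset is a package choice — no published figure
  pins it — made equal to the end offset for symmetry.
- jetty: three 0.8 m landmarks at mutually oblique orientations
  (0.2/1.25/2.4 rad), centres on a 1.1 m ring (pairwise 1.91 m); two end
  targets per landmark 0.5 m from centre (0.1 m past the tip, the same
  convention as the arctic ends), so mirror pairs are 1.0 m apart.

Nearest-landmark classification uses centre-to-centre distance with ties to
the lowest id. Whether the original classification used centre or surface
distance is unknowable from the text; centre distance is the simplest rule
and the two agree everywhere except a measure-zero boundary set.

One published worked example could not be used to calibrate the geometry:
the exponential-decay family at its reported fit (k = 0.058 per metre) gives
the 1.2 m mirror a relative weight e^(−0.0696) = 0.933 of the correct
target's, so its normalised weight on any 8-target layout is at least ~12% —
the reported "5%" is unreachable for any geometry (it would need the eight
weights, each ≤ 1, to sum to ≈ 18.7). The implementation keeps the model's
definition, e^(−kd) with d in metres, and verifies the likelihood against a
brute-force oracle instead; k ≈ 2.2 per metre would reproduce 5% on the
canonical layout, suggesting a units slip in the original report.

## Fitting and model selection

Maximum likelihood uses Nelder–Mead simplex search on transformed axes:
log-odds for probabilities, log for σ and k, so the search is unconstrained.
σ is parameterised as `1e-4 + exp(u)`: the floor keeps the likelihood
bounded for degenerate data (all responses exactly at one centre), which is
returned as a finite fit flagged `sigma_at_floor`. Multi-start: one
method-of-moments start (stage-wise empirical rates from nearest-target
classification; RMS distance for σ) plus seeded Halton draws over a broad
box. Defaults are 10 starts with 1e-8 simplex tolerances for single-dataset
fits; the recovery simulations use 3 starts and 1e-6 tolerances, which was
verified to reproduce single-start and 10-start winners exactly while
keeping a 100-run study to a few minutes — these 2–4 parameter likelihoods
are smooth and essentially unimodal on the transformed axes.

Cross-validation is leave-one-target-out: folds are true-target ids (all
repeats of a target travel together), parameters are fitted to the remaining
targets' trials, and the fold score is the negative sum of held-out log
probabilities. Totals across folds are compared between families; exp(Δ) is
reported as the joint-probability ratio, exact ties are flagged and broken
by fewer free parameters, then label. A restricted stage tree (p2 = p3 = 0.5
pinned, p1 and σ free) expresses the "remembers only which landmark" reading
and is always scored by the same fold structure.

### Model recovery

Datasets of 528 trials (66 per target, the equal split implied by the
design) are simulated from a chosen generator and pushed through the exact
selection procedure; 100 runs per generator, each run on its own seed
substream so a study is reproducible bit-for-bit. With the Correct-Or-Guess
generator (pc = 1/3, σ = 0.15 m — the one stated noise scale, reused for the
exponential generator) the package selects the generator on ~85–90% of runs
rather than nearly always: on the 8-target layout the stage tree *exactly*
nests Correct-Or-Guess (p1 = 0.619, p2 = 0.692, p3 = 0.778 reproduces
pc = 1/3), so the cross-validation score difference is a near-tie — mean
≈ +1.0, SD ≈ 1.15 in the simpler model's favour — and the richer model wins
the remaining runs through out-of-sample sampling noise alone. Pushing the
selection rate higher would require systematically under-optimised stage-tree
fits, which the package deliberately does not emulate. The exponential
generator (k = 1) is recovered essentially always, and recovery of the true
generator strengthens with trial count.

## Posterior estimation

The stage-tree posterior uses univariate slice sampling (stepping-out and
shrinkage), coordinate-wise over (p1, p2 where applicable, p3, log σ), flat
priors on [0,1] for probabilities and flat on log σ, initialised at the
maximum-likelihood estimate. The default chain discards the first 10% as
burn-in (a package choice; overridable). The sampler is validated against
the conjugate Beta closed form on a Bernoulli reduction.

Posterior p-draws are reported as memory rates m = (p − chance)/(1 − chance)
with chance 1/n_landmarks for p1 and 1/2 for p2 and p3; m = 0 is chance
guessing, m = 1 perfect recall, and the transform exactly inverts the
mixture p = chance + m(1 − chance).

### Probit regression on covariates

The text never states how the regression likelihood touches the trial data;
this package classifies each response to its nearest target centre and reads
off per-stage Bernoulli outcomes mirroring the stage tree (landmark correct;
given that, relation correct; given both, exact target rather than mirror —
later stages undefined when an earlier one failed). Per participant and
stage, successes k of n defined trials enter a Bernoulli likelihood with
success probability Φ(μ + b·Z + E_i); E_i ~ N(0, 1/τ) is a participant-level
error, τ has an Exponential prior with mean 100, μ and b are flat. Z columns
are the z-scored age, z-scored vocabulary raw score, and the Day-Night
combined score: z-scored average ranks of reversed-round time plus z-scored
average ranks of reversed-round errors (ranks because of outliers; a
zero-variance component contributes zero).

Sampling is slice-within-Gibbs: scalar slice updates for μ and b, one
vectorised slice update for all E_i (conditionally independent given the
globals), and a conjugate Gamma(n/2 + 1, ΣE²/2 + 1/100) draw for τ. Four
chains of 5000 samples with 1000 burn-in by default; split-R̂ and effective
sample size are computed with arviz and any stage with R̂ > 1.1 is flagged.
Tests run shortened chains (2 × 700, burn-in 200), which suffice for this
5 + n parameter posterior at n = 64.

## Synthetic cohorts

The generator reproduces the study designs: age bins of 33/35 participants
(arctic; 16 near trials each, every target twice, plus 8 far trials) and
12/15/9 (jetty; 14 near trials: the first landmark's ends twice each, the
remaining ten round-robin over the other four targets, plus 16 far trials).
Far trials carry a sentinel target id and a broad scatter — they exist for
schema fidelity only and are excluded from every analysis. Teleport
rotations are drawn from the designs' stated lists and stored but never
enter the generative model.

Default stage probabilities per bin are anchored to the published parameter
scale (0.79/0.77/0.61 for the youngest two-landmark group) and to the
printed landmark-correct rates for the other bins; σ defaults to 0.22–0.25 m,
a realistic pointing-noise scale consistent with the youngest group's
~0.6 m median error once mixture errors are included. Covariates: age
uniform in its bin; vocabulary raw score grows linearly with age plus noise;
Day-Night time and errors are monotone in one latent inhibition skill. When
a ground-truth probit link is supplied, the generator first draws covariates,
computes the covariate z-scores *with the same functions the analysis uses*,
and then passes them through the link — so a planted coefficient is defined
on exactly the scale the regression estimates.

What the generator does not emulate: egocentric-strategy contamination,
response-time structure, anisotropic or target-specific noise, far-target
geometry, and any age trend within a bin. Passing tests therefore show that
the pipeline recovers truth under the model's own assumptions, not that the
model is true of children.

## Numerical and design choices

- Weight vectors sum to 1 to ≤ 1e-12 by construction; the likelihood guards
  log(0) and returns a large penalty for non-finite values inside the
  optimiser.
- Age brackets are half-open [lo, hi) with a closed top bracket, so printed
  brackets partition cleanly.
- The canonical CSV schema is bit-exact across write/read (%.17g formatting
  and correctly-rounded parsing); XLSX is supported read-only through an
  editable column mapping and is exact to the workbook format's float
  serialisation.
- Every stochastic stage takes a seed; studies spawn per-run substreams from
  one master seed, so any report is reproducible bit-for-bit.

## Known limitations

- Deposited trial data are not bundled; analyses of the original datasets
  require pointing the readers at the published workbooks with a column
  mapping. All shipped numbers come from the package's own simulations.
- The canonical layouts are constraint-based reconstructions; distances not
  pinned by the constraints (side-target offsets, jetty geometry beyond the
  separation rule) are package choices and can shift structured-model scores
  slightly for models sensitive to inter-target distances.
- The probit regression's trial-level reading (nearest-target stage
  outcomes) is one defensible interpretation of an under-specified
  procedure; coefficient scales depend on it.
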