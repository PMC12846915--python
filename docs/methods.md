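# Methods

This note documents the models implemented in `continualtwin`, the
parameter choices that matter, the measurement windows behind every
reported metric, and the limits of what the synthetic pipeline can show.

## Task schedules

A schedule is one subject's full experiment: 3 phases × 10 blocks × 12
trials = 360 probes, with blocks labelled 1–30 globally. A block presents
each of the active task's six stimuli once per season; stimulus order is
randomised within a block, and a stimulus' summer probe always immediately
precedes its winter probe, so the winter response can be anchored on the
summer feedback just shown.

Randomisation, per subject:

- **Rule A** is uniform over [60°, 150°] ∪ [210°, 300°] (each arc carries
  mass ½). These arcs keep the rule comfortably away from 0°, where the
  two seasons would coincide and the rule would be unobservable.
- **Rule B** is rule A (Same), rule A ± 30° with a fair Bernoulli sign
  (Near), or rule A + 180° (Far). The sign is recorded in the condition
  so pooled displays can flip −30° subjects.
- **Stimulus placement**: per task, a uniformly rotated 60° lattice of six
  positions with independent Gaussian jitter (s.d. 15°). The lattice keeps
  mean spacing exactly 60°; the jitter makes placements unique.
- **Test stimulus**: one of task A's six stimuli, drawn uniformly.
- **Feedback**: the true location plus Gaussian display noise (s.d. 5°),
  resampled independently per trial; withheld on winter probes of the test
  stimulus (all phases) and on every winter probe at retest. The noise is
  drawn once when the schedule is built, so all consumers of a schedule —
  networks, agents, analyses — see identical feedback values.

All angles are stored in degrees on [0, 360); conversion to radians
happens only inside the network targets and the von Mises likelihoods.
Regenerating a schedule from the same seed reproduces it byte-for-byte.

## Twinned linear networks

Architecture: 12 one-hot inputs → H hidden units (default 50) → 4 linear
outputs ordered (sin summer, cos summer, sin winter, cos winter). No
biases, no nonlinearity: the linear chain is the simplest architecture
that can share structure across stimuli, which is exactly the capacity
under study (a single-layer map from one-hot inputs cannot transfer
anything between stimuli).

Training is online SGD (batch size 1, η = 0.01) on the masked squared
error `L = ½[(x̂ − sin θ)² + (ŷ − cos θ)²]` of the probed season's output
pair only; the unprobed pair is not penalised, and both weight matrices
are updated simultaneously from the same gradient. Targets are the
noiseless sin/cos of the true location — display noise is a property of
the feedback shown to behavioural subjects, not of the supervision signal.
Trials without feedback (test-stimulus winter; all retest winters) perform
no update, and the state is bit-identical across such trials.

Each phase of the schedule is looped `repeats_per_phase = 100` times
(networks need more exposures than humans to converge), phases strictly in
order trainA → trainB → retestA, weights never reset. Responses are
logged from the pre-update forward pass on every trial of every pass,
mirroring the respond-then-see-feedback structure of the behavioural task;
the angle read-out is `atan2(sin-channel, cos-channel)` and is
scale-invariant, so even tiny-magnitude outputs have a well-defined
direction (the all-zero origin maps to 0° by atan2 convention).

Initialisation is zero-mean Gaussian. The embedding scale is the
rich/lazy dial: σ_embed = 10⁻³ (rich) or 2 (lazy); the readout is always
initialised at 10⁻³ so it remains free to learn on top of whatever
representation the embedding provides.

### Metric windows

All behavioural metrics operate on the tidy response log and apply equally
to single-pass subjects (agents, humans) and 100-pass networks:

- **Transfer**: mean winter accuracy in block 11 (first task B block) of
  the *first* pass minus mean winter accuracy in block 10 (last task A
  block) of the *final* pass — the knowledge state directly at the task
  boundary.
- **Generalization**: mean winter accuracy of the test stimulus over
  blocks 6–10 of *every* task A pass (the second half of each pass, to
  allow rule learning first). Including early passes is deliberate: it
  measures how quickly the rule becomes available for inference, not just
  its asymptote.
- **Summer accuracy**: mean summer accuracy over the *first* task A pass
  (120 trials), matching the exposure a human gets.
- **Interference**: the mixture weight π fitted to the rule responses of
  all retest winter trials across all passes. Undefined (refused) in the
  Same condition, where the two rules coincide.
- **Chance exceedance** (subject exclusion): one-sided one-sample t-test
  of per-trial accuracies against 0.5 in blocks 9–10 of the first pass.
  Chance is 0.5 because uniform responding has expected circular error
  90° and accuracy = 1 − error/180. The choice of test is isolated behind
  this one function; any consistent level-α test would do.

Points, used only for display parity with the behavioural task, are
`round(log(1/error²))` under the natural log, floored at 0 and capped at
10, with errors ≥ 30° earning nothing; ties round to even (numpy
default). Under this reading only sub-degree errors score, which is what
an unqualified "log" implies; the floor exists because negative points are
never meaningful.

## Von Mises mixture and strategy classification

Rule responses pool each winter response minus the summer feedback shown
immediately before for the same stimulus. The interference model is

    x ~ (1 − π)·vM(θ_A, κ) + π·vM(θ_B, κ),

with both means fixed at the schedule's true rules and a single shared κ.
EM alternates responsibilities (E) with closed-form updates (M): π is the
mean responsibility, and κ solves the Bessel-ratio equation
A(κ) = I₁(κ)/I₀(κ) = R̄ for the responsibility-weighted mean resultant R̄,
by Newton iteration from the standard piecewise starting approximation.
Numerical guards: κ is clamped to [10⁻³, 10³] (the cap prevents divergent
likelihoods on point masses, the floor handles non-positive resultants);
log densities use exponentially scaled Bessel functions; the log
likelihood is asserted non-decreasing on every fit.

Restarts cover π ∈ {0.1, 0.3, 0.5, 0.7, 0.9} × κ ∈ {1, 5, 20, 80};
convergence is Δlog-likelihood < 10⁻⁶ or 500 iterations, and the best
restart by log likelihood wins. The grid and tolerance are this package's
choices (the procedure requires *a* grid; results are insensitive to it on
recovery simulations).

Classification uses single fixed-mean von Mises fits (ML κ from the same
Bessel-ratio equation): a subject *learned task B* if the θ_B fit beats
the θ_A fit on task B rule responses excluding block 11 (no opportunity to
have learned yet); learners are *lumpers* if θ_B wins again at retest and
*splitters* otherwise, with ties breaking toward splitter. Interference
analyses presuppose task B learning, since interference is defined as a
consequence of new learning.

## Hidden-layer geometry

Hidden activity for stimulus *i* is column *i* of the embedding matrix
(linear network, one-hot inputs). Dimensionality is the smallest number of
centred principal components capturing ≥ 99% of activation variance over
all 12 inputs, computed after task A training and again after task B
training. Task subspaces are the top-2 centred PCA directions of each
task's six stimuli, taken from the end-of-task-B weights (the geometry
that determines retest behaviour); the principal angles are the arccosines
of the singular values of V̂_A V̂_Bᵀ, and the first (largest-cosine) angle
is the headline number, with the second logged for diagnostics. Centring
is the standard definition of explained variance; on these data it is
immaterial (the representations are near-centred), which we verified
explicitly.

## Synthetic behavioural agents

Agents exist to close the loop on the analysis pipeline with known ground
truth. A `rule_user` responds to summer probes from a von Mises memory of
the true location (κ_memory) once past its learning-onset block, and to
winter probes by applying the active rule to the feedback just shown
(κ_rule); at retest the active rule is rule B with per-trial probability
`pi_retest`. Per-trial (rather than per-subject) rule choice matches the
exchangeability the mixture likelihood assumes; the fitted π estimates
`pi_retest` directly. A lapse parameter mixes in uniform responses;
`memorizer` and `random` strategies cover the non-rule-based behaviours
the classifier must reject.

What the agents deliberately do not model: learning dynamics (onset is a
free parameter, not a process), sequential dependencies between trials,
response biases, or reaction times. Passing recovery tests therefore shows
the *analysis* is sound — that π, κ and strategy labels are identifiable
from data generated under the model's assumptions — not that humans
conform to those assumptions.

## Cohort experiments and problem sizes

`run_condition_experiment` draws n independent schedules, trains one
freshly initialised network per schedule, and reduces the per-subject rows
to group means, standard errors, and Welch/ANOVA annotations. The default
reproduction and the acceptance script use n = 50 networks per cell; 50
keeps a full four-cohort reproduction to a few minutes on one CPU while
leaving standard errors small relative to every effect of interest (the
rich/lazy differences are all ≥ 10 s.e.m. at this n).

## Numerical and design notes

- The schedule grammar fixes 3 phases × 10 blocks × 12 trials (360
  probes): 120 trials per phase, two seasons per stimulus per block. A
  "block" is one full cycle through the active task's six stimuli in both
  seasons.
- Near-condition ± signs are sampled fairly and independently of rule A;
  derived task B rules can leave the nominal task B arcs by up to 30°,
  which is intentional (the shift, not the arc, is the manipulated
  variable).
- Far-condition task subspaces converge to *near*-orthogonality (first
  principal angle ≈ 85–88° per network) rather than exactly 90°. This is
  a property of the learned solution, not under-training: both task
  subspaces must project onto the row space of the shared summer readout,
  which leaves a few degrees of residual alignment. It is stable from 100
  to 800 passes and is unaffected by PCA centring.
- In the Same condition, task A winter predictions survive task B training
  to within a few degrees (not exactly: readout retuning to task B's
  different summer placements costs 1–4° per stimulus).

## Limitations

- Only linear networks: no ReLU or deeper variants, and no
  interference-mitigation baselines (consolidation, replay, modularity).
- The mixture model fixes both means at the true rules; free-mean or
  swap-vs-graded variants are out of scope.
- Human-facing aspects of the paradigm (recruitment, instruction,
  stimulus imagery, reaction times, onset-recall debriefing) are not
  modelled; human data can only enter through the response-log dialect.
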