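# continualtwin

Transfer and interference in continual rule learning: task schedules,
twinned linear networks, and circular-response analysis.

## The problem

When a learner masters task A and then trains on a related task B,
returning to task A reveals a trade-off: reusing what was already learned
speeds up task B (*transfer*), but reuse overwrites the old knowledge
(*catastrophic interference*). This package implements a complete
computational laboratory for that trade-off, built around a two-task
continual-learning paradigm:

- each task maps six discrete stimuli to locations on a circle in two
  seasonal contexts (summer and winter), with a fixed angular *rule*
  relating each stimulus' winter location to its summer location;
- the task B rule is either identical to rule A (**Same**), shifted by
  ±30° (**Near**), or shifted by 180° (**Far**);
- subjects train on task A (10 blocks), then task B (10 blocks), then are
  retested on task A with winter feedback withheld; one task A *test
  stimulus* never receives winter feedback, isolating within-task
  generalization.

Subjects here are *twinned two-layer linear networks* — one network per
schedule, trained by online SGD on the same trial sequence a human would
see — and *synthetic behavioural agents* with known generative parameters,
so every analysis stage can be validated by parameter recovery. The
package is for computational cognitive scientists who want to simulate,
fit, and dissect these dynamics without collecting data; externally
recorded response logs in the same tabular dialect can be analysed too.

## Models at the core

**Network.** A linear map `y = W₂W₁x` from 12 one-hot inputs (6 stimuli ×
2 tasks) through H = 50 hidden units to 4 outputs
(sin s, cos s, sin w, cos w). Each trial penalises only the probed
season's pair through the masked squared error

    L = ½[(x̂ − sin θ)² + (ŷ − cos θ)²],

updated online with η = 0.01; weights are never reset between phases.
The initial embedding scale σ selects the learning regime: σ = 10⁻³
(*rich*) yields structured low-dimensional representations, σ = 2 (*lazy*)
leans on random high-dimensional projections.

**Interference model.** Rule responses (winter response minus the summer
feedback just shown) are fitted with a two-component von Mises mixture
with means fixed at the two rules θ_A, θ_B, a shared concentration κ, and
a mixing weight π on the rule-B component, estimated by EM with restarts.
π is the probability of applying the new rule when retested on the old
task — the interference weight. Model comparison of single fixed-mean fits
classifies subjects as *lumpers* (rule B wins at retest) or *splitters*
(rule A wins).

**Geometry.** Hidden activity per stimulus is a column of W₁. The package
reports the number of principal components capturing 99% of activation
variance, and the first principal angle between the top-2 PCA subspaces of
the two tasks' stimuli (arccos of the largest singular value of the basis
inner-product matrix).

## Worked example

```python
import continualtwin as ct

schedule = ct.build_schedule(ct.NEAR(), seed=5)
results = ct.TwinnedLinearNetwork(schedule, ct.TrainConfig.rich(seed=1)).fit()
print(results.summary())

log = results.responses
print("transfer        ", round(ct.transfer(log), 3))
print("generalization  ", round(ct.generalization(log, schedule.spec.test_stimulus_index), 3))

fit = ct.fit_mixture_em(ct.rule_responses(log, "retestA"),
                        schedule.spec.rule_a, schedule.spec.rule_b)
print(fit.summary())
geometry = ct.subspace_report(results)
print("principal angle ", round(geometry.principal_angle_deg, 2), "deg")
```

Output:

```
Twinned linear network training results
==========================================
condition:        near
hidden units:     50
sigma_embed:      0.001
repeats/phase:    100
final trainA loss: 3.555e-08
final trainB loss: 2.386e-10
final retestA loss: 2.054e-20
transfer         -0.143
generalization   0.95
Von Mises mixture (fixed means, shared kappa)
==============================================
theta_A:   264.90 deg   theta_B:   234.90 deg
n obs:   6000
pi (rule B weight):   1.0000
kappa:                31.418
log likelihood:       1779.537
converged: True after 33 iterations
principal angle  0.46 deg
```

Read: this rich network learned both tasks to near-zero loss, paid only
the ~30°/180° ≈ 0.17 accuracy cost at the task switch (strong transfer),
generalized the rule to the held-out stimulus, and then applied rule B on
*every* retest trial (π = 1, total interference) because it kept both
tasks in one shared subspace (principal angle ≈ 0°). A lazy twin
(`ct.TrainConfig.lazy()`) shows the mirror profile: little interference,
weak transfer and generalization, near-orthogonal task subspaces.

Cohort-level experiments, and a command line:

```bash
continual-twin reproduce --conditions same,near,far --regimes rich --n 50 --seed 1 --out out/
```

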