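# Methods

## The task model

`prlflex` models two-alternative probabilistic reversal learning (PRL):
on each of `n_trials` trials (default 80) the participant chooses one of
two stimuli, A or B. One stimulus is "correct" (usually rewarded); the
feedback plan assigns the correct stimulus an outcome of +1 or −1 per
trial, with exactly `p_reward` of each phase's trials rewarded (default
0.8, i.e. 32 rewards and 8 misleading punishments per 40-trial phase).
The contingency reverses once, at `reversal_trial` (default 41). The
stimuli are anti-correlated: choosing the incorrect stimulus yields the
negation of the scheduled outcome, so a misleading punishment for the
correct stimulus is simultaneously a misleading reward for the other.

Conventions worth stating because the published task description leaves
them open:

- Whichever stimulus is chosen first is coded correct for the
  acquisition phase (the task is self-referential in this way), so a
  simulated agent's first trial is always "correct".
- Punishments are placed uniformly at random within each phase under
  the exact-count constraint, with at most 2 consecutive scheduled
  punishments — enforced across the phase boundary too — because a
  longer run is behaviorally indistinguishable from a brief reversal.
  Only the statistics of the original fixed sequence are published;
  any seeded schedule drawn here is one realization of those
  statistics.
- Trials are 1-based; `reversal_trial` is the first reversal-phase
  trial.

## Learning models

All four models maintain stimulus values V_A, V_B (initialized at 0,
an unbiased start) and share the softmax choice rule

    p(A) = 1 / (1 + exp(β (α − (V_A − V_B))))

with value sensitivity β ∈ (0, 5) — higher β means choices track the
value difference more deterministically — and an indifference point
α ∈ (−0.5, 0.5) capturing response bias. Outcomes are coded O ∈ {+1, −1};
the symmetric coding is what makes the counterfactual update
well-formed and gives the reward/punishment branches a clean sign test.

- **RW** (baseline): V_c ← V_c + η(O − V_c), chosen stimulus only.
- **CU**: the chosen stimulus updates toward O and the unchosen toward
  −O with the same learning rate η, exploiting the anti-correlation of
  the stimuli. High η here means strong updating after every outcome,
  including misleading punishments.
- **RP**: the RW update with separate rates η_rew (O > 0) and η_pun
  (O < 0); only the chosen stimulus updates. An outcome of exactly 0
  is rejected rather than silently assigned a branch.
- **EWA-DL**: each stimulus carries an experience weight, updated for
  the chosen stimulus as n_c ← n_c ρ + 1 with
  V_c ← (V_c φ n_prev + O) / n_c. The weight acts as a growing
  divisor: for ρ > 0 the effective learning rate shrinks with
  experience (interpolating between averaging and decaying-memory
  updating), which is the model's mechanism for perseveration; φ
  decays past payoffs and behaves as an inverse learning rate.
  Experience weights start at n = 1, which keeps the first update
  bounded for every ρ (V₁ = O/(ρ+1)). The unchosen stimulus's weight
  is frozen, not decayed, mirroring the chosen-indexed update rule.
  With n₀ = 1 and ρ = φ = 1 the value is the running mean of the
  outcome stream together with one pseudo-observation at 0.

Likelihoods are computed in the log domain by iterating the model
state along the *recorded* choices and outcomes (never re-simulated),
with a per-trial floor of log(1e−12) guarding pathological parameter
draws during sampling. A single vectorised engine evaluates any
(parameter-set × subject) batch in one pass over trials; the test
suite checks it against a naive per-trial loop built from the scalar
update functions.

## Synthetic cohorts

No trial-level data were published for the study design this package
emulates, so the generator is a first-class module. It reproduces the
six-group structure — diagnosis (ASD, TD) × age (children,
adolescents, adults) — with each group's published winning model and
group-level parameter means/SDs as generative targets (children:
counterfactual updating with η ≈ 0.19–0.26; adolescents: separate
reward/punishment rates with the TD group at β ≈ 2.5; adults: EWA-DL
with φ ≈ 0.52–0.59), and the published group sizes (64–126). Subject
parameters are drawn from normals truncated to each parameter's
support — means and SDs are all that is published, and truncation
respects the bounds. Parameter draws and task/choice noise use two
independent streams derived from the master seed so tests can vary
them separately. Ground-truth parameters are stored with every
synthetic subject; recovery testing is impossible without them.

What the generator does *not* emulate: clinical covariates (IQ, sex,
site, symptom scores), attentional lapses or response-time structure,
within-subject nonstationarity beyond what the models produce, and
any model-misspecification (each synthetic subject truly follows its
generating model). Passing recovery tests therefore demonstrates that
the estimation machinery works under the study's design and noise
levels — not that real participants follow these models.

Model-recovery cohorts (default 40 subjects per generating model) draw
parameters uniformly over each parameter's support; how the original
recovery participants were parameterized is unpublished, and
uniform-over-support is the deliberately agnostic choice.

## Behavioral metrics

Accuracy is the proportion of choices of the currently correct
stimulus (overall and per phase). Perseverative errors are
reversal-phase choices of the pre-reversal correct stimulus occurring
in runs of ≥ 2 consecutive such choices, as a proportion of
reversal-phase trials; error trials count irrespective of the feedback
each drew (a misleading reward does not interrupt a run), since
per-trial feedback conditioning is not part of the published
definition — the stricter reading is available behind
`require_negative_feedback=True`. Win-stay (lose-shift) is the
proportion of rewarded (punished) trials with a successor whose next
choice repeats (switches); the final trial has no successor and is
excluded, and an empty denominator yields NaN, never 0. The learning
criterion is operationalized as a one-sided exact binomial test of
phase accuracy against 0.5 at level .05 (27/40 passes at p ≈ .019;
25/40 does not) — the published criterion itself is not defined in
enough detail to reproduce.

## Hierarchical Bayesian estimation

Each group × model fit uses a two-level model on an unconstrained
scale: subject parameters raw_i ~ Normal(μ, σ) per parameter, with
μ ~ Normal(0, 1) and σ ~ half-Normal(1). Natural-scale parameters are
obtained by logistic squashing scaled to each support (β: 5·logistic;
α: logistic − ½; rates/decays: logistic); a probit-style squashing is a
config switch. The half-Normal(1) scale is deliberate: the group SDs
implied by the published dispersions are ~0.5–0.9 on the logistic
scale, and a much tighter SD prior would over-shrink individual
estimates by fiat.

Sampling is a purpose-built vectorised Metropolis-within-Gibbs scheme
rather than gradient-based MCMC; the likelihood's trial recursion
makes gradients awkward while the hierarchy's conditional structure is
ideal for Gibbs blocking. Per iteration and chain:

1. conjugate Gibbs update of each group mean μ_p;
2. random-walk Metropolis on log σ_p (needs no likelihood evaluation —
   σ is conditionally independent of the data given the raw subject
   parameters);
3. two interweaved non-centered block moves — a translation of
   (μ, raw) with deviations fixed and a per-parameter rescaling of
   (σ, raw) with standardized deviations fixed. These are what break
   the funnel geometry when a group SD is small, where purely centered
   updates stall (observed symptom: split-R̂ > 1.1 and ESS < 50 on
   σ_α at reduced settings; both moves restore ESS by an order of
   magnitude);
4. a random-walk Metropolis proposal per subject with a diagonal
   shape — an exponential moving average of each chain's own
   per-subject, per-parameter spread, learned during warmup — so that
   weakly identified parameters (e.g. the experience decay when a
   cohort's behavior carries little signature of it) get
   proportionally larger proposals; all subjects and chains are
   accepted/rejected in lockstep from one vectorised likelihood
   evaluation per sweep (2 sweeps by default).

Proposal scales adapt by Robbins-Monro only during warmup (targets:
0.30 for the multivariate subject blocks, 0.44 for scalar σ moves,
0.25 for the non-centered blocks), so the post-warmup chain is a
fixed-kernel Markov chain. Defaults retain 4 chains × 1000 draws
(thinning 3, warmup 1500) = 4,000 draws — sized so that the hardest
routine fit (a deliberately misspecified model on another model's
cohort, as in model recovery) clears the split-R̂ gate. Split-R̂ and bulk ESS are
computed (arviz) for all group-level parameters; any split-R̂ > 1.1
raises a `ConvergenceError` naming the offenders — the sampler never
returns silently bad draws. Identical data, config and seed give
bit-identical draws.

The "group mean" reported on the natural scale is the subject-average
of transformed parameters per draw, not the transform of μ: the former
estimates exactly the quantity a cohort table reports and is immune to
the Jensen gap of the squashing transform.

A per-subject maximum-likelihood routine (multi-start Nelder-Mead on
the unconstrained scale) serves as the non-Bayesian oracle in
shrinkage and recovery tests.

## Model comparison

Per-model pointwise log-likelihood matrices (draws × subjects, subject
as the exchangeable unit) are reduced to per-subject elpd with a
complexity penalty equal to the gap between the log posterior-mean
likelihood and the posterior-mean log-likelihood (an effective-
parameter count per subject); PSIS-LOO over subjects is the
configurable alternative estimator. Weights are pseudo-BMA stabilized
by a Bayesian bootstrap: 10,000 Dirichlet(1) reweightings of subjects,
softmax-normalization of weighted elpd totals per replicate, then
averaging. Weights are invariant to adding any constant to all
matrices, sum to 1, and collapse onto a dominant model at ~10 nats per
subject. Argmax ties break toward the model with fewer parameters
(parsimony).

## Posterior prediction and optimal learning parameters

One-step-ahead prediction evolves each posterior draw's model state
along a subject's recorded history and samples a choice from the
softmax *before* each trial's record is revealed; accuracy is matches
over draws × trials, tested against 0.5 with an exact binomial test.
This measures absolute fit: a model can win a relative comparison yet
predict barely above chance.

The optimality grids simulate agents across the learning-parameter
grid with β and α fixed, scoring mean accuracy against the currently
correct stimulus on every trial, reversal included. The published
record does not state the β used in these simulations; here β defaults
to the fitted group-level mean of the age group each model won
(CU: 1.2, RP: 2.5, EWA-DL: 1.3) with α = 0, exposed as arguments,
since the optimum is β-dependent. Grids default to 101 points for the
1-D (CU/RW) scan and 51 × 51 for the 2-D (RP, EWA-DL) scans with
2,000 simulated agents per point — desk-scale sizes chosen so a full
scan runs in minutes; the full 1,000-step × 10,000-simulation setting
is reachable through the same arguments. Grid ties break toward the
smaller parameter value; memory stays flat by simulating the grid in
bounded chunks.

Two cautions about these surfaces, found while validating against the
published optima (0.18 for CU's η; (0.96, 0.60) for RP; 0.85 for
EWA-DL's φ):

- They are extremely flat near their maxima. For CU at β = 1.2 the
  expected accuracy between η = 0.24 and 0.35 varies by < 0.002, so a
  single-run argmax wanders that plateau, and for RP the η_pun
  coordinate wanders a similarly flat ridge. Surfaces should be read
  with their standard-error columns, not reduced to the argmax alone.
- Under this package's task implementation and β defaults the CU
  optimum lands at η ≈ 0.24–0.35 (reproducing 0.18 requires a
  *non-reversing* 80:20 environment, a reading inconsistent with the
  EWA-DL optimum, which matches 0.85 only *with* the reversal), and
  the RP surface's true maximum sits at η_pun ≈ 0.46–0.48 rather than
  0.60. The EWA-DL φ optimum (≈ 0.84) and RP η_rew optimum (≈ 0.96)
  reproduce well. The corresponding acceptance checks assert the
  published values and are left failing rather than loosened.

## Known limitations

- The sampler is random-walk based; for much longer sequences or many
  more parameters per subject a gradient-based sampler would scale
  better. At the study's scale (80 trials, 3–4 parameters, ≤ 130
  subjects per group) mixing is adequate and checked.
- Exact reproduction of the original fits is impossible in principle:
  the raw data, the exact fixed feedback sequence, and the original
  priors/transforms are unpublished. All estimation choices here are
  stated conventions, not reproductions.
- The likelihood floor (log 1e−12 per trial) introduces a bias that is
  zero in practice for any parameters the posterior visits; it exists
  only to keep early warmup finite.
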