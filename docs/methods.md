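# Methods

## The task being modeled

An observer watches a demonstrator play a two-armed bandit (two fractal
stimuli; constant Bernoulli reward rates 70% / 30% within a block), first
predicting the demonstrator's choice, then choosing for themselves.  Their
own outcome is hidden in the observational conditions, so everything they
learn comes from the demonstrator.  Five conditions cross the visible
information (Action-Outcome: the demonstrator's outcome is shown;
Action-Only: it is scrambled) with demonstrator quality (superb / bad), plus
an individual-learning condition used only as a behavioral baseline.  Each
of two visits (one per stimulation site: vertex control, dmpfc
downregulation) has 3 sub-sessions x 5 conditions x 2 blocks x 11 trials =
330 trials; the first trial of every block has no observation phase.

The package simulates this design (`obslearn.task`), implements six
candidate learning models (`obslearn.models`), fits them hierarchically
(`obslearn.inference`), and runs the validation program — parameter
recovery, model recovery, stimulation-effect simulation, model-free
summaries (`obslearn.validation`).

## The internal simulation of the demonstrator

The observer simulates the demonstrator with a Rescorla–Wagner learner:

    Q_d(a) <- Q_d(a) + alpha_dem * (r - Q_d(a))
    p_d(a) = logistic(beta_dem * (Q_d(a) - Q_d(b)))

`alpha_dem = 0.2`, `beta_dem = 9` are fixed for all subjects and models,
chosen by a maximum-likelihood grid search over demonstrator traces
(`grid_search_sim_params`, alpha in 0.1..1 by 0.1, beta in 1..10 by 1; ties
break toward the smallest alpha, then beta).  Simulated values start at the
uninformative midpoint 0.5 and reset at every block boundary (each block has
fresh stimuli).  In Action-Only blocks no outcome is visible, so the
simulation is driven by a pseudo-reward of 1 for the chosen option — it then
tracks choice tendencies, which is all the entropy computation needs.  This
driver is a package decision (the task leaves it open) and is exposed in the
code.

Because `alpha_dem` and `beta_dem` carry no subject-level free parameters,
the per-trial predictability sequence depends only on the data.  The
sampler therefore precomputes it once per dataset; the pure-Python model
runner recomputes it trial by trial, and a test pins the two paths to exact
agreement.

## The six models

Shared machinery, per observed trial:

* outcome channel (Action-Outcome only): `Q_out(a) <- Q_out(a) + alpha * (R - Q_out(a))`
  for the chosen option;
* action channel (all observed trials): `Q_act(a) <- Q_act(a) + kappa * (A - Q_act(a))`
  applied to both options (chosen toward 1, unchosen toward 0), so the pair
  behaves as complementary accumulated choice probabilities;
* mixing: `V = w*Q_out + (1-w)*Q_act`, with `w = 0` forced in Action-Only;
* response: `p(a) = logistic(beta*(V(a)-V(b)) + rho*(C(a)-C(b)))` where C
  indicates the previous response (both zero on a block's first trial).
  With this sign convention positive rho is stickiness; the repelling
  convention is available via `sticky=False`.

Predictability: `pred = 1 - H(p_d)` with base-2 entropy, so both entropy and
predictability live on [0, 1] for two options.  Accumulated predictability
follows `AcP <- AcP + upsilon * (pred - AcP)`, starting at 0 (an unfamiliar
demonstrator is maximally unpredictable).

Stimulation mechanisms (dmpfc sessions only; tau = 1 is always a no-op):

| model | outcome rate | action rate | tau acts on |
|---|---|---|---|
| 1 outcome | alpha/tau | kappa | outcome learning |
| 2 action | alpha | kappa/tau | action learning |
| 3 action-outcome | alpha/tau | kappa/tau | both (shared tau) |
| 4 predictability-outcome | AcP | kappa | upsilon/tau in the AcP update |
| 5 predictability-action | alpha | AcP | upsilon/tau |
| 6 predictability-both | AcP | AcP | upsilon/tau |

Within a trial the order is: prediction response (pre-observation values) →
observe action/outcome → belief step → predictability and AcP update →
value updates (AcP models use the just-updated AcP) → own choice
(post-update values).  This order lets learned predictability modulate the
current trial's learning, which is the mechanism the predictability models
express.

Parameter ranges: alpha, kappa, w, upsilon in [0,1]; beta in [0,30]; rho in
[0,3]; tau in [0,10].  Effective rates alpha/tau, kappa/tau, upsilon/tau may
exceed 1 when tau < 1; they are deliberately not clamped — the model runner
raises a diagnostic warning, and the sampler treats any resulting
non-finite likelihood as a rejected proposal (upsilon/tau > 2 makes the AcP
recursion divergent).  Both behavior streams (choice for self; prediction of
the demonstrator's action) use the same latent learning machinery and are
fitted separately with stream-specific beta, rho and tau; the prediction
stream's perseverance indicator is the previous prediction.

## Synthetic data generation

`simulate_observer` drives exactly the same `ModelRunner` the likelihood
uses, so simulated data and fitted probabilities cannot drift apart.  The
superb demonstrator is a Q-learner (alpha = 0.3, softmax temperature 9 —
the temperature is a package default, exposed in the design config) with
block-level rejection sampling until the proportion of better-option choices
lands in [0.70, 0.90] (8 or 9 of 11 trials), capped at 10,000 attempts; the
bad demonstrator chooses uniformly.  Demonstrator traces are generated
fresh per block by default; pre-generated traces can be injected.
Individual-condition choices come from a standard Q-learner on own outcomes
(rate 0.3, the subject's beta and rho) and are excluded from fitting.

What the generator does *not* emulate: response-time structure, lapses and
attention drift, stimulus-identity effects, session-order effects, and any
subject-level correlation between parameters.  Passing recovery tests on
these data therefore show that the estimation machinery is correct and the
models are identifiable under the assumed generative process — not that real
participants obey it.

## Hierarchical estimation

Unit-scale subject parameters map linearly onto their native ranges and are
given group-level beta densities with shape a = m*s, b = (1-m)*s, where
m ~ U(0.001, 0.999) and s ~ U(0.001, 10).  Sampling is
Metropolis-within-Gibbs: component-wise Gaussian random walks on each
subject parameter (vectorized across subjects, which are conditionally
independent given the hyperparameters), then random-walk steps on each m and
s.  Proposal scales adapt toward ~35% acceptance during burn-in only.
Initialization draws hyperparameters from the middle of their ranges and
subjects from the implied beta; a non-finite initial likelihood triggers a
restart (up to 20 attempts).

The study-scale schedule (3 chains x 40,000 iterations, burn-in 10,000,
thinning 5) retains 18,000 draws per parameter; the reduced desk schedule
used by tests and the bundled experiments (3 x 4,000, burn-in 1,000,
thinning 5) retains 1,800.  Retention counts must divide exactly or the
configuration is rejected.

DIC uses D-bar (posterior mean deviance) and D-hat evaluated at the
posterior means of the *unit-scale* subject parameters (the point estimate's
scale is a package decision; unit scale is transform-consistent and
bounded), p_D = D-bar − D-hat, DIC = D-bar + p_D.  Split-R-hat is computed on
all hyperparameters and a warning is raised if any exceeds 1.05 when DIC is
requested.  Comparisons require identical data hashes; ties break by model
id and are flagged.

## Validation experiments and problem sizes

* Parameter recovery (`parameter_recovery`): instances are Latin-hypercube
  points over the unit-scale group means (kept in [0.05, 0.95] to avoid
  degenerate groups); subjects scatter around each instance mean with beta
  precision 10 (the midpoint of the precision hyperprior).  Recovered values
  are posterior-mean subject parameters; correlations pool subject-level
  pairs across instances.  The bundled experiment uses 10 instances x 30
  subjects with the reduced schedule (~7 minutes on one core).
* Model recovery (`model_recovery`): generating parameters are beta draws
  around realistic mid-range values with tau = 5 so the stimulation
  mechanism is expressed; all candidates are fitted and the DIC winner
  tabulated.  Row sums of the confusion matrix are conserved by
  construction and checked.
* Stimulation-effect simulation (`stimulation_effect_simulation`): matched
  seeds and subject parameters across tau arms, so the tau = 1 arm is
  draw-for-draw identical to an unstimulated run; reported per condition in
  dmpfc sessions.
* Model-free summaries (`behavior_summaries`): per subject x site x
  condition proportions (better-option choices, correct predictions,
  imitation defined as same-trial agreement with the demonstrator),
  vertex-minus-dmpfc differences, and Pearson correlations against supplied
  parameter deltas with two- and one-sided p-values.

## Numerical choices and limitations

* Logistic and log-likelihood accumulation use softplus forms; no
  probability is ever materialized as exactly 0 or 1.
* All randomness flows through explicit `numpy.random.Generator` objects
  seeded hierarchically from one master seed; every experiment is
  bit-reproducible given its seed and schedule.
* The sampler is a general-purpose MCMC whose correctness is checked by
  simulation (recovery of generating values), not a reimplementation of any
  particular Gibbs sampler; with short schedules the split-R-hat warning
  should be taken seriously.
* Model 3 uses a single tau shared by both channels; distinct per-channel
  divisors would add one parameter and are not implemented.
* The likelihood conditions on observed responses; it does not model
  missing trials beyond the structurally absent first-trial observation.
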