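# Methods

This note documents the models, the synthetic-data generator, the fitting
and comparison machinery, and the numerical and design choices behind
`explorepredict`. Everything stated here is computed by the package's tests
or by `scripts/acceptance.py`; nothing rests on external data.

## Task environment

States are the three islands, actions the three plane colors. The
instructed rules are a bijective color→island map (pink→palm,
green→volcano, orange→lighthouse) and a single 3-cycle route
(volcano→lighthouse→palm). Because the map is a bijection and the route a
fixed-point-free cycle, offering exactly the two colors that do *not* map
to the current island guarantees that precisely one offered plane is
diagnostic of the hidden condition on every trial. The offered-plane rule
is not fully pinned down by the task description; this derivation is the
only rule consistent with the worked example in the task's figure and with
one-diagnostic-choice-per-trial, and it is exposed as a replaceable policy.

A main session has 360 exploratory trials in 12 condition blocks
(alternating controllable/uncontrollable, 11 switches). Block lengths are
the multiset {18, 24, 30, 30, 36, 42} taken twice and shuffled per seed.
Restricting block lengths to multiples of 6 makes every condition switch
fall on a probe-set boundary (probes occur after every 6 exploratory
trials; the admissible 18–42 range contains exactly these multiples). The
session splits into 4 runs with transition fidelities (0.9, 0.8, 0.9, 0.8);
run lengths default to (90, 90, 90, 90) and a seeded sampler draws lengths
in [72, 108] (multiples of 6, summing to 360) when enabled. Start state and
start condition are uniform per seed and configurable.

Each probe set queries the two planes offered from the *current* island
(the outcome of the last exploratory trial), in random order, then asks for
the condition. Exactly one of the two state predictions is reinforced,
chosen uniformly; its correctness is judged against a freshly sampled
environment outcome at the current fidelity, because the task displays a
realized flight. Analysis-level accuracy, by contrast, is scored against
the nominal (rule-consistent) destination under the true condition — the
two conventions serve different roles and both are configurable. Whether
the original task queried the current island or a random one is not
documented; the current island is assumed.

The training phase has 48 deterministic exploratory trials (fidelity 1),
8 probe sets, the condition announced, feedback on every prediction, and
the two conditions in two 24-trial halves.

Trials are 0-indexed in memory and 1-indexed in exported CSV files.

## Learning models

The four models and their free parameters:

| model     | parameters                              | k |
|-----------|------------------------------------------|---|
| Spectator | α, β_choice                              | 2 |
| Actor     | α, β_choice                              | 2 |
| LTS       | α, α_Ω, β_Ω, bias_Ω, β_choice            | 5 |
| Task Set  | α_Ω, β_Ω, bias_Ω, β_choice (α ≡ 0)       | 4 |

α, α_Ω ∈ [0, 1] are learning rates; β_Ω ≥ 0 and bias_Ω ∈ ℝ shape the
sigmoid mapping the controllability evidence Ω onto the arbitration weight
ω; β_choice ≥ 0 is the softmax inverse temperature. The per-transition
subscripts sometimes attached to the delta-rule learning rate are read as
index decorations on a single scalar rate per model (each model has at most
two learning rates). Learned tables start uniform (1/3); Task Set tables
are frozen 0/1 encodings of the rules; Ω starts at 0.

Decrementing unobserved transitions by the factor (1 − α) is both the
delta rule toward 0 and an exact normalization preserver, so every row sums
to 1 after any update (tested to 1e−9 under random update sequences).

The Ω update uses the two components' **pre-update** predictions of the
realized next state, and Ω is updated before the tables. The printed
mixing equation contains a max over departure states in the actor term; the
default implementation uses the current departure state's row (under which
the mixture needs no renormalization), and the literal max-over-states
reading is available as `eq5_actor_max=True` (renormalized). For Task Set
the two readings coincide because the color rule is state-independent. The
softmax normalizer sums over all three islands — the only normalizing
reading of the response rule — and is computed in log space, so no
probability clipping is needed in the likelihood.

Updates occur after every exploratory trial and after reinforced state
predictions. What an *incorrect* reinforced prediction conveys is not
documented, so three feedback modes are implemented:

* `asymmetric` (default) — correct feedback is a full observation of the
  realized transition (including the Ω update); incorrect feedback only
  multiplicatively decrements the predicted island (renormalized), with no
  Ω update because no realized state is revealed;
* `full_observation` — the realized outcome is always observed;
* `correct_only` — incorrect feedback is ignored.

Condition responses threshold the arbitration weight: controllable iff
ω > 0.5, ties toward uncontrollable. Spectator and Actor have no
arbitrator; simulated agents of those classes carry an auxiliary Ω-tracker
(fixed α_Ω = 0.2, β_Ω = 20, bias 0) fed by the agent's own learned
component prediction and a uniform 1/3 for the component it does not learn.
The tracker is used only for condition responses, never for state
predictions. Under this construction Spectator and Actor condition
accuracy sits near chance under either exploration policy, while LTS is
clearly better under random exploration and Task Set clearly better under
diagnostic exploration — the qualitative policy-by-model ordering the
simulation experiment checks.

## Synthetic cohorts

The default cohort emulates the study design being modeled: 90 agents, 30
per age band (8–12, 13–17, 18–25 years, ages uniform within band). Age is
a purely synthetic covariate driving three monotone links: the Task Set
mixture weight rises 0.60 → 0.95 from age 8 to 25 (remainder split among
Spectator/Actor/LTS with the Spectator share falling 0.6 → 0.2); the
diagnostic-choice propensity rises 0.40 → 0.75 (bracketing the ~40% and
~71% halves reported for a median split on diagnostic choices); parameter
distributions are age-independent by default. Generating distributions:
α, α_Ω ~ Beta(2, 4); β_Ω ~ LogNormal(ln 10, 0.5); bias_Ω ~ Normal(0,
0.15); β_choice ~ LogNormal(ln 8, 0.5). The empirical fitted posteriors
these stand in for were published only graphically, so the defaults are
plausible-range choices and fully configurable. Default probe lapse rate
is 0.05 (uniform response); recovery runs use lapse 0 because the fitted
models contain no lapse parameter.

What the generator does **not** emulate: response times, working-memory or
questionnaire measures, within-session parameter drift, and any
age-behavior link beyond the configured monotone mixtures. Passing tests
therefore validate the pipeline's internal consistency on data whose
generative process is exactly the model class, not behavioral realism.

Randomness is hierarchical: every agent derives independent schedule,
environment and response streams from its own `SeedSequence` child, so
per-agent results are invariant to cohort size.

## Fitting and model comparison

Likelihoods replay the full event stream and accumulate −log softmax
probability of the logged island over the 120 state predictions; condition
predictions and unreinforced predictions contribute nothing. The replay
has two implementations: a readable reference learner and a numba-compiled
kernel used by the optimizer; the test suite holds them to 1e−9 agreement
(and both to an independently written brute-force oracle at 1e−12 on a toy
stream).

Fitting maximizes the posterior in unconstrained space — logistic
transform for rates, log for β_Ω and β_choice, identity for bias — with
independent Normal(0, 1.5) priors per transformed parameter (the original
study's prior moments are unpublished). Optimization is Nelder-Mead
(xatol = fatol = 1e−6) from 10 seeded latin-hypercube starts in
[−2, 2]^k; non-convergence is flagged, not raised. BIC = k·ln(120) +
2·NLL with the likelihood term evaluated at the MAP optimum (no separate
ML refit) — both common-practice choices where the original procedure is
unspecified. A zero-parameter guessing baseline (NLL = 120·ln 3) anchors
the comparison.

Group comparison assigns each agent its lowest-BIC model (ties to fewer
parameters) and runs random-effects Bayesian model selection with −BIC/2
as log evidence: a variational Dirichlet(1) scheme estimates population
frequencies, and exceedance probabilities come from 100,000 seeded Monte
Carlo draws of the Dirichlet posterior.

## Recovery analyses and their limits

Model recovery simulates agents per model from the default generating
distributions with an epsilon-diagnostic(0.6) policy, refits all four
models, and reports the confusion matrix of generating versus best-fitting
model; parameter recovery refits the generating Task Set model and reports
native-space Pearson correlations. Both are deterministic given the seed.

Two identifiability limits are worth knowing, and the package reports them
honestly rather than papering over them:

* **LTS vs Actor.** Under the default generating distributions the LTS
  model's likelihood advantage over the Actor (typically 3–7 nats per
  session) often falls below the BIC penalty for its 3 extra parameters
  (1.5·ln 120 ≈ 7.2 nats), because outside the windows just after a covert
  switch the learned action-conditional table mimics the mixture. The LTS
  diagonal of the confusion matrix is therefore far below the other three
  (≈0.4 at 25 agents/model) under these distributions. This is a property
  of the generating regime, not an optimizer failure: the fitted penalized
  objective is never worse than the objective at the generating
  parameters (tested).
* **Saturation of β_choice and β_Ω.** The softmax argument gap is bounded
  by 1, so likelihoods flatten for β_choice beyond ≈8, and a sigmoid slope
  β_Ω beyond ≈10 makes ω effectively a step function. Generating values in
  those regions (which the default LogNormals produce often) are compressed
  on recovery, capping the native-space correlations for these two
  parameters well below those for α_Ω and bias_Ω. Narrower generating
  distributions concentrated below the saturation points recover
  substantially better; both are fully configurable.

## Derived statistics

* Mutual information I(S; A) over exploratory (departure, chosen plane)
  pairs uses the plug-in estimator with base-2 logs, zero-count cells
  contributing 0, no bias correction.
* Reversal alignment bins probe trials by probe sets since the last
  condition switch (bin 0 = first probe set after a switch).
* The median-split contrast splits agents at the median diagnostic
  proportion and compares covariate-accuracy Pearson correlations between
  halves with the two-sample Fisher r-to-z test.
* The ω read-out check fits, per agent, a univariate logistic regression of
  condition predictions on ω at the probe (ω standardized within agent),
  then a one-sample t-test of slopes against 0. Slopes are capped at ±25
  under (quasi-)separation; agents with constant ω are excluded with a
  warning.
* Mixed-effects analyses are out of scope: the package emits tidy per-trial
  tables for external mixed-model software.

## Problem sizes

Default analysis scales, chosen to keep full runs comfortable on a single
CPU while leaving Monte Carlo error well inside the tolerances being
checked: 1,000 schedules for structure sweeps, 60 random-policy sessions
(≈10,800 low-fidelity transitions) for the fidelity check, 25 agents per
model (100 fits × 4 models, 10 multistarts each) for model recovery, 40
agents for Task Set parameter recovery, and 20 agents per cell for the
policy-by-model simulation experiment. All are arguments.
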