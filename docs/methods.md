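# Methods

## Task model

Each trial is a two-stage Markov chain. Stage 1 presents (training) or
offers (test) one of two cues: *free*, leading to a terminal state with a
self-determined choice between two targets `a1`/`a2`, or *forced*, leading
to a terminal state whose action is mandated. Reward is Bernoulli with the
probability attached to the *displayed* target. Experiments 1–2 use six
states (one forced terminal target); experiment 3 adds a second forced
terminal target (seven states) so that *incoherence* — a probability that
the displayed target is swapped relative to the emitted action — can be
applied after both options.

Canonical schedules (`build_config`):

| experiment | blocks | training per option | test |
|---|---|---|---|
| exp1a | P = 0.5, 0.75, 1 (free targets P / 1−P; forced P) | 48 (24 when P = 1) | 48 |
| exp1b | P = 0.5, 0.67, 0.83, 1 | as exp1a | 48 |
| exp2 | free fixed 0.75/0.25; forced 0.75, 0.85, 0.95 | 40 | 40 |
| exp3 | all P = 0.75; incoherence 0, 0.15, 0.3 | 40 | 40 |

Block order is permuted per seed; exp2 always starts at forced = 0.75 and
exp3 at incoherence 0. The "minimum of 40 trials" in exps 2–3 is read as
40 training trials per option plus 40 test trials, mirroring exp1's 48/48
structure; exp1b reuses exp1a's counts. Training interleaves free- and
forced-type trials uniformly at random under the equal-count constraint.
Screen side is not modelled (actions are abstract), and no stimulus
timing, early-press handling, or reaction times are simulated.

## Learning model

One-step temporal-difference learning with no discounting (none appears in
the update equations; γ = 1) and no eligibility trace: terminal reward
reaches stage 1 only through the learned stage-2 values. Within a trial
the decision probabilities are emitted from pre-update values, then the
stage-1 backup is applied using pre-update stage-2 values, then the
stage-2 outcome update. Stage-1 cue values are shared across blocks within
an experiment (the cues are reused; fractal targets are unique per block,
so stage-2 tables are per block); `share_stage1=False` switches to fully
per-block tables.

Free parameters and units (Q and rho in reward units, one reward = 1):

| parameter | meaning | support | prior |
|---|---|---|---|
| alpha1, alpha2 | learning rate per stage | [0, 1] | Beta(1.1, 1.1) |
| tau1, tau2 | softmax temperature per stage | > 0 | 1/tau ~ Gamma(1.2, scale 5) |
| beta | pessimism weight (pessimistic target only) | [0, 1] | Beta(1.1, 1.1) |
| rho | free-choice bonus | real | N(0, 1) |
| kappa | stage-1 stickiness | real | N(0, 1) |
| b | static free-cue bias (supplementary) | real | N(0, 1) |

Following the printed reward equation, rho is added to *every* free-option
stage-2 outcome — unrewarded trials included, and during training as well
as test, so trained values carry the bonus into test. The stickiness
indicator resets at the first test trial of each block (training has no
stage-1 choices). Incoherent trials credit the *emitted* action with the
reward as delivered; model fits were only ever reported for the coherent
experiments, so this choice matters only for simulation completeness.

## Fitting and model comparison

The likelihood of a subject is the sum of log softmax probabilities over
all modelled decisions — stage-2 choices of free-type trials in both
phases plus stage-1 choices in test — under an exact replay of the
updates, one parameter set across all blocks and phases. Forced key
presses contribute no term. MAP estimation uses L-BFGS-B with 10 restarts
drawn from the priors, bounds alpha, beta ∈ [0, 1] and 1/tau ≥ 0
(optimisation is on the inverse-temperature scale, so a flat policy is the
interior-limit 1/tau → 0 rather than a singularity), and rho, kappa, b
unbounded. A restart counts as converged when the optimizer reports
success; the best converged restart wins, a warning is issued if any
failed, and an error is raised only if all fail. Logs with zero modelled
decisions are rejected.

BIC = k·ln(n_obs) − 2·logL at the MAP estimate, with n_obs the number of
modelled decisions (each is one likelihood term, so it is the natural
sample size for the penalty). Schwarz weights are the max-stabilised
normalised exp(−ΔBIC/2). Per-subject selection pools all 48 family specs
at both Q-initialisation values (0 and 0.5) into a single weight
computation and takes the argmax — equivalent to "select the best
initialisation per subject" under max weight; exact ties break toward
fewer free parameters, then lexicographic spec name. The bonus-versus-
static-bias comparison is a separate two-model weight computation, never
pooled into the 48.

Numerical notes: softmax terms are computed as stable log-sigmoids of
utility differences (no overflow at extreme inverse temperatures); prior
densities are closed-form (log-Beta / log-Gamma / log-normal) and −inf
outside support, mapped to a large finite penalty inside the optimiser;
the replay core is numba-compiled over flat per-trial integer arrays and
is verified against a straight-line dict-based reimplementation to 1e−12.

## Synthetic data

The generator emulates the published trial structure exactly: scheduled
stage-1 cues during training, agent-chosen free stage-2 actions, mandated
forced actions (uniformly drawn between the two forced targets in exp3),
softmax stage-1 choices in test, and Bernoulli rewards on the displayed
target. Cohort members get independent SeedSequence-spawned streams, so
cohorts are bit-reproducible from a master seed. Generating parameters are
either fixed or drawn from the fitting priors (1/tau clipped to its 99th
prior percentile, and floored at 1e−3, for identifiability).

Four value-free strategy agents cover the interpretive space for stay
behaviour under degraded controllability. On free trials they repeat the
most recent free trial's emitted action with probability equal to their
*adherence* when their rule says stay, 1 − adherence when it says switch
(uniform at adherence 0.5 or with no prior free trial): reward-based
(stay iff rewarded), swap-avoidance (stay iff coherent), model-based
(stay iff rewarded = coherent), and control-maintenance (ignore incoherent
outcomes and repeat; stay iff rewarded when coherent). Their stage-1
choice is free with a fixed probability (default 0.69, the coherent-block
cohort mean), since the strategies only specify stage-2 behaviour. The
adherence levels behind the published schematics are not printed, so the
agents are parameterised rather than matched.

What the generator does **not** emulate: reaction times, early-press
repeats, left/right positions, within-session fatigue, or any between-
subject heterogeneity beyond the parameter draws. A green recovery test
therefore establishes that the estimation machinery is consistent for
agents of this family at the published trial counts — not that human data
would be fit equally well.

## Behavioural summaries

Free-choice preference is the proportion of test stage-1 choices that
select the free cue, per subject per block; the trial-indexed cohort
series supports an optional 2-point moving average (raw series always
retained). Conditional stage-1 preference conditions on the immediately
preceding test trial's choice, excluding the first test trial per block.
Stay tables classify each pair of successive test-phase free trials
(intervening forced trials allowed: the conditioning trial is the most
recent free trial) by the earlier trial's reward × coherence; *stay* is
defined on the emitted action, not the displayed target, because the
subject controls only the action. The preference reversal point is a
descriptive binomial-logit interpolation of per-subject block preferences
against the forced reward probability, returning the 0.5 crossing
(undefined outside [0, 1] or for degenerate inputs) — an approximation to
the original mixed-model estimate, not a reimplementation of it. The
reward-repetition odds ratio pools consecutive test-trial pairs into a
2 × 2 (previous reward × stage-1 repetition) table with Haldane–Anscombe
correction on zero cells. Inferential statistics (mixed models, smooths,
bootstrap intervals) are deliberately out of scope.

One empirical caveat the tests document: for simulated TD agents the
reward-repetition odds ratio exceeds 1 only when reward is informative
about the better stage-1 option (e.g. the unequal-probability exp2
schedule); at exact parity (exp1 P = 0.5) the within-trial update ordering
leaves it at or slightly below 1. Similarly, Q-learning's max operator
leaves a small optimism bias at parity, so "indifference at symmetric
schedules" is asserted only within Monte-Carlo-plus-bias tolerance for a
moderate learning rate.

## Recovery validation

Parameter recovery draws generating parameters from the priors, simulates
the exp1a schedule by default (largest trial counts, best
identifiability), refits with the generating spec, and reports Pearson and
rank correlations plus median absolute error per parameter. At 50 subjects
the stage-2 learning rate and bonus recover with rank correlations well
above 0.6; the stage-1 learning rate is weakly identified (few stage-1
decisions constrain it) and recovers poorly — an expected limitation, not
a defect. Model recovery simulates cohorts from representative fixed
parameters per family (alpha 0.5, tau 0.3, rho 0.5 when present, beta 0.3
for the pessimistic target — values chosen to make families behaviourally
expressed), fits all families to every log, and tabulates the selection
confusion matrix at the family level. Beta near 1 is correctly confusable
with Q-learning by construction. Failed fits are excluded and counted,
never imputed.

## Known limitations

- The stage-1 learning rate and, for near-deterministic agents, the
  temperature are weakly identified; recovery reports flag this rather
  than hide it.
- The reversal-point estimate is a cohort-level logistic interpolation
  with no random effects; with three design points it should be read as a
  summary, not an inference.
- Strategy agents are schematic: they bypass value learning entirely and
  use a fixed stage-1 policy.
- Differential learning rates for positive versus negative prediction
  errors are intentionally not implemented.
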