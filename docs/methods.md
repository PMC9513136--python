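# Methods

## The measurement problem

`itclab` models a two-session intervention study of choice impulsivity.
Each participant completes an intertemporal-choice (ITC) session before
and after a cognitive task (associative memory, Serial-7s working
memory, a spatial-attention control, a control memory task, or rest);
the question is whether the intervention shifts the participant's delay
discount rate, and whether within-task performance predicts the shift.
Everything below is exercised on synthetic cohorts with known ground
truth, so every estimator in the pipeline has a recoverable target.

## The adaptive staircase ITC task

Every trial pits a fixed immediate 10,000 KRW against a delayed reward.
Twelve staircase arms — delays {1, 10, 21, 50, 90, 180} days crossed
with initial delayed amounts {15,000, 20,000} KRW — each present five
offers per block; a block interleaves the arms in random order (uniform
over non-exhausted arms, immediate repetition allowed), and a session is
three blocks of 60 trials (180 total).

After an arm's *t*-th offer is answered, the delayed amount moves
against the choice. Two titration schedules are configurable:

* `halving` (default): step ±10,000·(1/2)^t KRW; a delayed choice on a
  15,000-arm instead halves the gap to the immediate amount,
  `next = 10,000 + (current − 10,000)/2`. With rounding-down to the
  nearest 100 KRW, exhaustive enumeration of all 2⁴ choice paths per
  arm spans offers 10,300–29,300 KRW.
* `literal`: step ±10,000·(1/2)^(t−1), with the 15,000-arm exception
  factor (1/2)^(t−1); the first delayed choice on a 15,000-arm lands
  exactly on 10,000 KRW and the all-immediate path on a 20,000-arm
  reaches 38,700 KRW.

`halving` is the default because it is the only schedule whose offer
range matches the task's published operating range under the
floor-to-100 rounding rule; both are kept because the printed update
formula corresponds to `literal`. A `min_margin` clamp (default 0) lets
users forbid delayed offers equal to the immediate amount.

One caution documented here because it is easy to assume otherwise: the
20,000-arm staircase is a true binary bisection (terminal step 625 KRW),
but the 15,000-arm's gap-halving exception is not — it contracts toward
10,000 KRW asymmetrically, and for indifference points in the upper part
of the arm's range the final offer can sit more than a thousand KRW from
the indifference reward. The tests assert the one-terminal-step
convergence only for the 20,000 arms, plus the choice-consistency
bracketing (immediate-chosen offers at/below the indifference reward,
delayed-chosen offers above it) that holds on every arm.

## Choice model and estimation

Subjective value is hyperbolic, `SV = V/(1 + kD)` with `k ∈ (0, 1)` per
day; choice follows a softmax on the SV difference,
`P(immediate) = 1/(1 + exp(−μ(SV_imm − SV_del)))`, with inverse
temperature μ ≥ 0 in 1/KRW (SVs are in KRW, so typical μ is 10⁻⁴–10⁻³).
Per session, (k, μ) is fitted by maximising the summed log choice
probability with Nelder-Mead in the transformed space (logit k, log μ),
which enforces both constraints without explicit bounds. Ten stratified
starting points cover log₁₀k ∈ [−4, −0.5] × log₁₀μ ∈ [−5, −2] with
seeded jitter; the best optimum wins, ties broken toward smaller k. All
reported log k are base 10 (the base is a convention; differences scale
by ln10 between bases).

A fit is flagged non-unique when every choice is the same option, when
the best k̂ is pinned near the (0, 1) boundary (k̂ ≤ 10⁻⁴ or ≥ 0.99), or
when two starts reach log-likelihoods within 0.01 of each other but
differ by more than 0.1 in log₁₀k (a flat ridge). The tolerances are
engineering choices: wide enough to pass normal optimiser scatter,
tight enough to catch unidentified sessions. Non-unique sessions are
excluded before any group statistic, and a 3-MAD screen on log₁₀k
(raw MAD, no consistency constant; participant dropped if either
session is flagged) removes outlying estimates.

On 200 simulated staircase sessions (log₁₀k ~ N(−2, 0.5),
log₁₀μ ~ N(−3.5, 0.3)) the estimator recovers log₁₀k with Pearson
r ≈ 0.94–0.97 and |bias| < 0.01 after the uniqueness screen (the screen
removes a few extremely patient agents whose sessions contain almost no
immediate choices). On small fixtures the optimum matches a 200×200
dense grid over (log₁₀k, log₁₀μ) to < 10⁻³ in NLL.

## Intervention-task logic

* **Associative memory**: 30 country→delay pairs; 6 target delays shared
  with the ITC task, 24 non-targets drawn between consecutive targets
  with fixed per-stratum counts (3, 4, 6, 5, 6; candidates exclude
  values within ±1 of a target, the last stratum drawn from 100–178).
  Fixing the counts keeps every target at a fixed sorted rank, so the
  country matched to each target by ascending distance-from-Seoul rank
  is always the printed anchor (Japan–1, Vietnam–10, Taiwan–21, The
  Philippines–50, New Zealand–90, Brazil–180). Encoding presents each
  pair twice (60 trials); retrieval cues targets ×3 and non-targets ×1
  (42 trials). The 30-country and office-supply lexicons are synthetic
  stand-ins; only the anchors and structural contracts are contractual.
* **Control_AM**: same schedule with each delay replaced by an office
  item whose annotated word length equals the delay's digit count.
* **Serial 7s**: subtract 7 from the previous answer; reset with a new
  uniform draw in [107, 999] on a wrong answer, a timeout (20 s), or
  when the next expected answer would fall below 100. The first expected
  answer after a (re)start is `initial − 7`, so the expected value never
  drops below 100.
* **Control_WM**: press the key matching the stimulus side within 1.5 s;
  late or absent responses score as timeouts.

Session duration is modelled as a trial budget (no wall clock);
reaction times, screen timing and the payment lottery are out of scope.

## Synthetic cohorts

`CohortDesign` draws per-participant baselines log₁₀k ~ N(−2.0, 0.5) and
log₁₀μ ~ N(−3.5, 0.3) — mid-range discounters with realistic choice
noise for KRW-scale values — and runs each participant through two
closed-loop staircase sessions with softmax choices. The intervention
effect is an additive shift of log₁₀k
(`post = pre − delta_log10_k − jitter`), with test-retest jitter
sd 0.1 log₁₀ units; the generator makes no claim that any task produces
a particular delta — effects are design inputs. Serial-7s accuracy is
Bernoulli around the saturating learning curve
`p(t) = p0 + (p1 − p0)(1 − e^(−rate·t))`, default 0.5 → 0.9 at
rate 0.02/trial over 240 trials. A Gaussian copula (correlation ρ,
default 0) couples the participant's learning rate (log-normal
perturbation, sd 0.3) with the idiosyncratic part of the pre-to-post
shift; the five-arm preset uses ρ = 0.5 to emulate a
faster-learners-improve-more scenario, the three-arm preset ρ = 0.

What the generator does **not** emulate: session-order and fatigue
effects inside the ITC task, non-stationary discounting within a
session, response times, memory content of the associative task, or
any dependence of μ on the intervention. Passing tests therefore show
that the pipeline recovers what this generative family produces, not
that real interventions behave this way.

## Group statistics

Per participant, `Δlog k = log₁₀k_pre − log₁₀k_post` (positive =
impulsivity reduced) and `ΔP(immediate) = P_pre − P_post`. Group tests
are bootstrap t-tests with B = 10,000 by default (2,000 in the heavier
simulation checks): samples are mean-centred (shift-to-null), resampled
with replacement, and the two-sided p-value is
`(#{|t*| ≥ |t_obs|} + 1)/(B + 1)`, which bounds p away from 0 at
1/(B+1). Correlation tests resample the two vectors independently to
break the pairing under the null. Cohen's d is mean/SD of difference
scores (paired) or the pooled-SD variant (two-sample). Under a Normal
null the one- and two-sample tests reject at 3.5–6.5% at α = 0.05
(measured over 1,000 replicates). No multiple-testing correction is
applied anywhere; callers comparing many groups should correct
downstream.

The time × type analysis is a split-plot ANOVA computed from the
standard sums-of-squares decomposition (between-subjects stratum: type
vs subjects-within-groups; within stratum: time and time × type vs
subject × time residual), with observation-weighted means when group
sizes differ. It agrees with `pingouin.mixed_anova` on balanced data
and reproduces a hand-worked 2×2 fixture exactly; the SS always sum to
the total to machine precision.

Task performance uses 10-trial windows stepped by 5
(`⌊(n−10)/5⌋ + 1` windows), the OLS slope of window accuracy on window
index, and five coarse bins of width ⌊L/3⌋ stepped by ⌊L/6⌋ (the fifth
bin right-anchored at the trace end so the bins always cover the task)
for the per-bin accuracy × Δlog k correlations.

## Reproducibility and problem sizes

Every stochastic stage derives its seed from the global seed by hashing
(seed, stage, participant), so single participants replay exactly and
full-pipeline reports are byte-identical under a fixed seed. The
simulation studies are sized for a desk machine: 200 agents for
parameter recovery, 25 fixtures for the grid comparison, 1,000
replicates (B = 2,000) for bootstrap calibration, and 20 replicate
two-group cohorts (n = 30/group) for effect recovery; all complete in a
few minutes on one core.

## Known limitations

* The 15,000-arm titration is not a bisection (see above); indifference
  points above ~15,000 KRW are localised mainly by the 20,000 arms.
* μ is estimated but only weakly identified in very consistent
  responders; its recovery is not a design target.
* The bootstrap's shift-to-null construction assumes exchangeability
  after centring; heavy-tailed effect distributions are handled only
  through the MAD screen.
* The mixed ANOVA uses weighted means under imbalance, which is not a
  Type-III decomposition; with the near-balanced designs generated here
  the difference is negligible.
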