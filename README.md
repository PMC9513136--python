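# itclab

Simulation and analysis toolkit for two-session intertemporal-choice
(ITC) intervention studies. It is written for behavioural and
computational-psychiatry researchers who measure choice impulsivity with
an adaptive monetary-choice task before and after a cognitive
intervention, and who want every stage of that analysis — task engine,
model fitting, exclusion rules, group statistics — testable on synthetic
cohorts with known ground truth.

## What it implements

* **Adaptive staircase ITC task.** A fixed immediate 10,000 KRW versus a
  delayed reward; 12 staircase arms (delays {1, 10, 21, 50, 90, 180}
  days × initial amounts {15,000, 20,000} KRW), 5 titration steps per
  arm per block, 3 blocks of 60 randomly interleaved trials (180 per
  session). Under the default titration schedule the offered delayed
  rewards span exactly 10,300–29,300 KRW.
* **Hyperbolic discounting + softmax choice model.** SV = V/(1 + kD),
  P(immediate) = 1/(1 + e^{−μ(SV_imm − SV_del)}); per-session
  maximum-likelihood estimation of (k, μ) via multi-start Nelder-Mead in
  a transformed space, with a uniqueness screen for boundary and
  flat-ridge fits.
* **Intervention-task logic.** Associative-memory encoding/retrieval
  schedules (60 + 42 trials, 30 country–delay pairs) and the matched
  control task; the Serial-7s working-memory validator (subtract 7,
  reset below 100, on errors, and on timeouts); the spatial-attention
  trial scorer.
* **Synthetic cohorts.** Per-participant (log₁₀k, log₁₀μ) draws, closed-
  loop pre/post staircase sessions, additive intervention effects on
  log₁₀k, and Bernoulli Serial-7s accuracy traces with logistic learning
  curves, all with retained ground truth.
* **Group statistics.** Δlog k = log₁₀k_pre − log₁₀k_post (positive =
  reduced impulsivity), ΔP(immediate), bootstrap t-tests (shift-to-null,
  10,000 resamples, p = (#{|t*| ≥ |t|}+1)/(B+1)), bootstrap correlation
  tests, a split-plot time × type ANOVA, 3-MAD outlier screening on
  log₁₀k, sliding-window accuracy (10-trial windows, 5-trial step),
  performance slopes, and five-bin performance × effect correlations.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Simulate a two-arm study (n = 30/group, a true 0.3 log₁₀-unit reduction
in the working-memory arm), fit every session, apply the exclusion
rules, and run the group statistics:

```python
from itclab.cohort import CohortDesign, GroupSpec
from itclab.io import PipelineConfig, run_pipeline

design = CohortDesign(groups=(GroupSpec("working-memory", 30, 0.3),
                              GroupSpec("rest", 30, 0.0)), seed=7)
report = run_pipeline(PipelineConfig(design=design, bootstrap_B=2000, seed=7))
```

This prints (via the report dict):

```
n_input 60  n_included 50  {'nonunique_mle': 2, 'mad_outlier': 8}
rest            n=26 mean dlogk=0.019 t=0.47 bootstrap p=0.6352 d=0.09
working-memory  n=24 mean dlogk=0.351 t=7.52 bootstrap p=0.0005 d=1.53
rest vs working-memory  t=-5.40 p=0.0005 d=-1.53
type       F=2.19  df=1 p=0.15
time       F=33.73 df=1 p=4.9e-07
time*type  F=29.11 df=1 p=2.1e-06
```

Reading it: two sessions were flagged by the uniqueness screen and eight
participants by the 3-MAD screen; the intervention arm's mean Δlog k of
0.351 recovers the true 0.3 shift within sampling error and is detected
by the bootstrap test (p ≈ 0.0005, floored near 1/(B+1)), while the rest
arm stays null; the ANOVA localises the effect in the time × type
interaction rather than a pure repetition (time) or baseline (type)
difference.

The same stages are scriptable from the shell:

```sh
itc-lab simulate --design config.yaml --out study/
itc-lab fit --trials study/trials.csv --out fits.json
itc-lab analyze --trials study/trials.csv --fits fits.json --out report.json
itc-lab run --seed 7 --out report.json       # end-to-end
itc-lab recover --n-agents 100 --out recovery.json
```

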