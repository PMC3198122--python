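# Methods

## Outcome model

Each simulated patient contributes an ordered trichotomous pair: a 24-hour
rapid response X ∈ {ICH < NEI < MNI} and a 3-month trichotomized Rankin
category Y ∈ {poor < neither < good}.  A *distribution scheme* fixes, for
each arm T ∈ {A, B, C (tenecteplase 0.10/0.25/0.40 mg/kg), D (rt-PA)}, the
joint law as the marginal P[X|T] plus the conditional P[Y|X,T]; the
implied Y-marginal must satisfy the marginalization identity
Σₓ P[X=x|T]·P[Y|X=x,T] = P[Y|T] (enforced to 1e-10, exact by construction
for generated schemes).  A *null* scheme has one Y-marginal for all four
arms, so both co-primary hypotheses are true whichever dose survives
selection; X-marginals and conditionals may still differ by arm, which is
what lets dose selection and safety-scenario classification interact with
the error rate.

Sampling is sequential: X from the arm's marginal, then Y from the
conditional row of the realized X.  Outcomes are i.i.d. across patients;
there is no site effect, no enrollment calendar, no dropout, and every
randomized patient yields both outcomes.  Matched sets are therefore pure
bookkeeping: one patient per active tenecteplase arm (plus one rt-PA
patient) per set.

## Dose selection

Scores (ICH 0, NEI 1, MNI 2 by default) accumulate per arm; after each
complete matched set, while the maximum cumulative sum among active arms
leads the minimum by at least the *lead* (default 6), all arms attaining
the minimum are eliminated.  Elimination therefore *cascades* within a
set: from sums (10, 4, 3) the trailing arm is removed and the remaining
gap 10 − 4 = 6 still meets the lead, so the second arm is removed in the
same set.  The stopping rule is stated on the post-elimination state, so
cascading is the reading we adopt; `SelectionConfig(cascade=False)` gives
the one-round-per-set alternative for sensitivity analysis (the replicated
operating characteristics in `tests/test_acceptance.py` are obtained with
the cascade on).  Elimination is only checked on complete sets, never
mid-set.  If no selection has occurred after `truncation_m` (default 150)
sets the procedure is truncated.

Patient accounting: with first/final elimination times N(1), N and
truncation point m, the selection phase uses
T = 2·min(N, m) + min(N(1), m) tenecteplase patients (a missing event
time is replaced by m).  This identity holds exactly per replication and
is verified against an independent set-by-set patient counter.

## Clinical promise/futility rules

At the assessment the selected arm and rt-PA each have
a₁ = clamp(N, 100, 150) patients (enrollment tops up to 100 per arm when
selection is early; assessment is immediate between 100 and 150).  ICH
counts use all accumulated rapid responses on the two compared arms;
Rankin proportions use the same denominators.  The safety scenario comes
from d = ICH(TNK) − ICH(rt-PA): scenario 1 (d ≤ −2), 2 (|d| ≤ 1),
3 (d ≥ 2).  Promise requires, respectively, poor(TNK) ≤ poor(rt-PA), an
arithmetic poor-proportion advantage of at least `poor_margin` (default
0.08), or nothing (scenario 3 is always futile).  A good-outcome deficit
significant at the two-tailed `alpha_interim` (default 0.001) level is
futile in any scenario.

At truncation, Criteria 1–4 select among the 2–3 survivors: keep the
promising ones; tie-break by lowest ICH rate, then lowest poor
proportion, then highest good proportion (all survivors share the
denominator 150, so these are exact integer comparisons), then a uniform
random draw — the last step is our addition, since the written criteria
can exhaust.  If no survivor is promising, one dose is chosen uniformly
at random, tested once at the 0.001 level on both endpoints (rejections
count as type I errors), and the trial stops.

## Hypothesis tests

Both endpoints use the pooled two-proportion z-test with 1/2-continuity
correction; the correction is clamped at zero when it exceeds the
absolute difference (the unclamped statistic would change sign), so the
corrected p-value is never smaller than the uncorrected one.  A pooled
proportion of exactly 0 or 1 is reported as z = 0, p = 1 (degenerate
flag).  The correction applies at interim and terminal analyses alike.
Rejection is `p ≤ α`; the far tail uses 2·Φ(−z) with a 1e-300 floor so
p-values stay in (0, 1].  The Holm step-down (smaller p vs α/2, then
larger vs α, overall α = 0.05) is applied and recorded at the terminal
analysis only; the error accounting uses the two per-endpoint 0.025-level
tests, i.e. Holm's first stage.

## Trial simulation and error accounting

Group-sequential (GS) mode: selection → assessment (the first interim
analysis: both endpoints at two-tailed 0.001, then the scenario rules) →
interim analyses when the two continuing arms total 500/1000/1500
patients (phase II patients included, 1:1 allocation, i.e. 250/500/750
per arm) → terminal analysis at 1908 (954 per arm).  Any rejection at an
interim (0.001) or terminal (0.025) test marks the replication as
contributing at least one type I error; futility stops without rejection
contribute none.  Interim rejections stop the trial (config switch
`stop_on_interim_rejection`); this does not affect the either-endpoint
rate, only the split across endpoints and stages.  Signed tails are
recorded per endpoint (tenecteplase better vs worse, by the sign of the
uncorrected difference).  Fixed-sample (FSS) mode removes the futility
examination and all interims: selection (truncation resolved by a uniform
random pick among survivors), then one terminal analysis at 954 per arm.

Phase II patients on eliminated doses contribute to selection only; their
Rankin outcomes are never tested, so exactly one hypothesis test per
endpoint is ever performed — the design's multiplicity argument.

## Scheme generation

Marginals are drawn uniformly on the probability simplex restricted to a
rectangular region (rejection from a flat Dirichlet(1,1,1); degenerate
zero-width bounds pin coordinates analytically).  Defaults encode the
clinical anchors of the trial population: X-region P[ICH] ∈ [0.01, 0.12]
(lytic-therapy ICH rates cluster near 6%), P[MNI] ∈ [0.05, 0.45] (the
pilot range was 16–36%); Y-region P[poor] ∈ [0.20, 0.60],
P[good] ∈ [0.15, 0.55].  Both regions are config-overridable
(`regions.x.ich`, `regions.x.mni`, `regions.y.poor`, `regions.y.good`).

Conditionals are generated by drawing P[Y|X=ICH] and P[Y|X=MNI] from the
flat simplex subject to the outer monotone ordering, solving P[Y|X=NEI]
from the marginalization identity (the default X-region guarantees
P[NEI] ≥ 0.43, so the solve is well conditioned), and accepting iff the
solved row is a valid probability vector satisfying the middle-position
monotone inequalities.  Monotonicity is non-strict: P[poor|X] may not
increase and P[good|X] may not decrease in X, with ties allowed so the
independence matrix is admissible.  An infeasible pair raises an error
naming the most frequently violated constraint.  A zero-probability
middle X category is rejected (the solve is undefined); this cannot occur
inside the default region.

A null ensemble is a nested factorial draw: n_x cells of per-arm
X-marginals; per cell, n_y shared Y-marginals; per (X, Y) pair, n_cond
sets of per-arm conditionals.  X-marginals and conditionals are drawn
independently per arm — the null constraint binds only the Y-marginal —
so safety asymmetries between tenecteplase and rt-PA arise naturally and
drive scenario-3 futility stops.

## Reproducibility

One master seed governs everything.  Named substreams are derived with
`SeedSequence` spawn keys (strings hashed by CRC-32), one per stage and
per (scheme, replication-block); replication blocks have fixed sizes
(8192 for trial batches, 20000 for selection runs), making every result
bit-reproducible and independent of scheme processing order.  Tie-break
uniforms are drawn unconditionally so stream positions never depend on
realized outcomes.

## Problem sizes

Selection operating characteristics are replicated at the study's full
100,000 replications per configuration (a few seconds each, vectorized
over replications).  The type I error study runs at a desk scale of 200
schemes × 4,000 replications; the factorization 10 × 5 × 4 keeps the full
ten X-marginal cells and scales down the nested Y and conditional
factors, because between-X-cell variation (which controls the
tenecteplase-vs-rt-PA ICH gap and hence the futility-stop rate) dominates
the ensemble variance of the error rate.  The full-scale study
(1000 × 40,000) is a config change (`ensemble.n_x/n_y/n_cond` and
`--reps`) but a cluster-scale job.

## What the generator does and does not emulate

The synthetic patient stream reproduces the joint trichotomous outcome
laws, the clinically monotone X–Y dependence, and arm asymmetries in
safety and early response.  It does not model site stratification (the
pooled z-test stands in for the site-stratified Mantel–Haenszel score
test, which site-stratified randomization renders essentially
equivalent under the null), response-time lags between randomization and
the 24-hour outcome, missing or delayed Rankin assessments, or enrollment
drift.  Passing tests therefore certify the design's statistical
machinery under the stated outcome model, not robustness to operational
artifacts.

## Known limitations

* Alternative-hypothesis ensembles (power studies) are out of scope; the
  error study is null-only, and the published power figures are not
  recomputable without the comparator's baseline Rankin distribution.
* The exact random regions used by the original ensemble are not public;
  the defaults above are this package's own declaration, and ensemble-level
  summaries (means across schemes) shift by a few thousandths of a
  probability unit across region choices and ensemble seeds.
* k-arm selection beyond three tenecteplase arms runs but is untested
  against any reference values.
* The truncation-without-winner branch of the FSS study (uniform random
  selection among survivors) is an assumption, flagged in the code.
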