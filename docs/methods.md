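# Methods

This package implements the analytic chain around a probabilistic reward- and
punishment-based category-learning task used in prospective clinical-risk
research: the task environment, a Q-learning model with a subjective value for
ambiguous (no-feedback) outcomes, per-session maximum-likelihood fitting with
recovery and predictive checks, behavioral summaries, 90-day prospective
outcome labeling with censoring, and clustered multinomial odds-ratio models.
A synthetic-cohort generator stands in for clinical data so the whole chain is
exercisable and testable end to end.

## Task environment

Four stimuli are classified into categories A or B over 80 trials (two blocks
of 40; 10 trials per stimulus per block, 8 paired with the stimulus's frequent
category and 2 with the infrequent one, so each stimulus's frequent category
is correct on exactly 80% of its trials). S1/S2 are reward-valenced (+25
points with explicit feedback when correct, nothing otherwise); S3/S4 are
punishment-valenced (−25 with explicit feedback when incorrect, nothing
otherwise). The no-feedback outcome is therefore ambiguous — a missed reward
or an avoided punishment.

The live task used one pseudorandom trial order fixed across participants.
That literal order is not public, so the package generates one canonical
schedule from a fixed seed under the stated constraints (block-level uniform
shuffle of the 40-trial multiset; each stimulus's first appearance within a
block carries its frequent category, enforced by swapping with the first
frequent-category occurrence). No further ordering constraint is imposed —
the constraints, not the literal order, carry the scientific content — and
`validate_schedule` polices them all. The 500-point starting tally is a UI
convention; the engine tracks it, allows it to go negative, and never uses it
in fitting.

A 4-trial guided practice prefix (two extra stimuli) is represented in logs
with `practice_flag=True` and excluded from all scoring and fitting.

## Learning model

Q(s, a) values (4 stimuli × 2 responses, initialized to 0) are updated by
prediction error `pe = r − Q(s, a)` on the chosen action only, with learning
rate `lr_plus` when pe > 0 and `lr_minus` when pe < 0 (pe = 0 leaves Q
unchanged; either rate would agree). Reinforcement is on the unit scale:
explicit reward +1, explicit punishment −1, and the ambiguous no-feedback
outcome is worth `r0 ∈ [−1, +1]` — the parameter of central interest. At
`r0 = +1` the Q-trajectory under no-feedback is exactly that of explicit
reward; at −1, of explicit punishment (asserted as a property test).

Choice is a softmax over the two Q-values with temperature
`tau = beta / (1 − beta)`, `beta ∈ (0, 1)`: beta → 0 is greedy exploitation,
beta → 1 approaches uniform choice. The original publication describes the
explore/exploit parameter on a bounded (0, 1) scale but does not print the
functional form of its choice rule; this temperature mapping is the package's
declared realization of those semantics and would be revised if the original
code showed otherwise. Numerical guards: tau clamped to [1e−3, 1e3], choice
probabilities clamped to [1e−6, 1 − 1e−6] before the log, overflow-safe
sigmoid on the Q difference.

The likelihood processes trials sequentially, accumulating −ln p(observed
response) and updating Q from the *recorded* feedback. It is implemented as a
plain-float loop (sequential dependence defeats vectorization; the loop is
~1 µs/trial) and is checked to 1e−10 against an independently written naive
reference in the tests. With both learning rates 0 and Q initialized at 0 the
negative log-likelihood is exactly `T ln 2`, which the tests assert to 1e−9.

## Fitting

Per-session maximum likelihood over `(lr_plus, lr_minus, beta, r0)` with
bounds [0,1], [0,1], [1e−3, 1−1e−3], [−1,1]; L-BFGS-B from 20 Latin-hypercube
starting points drawn with a fixed seed; best start wins, ties within 1e−6 in
negLLE broken toward the smaller parameter-vector norm. The spread (max−min)
of negLLE across converged starts is reported so flat-likelihood sessions are
visible. Powell and Nelder-Mead polishing were compared during development
and bought no recovery accuracy for 4× the runtime, so L-BFGS-B stands
despite the kink in the likelihood surface at pe = 0. Sessions need ≥ 50
non-practice trials to be fit; partial sessions are fit over available trials
and raw negLLE is reported un-normalized, alongside a per-trial normalized
variant for cross-session comparability.

Parameter recovery (simulate with known parameters → refit → correlation,
bias, RMSE per parameter) uses independent uniform truths over the bounds by
default. At 80 trials recovery is intrinsically modest — a high-beta agent's
choices carry almost no information about its learning rates — and the
harness reports that honestly: r0 correlation ≈ 0.5–0.57 in pilot runs of
120–200 agents, learning-rate correlations ≈ 0.2–0.3, with r0 RMSE shrinking
when the trial count doubles. The predictive check simulates sessions under
fitted parameters and compares observed percent-optimal scores with the
simulated 2.5–97.5 percentile band, using the same behavioral code for both
sides.

## Behavioral summaries and cleaning

Responses faster than 200 ms are anticipatory and excluded; a session whose
non-practice responses all use one key is flagged noncompliant (a softer
warning flag fires at ≥ 97.5% single-key without excluding); sessions with
50–79 usable trials are retained with a partial flag, below 50 rejected.
Cleaning never edits retained rows.

Percent optimal is the percent of trials (per valence) where the response
matched the stimulus's frequent category, regardless of that trial's actual
assignment. Win-stay / lose-shift condition on the most recent prior trial of
the same stimulus (not the globally previous trial), with success defined per
valence: reward delivered for reward stimuli, punishment avoided (no
feedback) for punishment stimuli. Both are validated against brute-force
pair enumeration.

## Outcome classification

Each session's window is `(session_date, session_date + 90]` — day 0
excluded by default (day-of-testing events belong to the preceding clinical
state; `include_day0=True` switches the convention), day 90 included. Labels
with strict precedence: ASA if any actual suicide attempt in the window
(events before censoring count even when the window is cut short); else
OtherSE for interrupted/aborted attempts, preparatory behavior, or
ideation-related hospitalization; else noSE if follow-up covers the full
window; else unclassifiable. Follow-up end per subject is the earliest of
death, withdrawal, and study end. Multiple events in one window yield one
label (earliest qualifying date recorded). Labels are translation-invariant
in calendar time.

## Risk models

Baseline-category multinomial logit with noSE as reference, estimated by
maximum likelihood (statsmodels MNLogit) — identical to the
independence-working estimating-equation solution — with cluster-robust
sandwich covariance grouped by subject, Wald 95% intervals exponentiated to
odds ratios. The original analysis used a local-odds-ratio-parameterized
multinomial GEE; both estimate the same marginal model, and the
working-association choice affects efficiency, not consistency, so small
numerical differences from the original software are expected and accepted.
Predictors enter untransformed (percent scale, raw r0, raw SSI, raw prior
attempt count) so odds ratios are per-unit. Singleton clusters provably
reduce to ordinary multinomial ML (tested to 1e−6 against an independent
Newton oracle); a binary predictor on a collapsed 2×3 table reproduces
closed-form cross-product ratios. Wald intervals with a normal reference are
standard estimating-equation practice; with 5-per-118 outcome prevalence
they are anti-conservative in small samples, which is a documented caveat,
not a correction the package applies silently.

## Synthetic cohort

Defaults mirror the study's shape: 58 subjects, 118 sessions (1–5 per
subject), sessions split 100/13/5 across noSE/OtherSE/ASA by exact
largest-remainder allocation (shuffled), with group assignment **per
session** — the analysis unit is the session and the same subject may
precede an attempt once and not another time. Parameters are drawn from
normals truncated to the model bounds with each group's observed mean/SD
(r0: +0.13/0.71 noSE, +0.22/0.60 OtherSE, −0.24/0.71 ASA; analogous profiles
for the learning rates, beta, and SSI). Truncated draws are not re-centered,
so realized means shift toward 0 by up to ~0.12 for the r0 profiles; the
truth table records realized values. SSI is normal floored at zero; lifetime
prior attempts per subject are 21.7% zero / 33.3% one / 45.0% two-or-more
(the multiple case uniform on 2–5). Parameters, SSI and prior attempts are
drawn independently; a correlation structure can be injected by supplying a
custom profile/sampler, but none is asserted because the true joint
distribution is unknown.

Event plans place one qualifying event uniformly on days 1–90 after
ASA/OtherSE sessions and none after noSE sessions; consecutive sessions are
spaced 91–180 days apart and study end is 365 days after a subject's last
session, so every planned event falls in exactly its own session's window
and intended labels are recovered exactly — which the tests assert. What the
generator does **not** emulate: reaction-time structure (lognormal filler
values only), practice-phase behavior, correlations between cognition and
covariates, within-subject parameter stability, or events outside planned
windows. A green end-to-end test therefore establishes that the pipeline's
plumbing and the direction of generator-built effects survive the chain — it
does not validate the clinical effect sizes.

## Known limitations

- With 5/118 ASA prevalence (or 15/354 at 3×), fitted-parameter group
  contrasts are fragile: ML estimation at 80 trials attenuates the r0
  contrast (fitted-truth correlation ≈ 0.5) and truncation shrinks the
  generating contrast itself, so the sign of the fitted-r0 odds ratio in the
  3× synthetic cohort is not reliably negative even though the model on the
  *generating* r0 recovers it. The acceptance test asserts the stated
  contract and is allowed to stay red rather than widening its band.
- The choice-rule functional form and the original optimizer settings are
  declared substitutes for unpublished details, as flagged above.
- Wald/sandwich small-sample behavior as noted under risk models.
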