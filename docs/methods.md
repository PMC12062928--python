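# Methods

## Scope and data model

`playface` analyzes dyadic play-fighting sessions of lowland gorillas (and,
in principle, any species with a comparable ethogram) recorded as
long-format event logs: one row per behavioral pattern or facial
expression, with times in seconds from session start. Two expression types
are distinguished — the Play Face (PF, lower teeth exposed) and the Full
Play Face (FPF, upper and lower teeth exposed). Behavioral patterns are
classified offensive / defensive / neutral by the packaged ethogram
(41 entries; the dual-role "play jump" appears as a directed offensive
entry and a solitary neutral one). Pattern names are matched
case-insensitively after whitespace normalization; the packaged ethogram
is the single source of category truth.

A session's `start` is 0 and its `end` is the latest event time in the
log. Ties in event order are broken by file order. Solitary patterns
(target absent) count toward diversity and the asymmetry denominator but
never toward directed offense or defense.

## Rapid facial mimicry (RFM)

Every expression is a stimulus toward the partner unless it was itself
consumed as a response. A stimulus counts as *replicated* when the partner
emits an expression of the **same** type (exact facial matching) with
onset strictly after the stimulus onset and at most `window_s` (default
1.0 s) later. Latency is onset-to-onset with an inclusive upper boundary:
onset is the only frame-anchored instant the duration coding defines, and
the window is configurable because "within 1 s" could also be read from
the offset. Pairing is greedy earliest-first; each expression answers at
most one stimulus, and a consumed response never becomes a stimulus
itself. Incongruent responses are recorded as non-replication, not
discarded.

Perception is an annotation, not a geometric computation: frontal or
lateral view → perceived, blind area → not perceived, doubtful → unknown
(dropped from every analysis). Perception-by-replication counts per
expression type form 2×2 tables tested with a Yates-corrected chi-square.
An individual's mimicry level is replications ÷ perceptions; individuals
who perceived nothing are excluded.

The occurrence analysis is completed by a binomial mixed model:
response (0/1) ~ perception + group, with trigger–responder dyad as a
random intercept, compared against the intercept-plus-random-effect null
by a likelihood-ratio test. The package builds the design table and
defines the comparison; estimation is delegated to lme4's `glmer` through
`Rscript` (`rfm.fit_binomial_glmm`).

## Indices

**Play Asymmetry Index.** For a window of patterns and an ordered player
pair (A, B):

PAI = [(off A→B + def B→A) − (off B→A + def A→B)] / (all patterns in window)

ranging −1 … +1; the denominator includes neutral and solitary patterns.
In the sequential analysis the default orientation points A at the focal
event's emitter, so a positive after-minus-before shift means asymmetry
moved toward the signaler; an `initiator` orientation (player order of
the session, first pattern performer) is available and recorded in run
manifests, since the orientation used in the original analysis is not
derivable from the published account.

**Shannon index.** H′ = −Σ (nᵢ/N) ln(nᵢ/N) over pattern *names* (not
categories), natural log. Bounds 0 … ln(#distinct patterns).

**Sequential windowing.** For each focal event (an unreplicated expression
or a mimicry stimulus), the k = 4 patterns strictly before and strictly
after its onset are selected. Two consecutive focal events are both
retained only when at least 2k + 4 = 12 patterns lie strictly between
their onsets (two disjoint windows plus a 4-pattern buffer); otherwise the
later event is dropped and spacing continues from the last retained one.
A side with 1–3 patterns is kept as a short window; an event with an empty
side is dropped. Retaining short windows preserves sample size but makes
the index comparison slightly liberal for H′ when sessions are short
(short windows bound H′ from above); the per-kind Wilcoxon of
after-versus-before values therefore pools windows of unequal length,
exactly as the windowing defines them.

## Session conditions and durations

Sessions are labeled by priority: mimicry of both expression types >
mimicry of FPF only > mimicry of PF only > at least two unreplicated PFs
with no FPF at all ("PF not mimicked"; symmetric for FPF) > excluded
(no expressions, a single one, or an ambiguous unreplicated mix).
`time_remaining` is session end minus the first qualifying event — the
first unreplicated expression for the not-mimicked conditions, the first
mimicry stimulus onset for the mimicry conditions (the earlier of the two
types in the mixed condition). The five groups are compared with the
Monte-Carlo Kruskal–Wallis and Dunn–Bonferroni post hocs. The midpoint
test records whether the first mimicry stimulus fell strictly before the
session's halfway point (ties conservatively count as "after", a
measure-zero event in real timings) and tests the flag against 0.5 with
an exact binomial test.

## Statistical toolbox

* **Yates chi-square**: χ² = N·(max(|ad−bc|−N/2, 0))²/(r₁r₂c₁c₂), df 1.
  The correction is clamped at zero so weak associations cannot be
  inflated; the clamp is compatible with both published chi-square values.
* **Exact Wilcoxon signed-rank**: zero differences are dropped and
  reported as the "ties" count; T is the smaller rank sum; mid-ranks for
  tied magnitudes. For ≤ 25 nonzero differences the two-sided p is exact
  over all 2^m sign assignments (doubled-rank dynamic programming);
  beyond that, a normal approximation with tie and continuity correction.
* **Kruskal–Wallis, Monte Carlo**: H with tie correction on pooled
  mid-ranks; the p-value shuffles group labels (sizes preserved) with the
  add-one estimator (1 + #{H* ≥ H})/(1 + B), B = 10 000 by default, seed
  recorded; permutation p-values can never be 0. Because pooled ranks are
  label-invariant the randomization is fully vectorized.
* **Dunn–Bonferroni post hocs**: both the raw mean-rank difference and
  the standardized z are reported (published "Q" values are consistent
  with raw differences but their definition is not stated); two-sided
  normal p × number of pairs, capped at 1.
* **Paired t, exact binomial, Cohen's kappa, duration IOA** follow the
  standard definitions; IOA is the mean over trials of
  min(d₁,d₂)/max(d₁,d₂), returned as a ratio by default and as a
  percentage with `percent=True`.

## Action-unit analysis

Binary FACS-style configurations are summarized by presence frequency;
"always or almost always present" defaults to ≥ 0.8. OpenFace-style
intensity tables (17 estimated AUs; AU16 and AU27 are not estimated by
OpenFace) are aggregated frame→clip by the per-AU maximum by default (the
apex of the expression; mean and median available since the original
reduction is not stated), and clip→subject by the median. Each AU gets an
exact Wilcoxon across subjects with both expressions; the family-wise
Bonferroni threshold is α/number of AUs tested (0.005 for 10 AUs at
α = 0.05).

## Synthetic generator

The generator produces event logs with the statistical structure the
analyses assume, so every stage can be validated against known ground
truth. Sessions are built pattern by pattern: exponential inter-pattern
gaps (mean 2 s), a session-specific category mixture (Dirichlet around
offensive/defensive/neutral weights 0.45/0.15/0.40), session-specific
concentrated pattern distributions within categories (Dirichlet
concentration 0.12), and a pattern-bout repetition probability of 0.4.
The last three produce the low within-window diversity real play shows
(4-pattern windows average H′ ≈ 0.6); offense is performed by the
session initiator with probability 0.65.

Expressions arise at 0.8 per player-minute, scaled per session by a
unit-mean gamma multiplier (shape 0.5) — expressiveness is strongly
heterogeneous across sessions, which is what makes sessions with zero
expressions and sessions with several unreplicated expressions of one
type both common. Expression type is FPF with probability 0.72 and is
sticky within a session (persistence 0.7; sessions with only one type
occur at a few percent, as observed). A stimulus is perceived with
probability 0.75 and replicated with probability 0.59 (perceived) or 0.20
(not perceived) — the aggregate proportions implied by the published
perception-by-replication counts; replication latency is uniform on
(0, 1] s and durations uniform on [0.5, 4] s. A player's *independent*
emissions are suppressed while inside the response window of the
partner's latest expression, since partner responding is modeled entirely
by the replication probability.

Ground-truth effects (defaults; `null_params()` switches all off and
equalizes the replication probabilities at 0.3):

* termination hazard per pattern 0.05, multiplied by 0.4 after the first
  mimicry event (mean session ≈ 40 s without mimicry);
* for exactly 4 patterns after an unreplicated FPF the offensive category
  probability is shifted up by δ = 0.3 and offense is directed by the
  emitter — the effect window equals the analysis window by design, so
  recovery directly tests the windowing;
* for 4 patterns after an unreplicated PF, pattern choice is mixed toward
  uniform with weight 0.7.

What the generator does **not** emulate: the demographic structure of the
real groups (ages, kinship, per-individual session counts), repeated
individuals across dyads, head-pose geometry behind the perception
annotation, and observation-time censoring. Passing recovery tests
therefore shows the pipeline detects these effect structures at realistic
sizes — not that the real data contain them.

## Problem sizes and runtimes

The recovery suite runs 100 replicates of 500 sessions (25 dyads × 20)
with 999-permutation Kruskal–Wallis tests per replicate; the type-I
calibration uses 500 null replicates of three groups of 10. The whole
pytest suite completes in about two minutes on one core; the acceptance
script in under a minute. One mixed-model fit (~1300 stimuli) is
exercised through lme4.

## Known limitations

* The paired Wilcoxon treats windows as independent events although
  several can come from one session; the Monte-Carlo Kruskal–Wallis
  exposes an optional within-stratum permutation only through its seed
  interface, not a dyad-stratified scheme, because the original
  randomization scheme for repeated individuals is unspecified.
* The condition classification depends on detection: a session whose only
  replication falls just outside the 1 s window classifies as
  not-mimicked.
* The mixed model requires an R installation with lme4; everything else
  is pure Python.
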