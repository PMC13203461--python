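# Methods

This note documents the models implemented in `gazeseq`, the choices
made where several defensible conventions exist, what the synthetic
generator does and does not emulate, and the numerical details that
affect results.

## AOI geometry

A face stimulus is segmented into three stacked bands — Upper, Central
and Lower Facial Zone — operationalized as axis-aligned rectangles in
screen pixels (origin top-left, y increasing downward). The default
layout places a 600 × 800 px face box at the center of a 1920 × 1080
screen and splits it 30% / 40% / 30% top to bottom, a plausible stand-in
for the anatomical band boundaries (supraorbital ridge, subnasale) used
when AOIs are drawn on real stimuli. Any layout satisfying the
non-overlap and vertical-ordering invariants can be substituted per
item.

Membership is half-open, `[x_min, x_max) × [y_min, y_max)`: a fixation
exactly on the boundary between two bands belongs to the lower band,
whose top edge is closed. This makes the three zones a true partition
of the face box — every in-box point maps to exactly one zone — which
the round-trip property tests rely on. Fixations outside all zones are
labeled `OUTSIDE` and, by default, dropped with the sequence stitched
across the gap; a flag instead breaks the sequence at such gaps, which
changes transition counts and is therefore off by default.

## Transition models and entropy

Transition models of order k ∈ {1, 2} are estimated by maximum
likelihood: counts of (context, destination) pairs accumulated strictly
within each participant × item × trial × event sequence, then
row-normalized. No pseudocounts are used; contexts never observed carry
NaN probabilities and are reported as unobserved. Sequences of length
≤ k contribute nothing at order k and are skipped (logged per
participant when an entire participant drops out).

Entropy of a destination distribution is Shannon entropy in bits with
0·log 0 := 0, normalized by log₂3 — the number of possible destination
zones — *regardless of model order*, so first- and second-order values
share a scale. The global value is the occupancy-weighted mean of
per-context entropies, with weights equal to each context's share of
counted transitions. This is exactly the plug-in conditional entropy
H(X_t | context) and is the only aggregation under which the published
arithmetic (global bits → global normalized, e.g. 0.537 → 0.339 and
0.505 → 0.319) is internally consistent with strongly central-dominant
occupancy. Unobserved contexts get weight zero rather than an imputed
value.

Aggregate (pooled over participants) models are used for the headline
matrices; the model-order comparison instead fits each participant
separately and compares per-participant global normalized entropies
H₁ and H₂ with (a) a two-sided Wilcoxon signed-rank test on the paired
differences (zeros dropped; the reported V is the sum of positive
ranks, the convention of R's `wilcox.test`; the p-value is exact when
the sample is small and tie-free, otherwise normal-approximated) and
(b) a percentile bootstrap that resamples *participants* with
replacement (default B = 10 000, seedable); the point estimate is the
median of the observed differences and the interval the 2.5/97.5
percentiles of the bootstrap medians. Participants are the unit of
inference, hence the resampling grain.

A useful analytic fact used in testing: when the order-1 model is fit
on each sequence's tail `seq[1:]`, both orders' global entropies are
plug-in conditional entropies over the *same* set of transition
targets, and conditioning on a longer history can only reduce plug-in
entropy, so H₂ ≤ H₁ holds exactly. Without that alignment the
inequality can fail on short sequences because order 1 sees transitions
that order 2 cannot use.

## Fixture matrices and the fill rule

The bundled fixture matrices pin the published aggregate entries:

- order 1: P(U→C) = 0.694, P(L→C) = 0.692, P(C→C) = 0.920;
- order 2: (U,C)→C = 0.902, (C,C)→C = 0.926, (L,C)→C = 0.830,
  (L,L)→L = 0.535.

Entries not pinned are completed by a documented rule and tagged
`"filled"` (vs `"printed"`), so recovery checks can restrict themselves
to pinned entries. Order 1: direct hops between the outer bands are
rare, so U→L = L→U = 0.030 and the self-transitions absorb the
remainder (U→U = 0.276, L→L = 0.278); the central row splits its
residual 0.080 symmetrically (C→U = C→L = 0.040). Order 2: each row
starts from the first-order row of the most recent state — a
minimal-information extension consistent with the first-order structure
— renormalizing the remaining first-order mass around any pinned entry
in that row. All rows are row-stochastic to 1e-12 by construction.

The fixture's own derived quantities are close to, but not identical
with, the published per-state entropies (the published values also
reflect the unprinted mass of the real matrices, which is not
recoverable); only pinned entries are treated as recovery targets.

## Synthetic generator

The generator emulates the study design: 27 participants (13 run with
the post-context procedure, 14 pre-context), 24 face items presented
once each. A pre-context trial is context image (500 ms) → target face
(3000 ms) → response screen; post-context reverses face and context, so
the event preceding a face is the *previous* trial's response screen.
Defaults chosen once where the design leaves them open:

- **Fixations per face:** Poisson with mean 10 (floor 2), a free
  parameter — roughly 3000 ms at typical fixation durations.
- **Durations:** log-normal, median 250 ms, σ = 0.4 on the log scale
  (typical human fixation durations); no duration model is implied by
  the emulated study.
- **Target coordinates:** band-center anchors with Gaussian jitter
  (SD 45 px vertically, doubled horizontally), rejection-sampled into
  the generating band, so ingest round-trips every label exactly.
- **Initial state:** stationary distribution of the first-order
  fixture (≈ 0.052 / 0.897 / 0.052 for U/C/L), so sequences start in
  steady state, matching aggregate estimation; for order 2 the second
  state is drawn from the first-order row of the first.
- **Anchor events:** context fixations scatter around screen center;
  response-screen fixations around one of four emoji positions in a
  centered horizontal band.

Fixed seed ⇒ byte-identical output tables. Onset times accumulate
fixation durations plus a 30 ms saccade gap and are not truncated to
the nominal event durations; no analysis depends on absolute onsets
beyond ordering.

What the generator does **not** emulate: saccade kinematics, pupil
data, measurement noise that moves a fixation across a band boundary
(validity flags default to all-true; tests inject invalid/missing rows
explicitly), item-level heterogeneity, and any coupling between dwell
and movement amplitude. A consequence of the last point: because
coordinate jitter is i.i.d. per fixation, within-zone path length grows
roughly linearly with visit length, and the synthetic stability index
does not reproduce the empirical ordering across zones reported for
real data (where the central zone is the most stable). Passing tests
therefore validate the *metrics and inference machinery* — arithmetic,
invariances, parameter recovery, df structure — not zone-level
stability effects in real recordings.

## Repositioning, stability and tests

Anchor transitions pair the last fixation of the anchor event with the
first fixation on the face; presentations missing either side are
skipped and counted (e.g. the first trial of a post-context block has
no preceding response screen). Distances are kept at trial level and
grouped by the *landing zone* of the first target fixation.

Within-zone path length sums the Euclidean steps of consecutive
same-zone fixation pairs inside a presentation; pairs spanning two
zones contribute to neither. Total duration sums every fixation
duration in the zone (including isolated fixations that contribute no
path). Stability = duration / path; groups with zero path are excluded
and counted rather than assigned infinite stability. Two grains are
supported: participant × zone aggregates (27 × 3 = 81 rows; the
AOI-only mixed model) and participant × zone × presentation (the
AOI × EventType model).

Rank tests: Kruskal–Wallis with tie correction and ε² = H/(n−1) (the
convention consistent with published χ²/ε² pairs); pairwise comparisons
are independent-sample rank-sum tests (trial-level observations with
unequal group sizes preclude pairing), tie-corrected normal
approximation, Holm step-down adjustment, effect size r = |Z|/√(n₁+n₂)
with |Z| recovered from the two-sided p.

Kendall's W uses the plain 12S/(m²(n³−n)) formula with mid-ranks for
tied dwell and *no* tie correction (the printed formula has none). The
default spatial units are the three zones; a uniform grid over the face
box is available.

## Mixed models

Both stability models are REML fits with a random intercept per
participant, delegated to statsmodels `MixedLM` (this stage is
plumbing, not re-derived estimation). Contrasts are reported against
the Lower Facial Zone. Per-term ANOVA F statistics are Wald contrasts
on the fixed effects with residual/containment denominator df
`n_obs − k_fixed` — reproducing the published df structure
F(2, 78) for 27 × 3 aggregate rows — rather than Satterthwaite or
Kenward–Roger approximations. The trial-level model's denominator df
depends on the realized number of usable presentations and is reported
in the output metadata. Singular fits (random-intercept variance at
the boundary, or non-convergence) are flagged in the result object,
never silently accepted.

## Problem sizes and tolerances

Parameter-recovery simulations size themselves so that three binomial
standard errors of each recovered entry fit inside its tolerance
(±0.01 for order-1 entries, ±0.015 for order-2): ≈ 4.5 × 10⁵
transitions for order 1 (the binding entry is P(U→C), upper-zone
occupancy ≈ 5%) and 8 × 10⁵ for order 2 (binding context (L,L),
occupancy ≈ 1.4%). The first-order recovery deliberately runs through
the entire pipeline — generation, TSV round trip semantics, cleaning,
AOI assignment, sequence building, estimation — while the second-order
recovery samples label sequences directly from the chain.

Numerical details: row-stochasticity enforced to 1e-12; entropy input
distributions validated to 1e-9; oracle-equivalence checks (brute-force
rank statistics, Holm, Kendall's W, path geometry) at 1e-10; Wilcoxon
zeros dropped before ranking; bootstrap and all simulation randomness
flow from explicit `numpy` generators seeded at the call site.
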