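# Methods

`endoquest` implements a questionnaire-only prediction pipeline for
endometriosis (EMS) in women using hormonal contraception, built around
a reference case-control cohort (n = 119 histology/examination-confirmed
cases, n = 109 examination-negative controls) for which only per-group
marginal summaries are public. This note records the models, the
defaults and why they were chosen, and what the synthetic checks do and
do not establish.

## Data model

Two instruments are modeled. The symptom questionnaire contributes the
classical EMS pain items (dysmenorrhea, chronic pelvic pain, dysuria,
dyschezia, dyspareunia, each with a 0-10 numeric rating scale (NRS),
plus constipation/diarrhea and menstrual-pain timing), eleven pain
adjectives and analgesic use. The PainDETECT neuropathic-pain screen
contributes seven 0-5 sensory items, a single-choice pain-course
pattern, radiating pain, three 0-10 intensity scales and seven pain
locations. Every answer is optional; missingness is explicit (empty
CSV cell, `None` in memory) and is resolved only at scoring time, where
a missing answer contributes 0/false. Rationale: the instrument asks
enough items that no single answer is decisive, and the reference
cohort was evaluable despite sparse missingness.

The published timing rows (pain before / during / after menses) are
mutually exclusive combinations of one timing question; the record
stores three booleans and the significant-parameter below uses their
conjunction.

## Scores

* **PainDETECT final score** = sum of the seven sensory items (0-35)
  + pattern adjustment (persistent/slight fluctuations 0, persistent
  with attacks -1, attacks without pain between +1, attacks with pain
  between +1) + 2 if pain radiates, clamped to [0, 38] (the -1
  adjustment could otherwise produce -1). Bands: negative <= 12,
  unclear 13-18, positive >= 19. A screen with *every* input missing is
  "not scorable", never a silent 0.
* **Sum VAS (ΣVAS)**: the default eight-item variant sums the five
  classical NRS plus pain now, strongest and average pain over 4 weeks
  (range 0-80). A five-item variant (classical symptoms only) is kept
  behind a flag because the published group means of the composite
  (19.2 cases / 5.13 controls) are much closer to the five-item sum of
  the published per-item means (~20 / ~5.5) than to the eight-item sum
  (~35 / ~9.3); the source's own description and its summary table are
  inconsistent, so both variants are implemented and neither is claimed
  to be "the" original computation.
* **Significant-parameter count (ΣSP)**: 34 binary indicators — the
  items the reference study found group-discriminating. Registry
  (serializable JSON, replaceable by the user): analgesic use;
  dysmenorrhea present; dysmenorrhea NRS > 3; pain before *and* during
  menses; CPP; dysuria; dyschezia; dyspareunia; obstipation; diarrhea;
  nine adjectives (cramping, tearing, pulling, stinging, pulsatile,
  touch-sensitive, pressing, cold/warmth, flashing — burning and
  diffuse are excluded, matching the study's selection); pain now > 0;
  strongest > 0; average > 0; seven locations; three of the four course
  patterns (all but persistent/slight fluctuations); PainDETECT final
  >= 4; ΣVAS > 8.5. With this registry, the sum of the published
  per-item case prevalences reproduces the published mean ΣSP in both
  groups (18.80 vs printed 18.88; 5.94 vs 5.98) — the identity that
  pins down the registry membership. A printed cut-off of 8.5 on an
  integer score means "> 8.5", i.e. >= 9. Note the three pattern
  indicators are mutually exclusive, so the attainable per-patient
  maximum is 32, not 34.

## Decision tree

The engine evaluates arbitrary binary trees whose nodes are predicates
over raw answers (`ITEM`), the SP count (`SP_COUNT`) or ΣVAS
(`SUM_VAS`); topology is data (JSON/YAML), validated against the
codebook at load time; missing answers evaluate false.

The original classifier was hand-crafted and only two facts about it
are public: it uses 11 parameters (ΣSP > 8.5 as root; ΣVAS cut-off 12;
dysuria; dyspareunia; obstipation; thighs/legs; vagina; cramping;
pulling; strongest pain in 4 weeks; lightning/flashing pain) and its
confusion matrix on the reference cohort was (tn, fp, fn, tp) =
(100, 9, 9, 110). The branch arrangement is not recoverable, so the
shipped `default_tree` is a reconstruction chosen as follows: among
read-once arrangements of the 11 parameters (root fixed at ΣSP > 8.5,
negative branch terminal), the candidate whose large-sample operating
point on marginal-calibrated synthetic cohorts is closest to the
published confusion matrix. The winner requires, on the positive
branch, ΣVAS > 12 *and* strongest pain > 3 (threshold not published;
configurable), then any of the remaining eight symptoms:

    ΣSP > 8.5 ──no──> no EMS
        └─yes─> ΣVAS > 12 ──no──> no EMS
                  └─yes─> strongest > 3 ──no──> no EMS
                            └─yes─> dysuria ∨ dyspareunia ∨ obstipation
                                    ∨ thighs/legs ∨ vagina ∨ cramping
                                    ∨ pulling ∨ flashing ──> EMS else no EMS

A natural alternative (positive branch = ΣVAS > 12 *or* any
confirmatory symptom) was evaluated and rejected: once ΣSP > 8.5,
nearly every control also carries at least one of the OR-ed symptoms,
giving specificity ≈ 0.71 — incompatible with the published 9/109
false positives. On 50 study-size synthetic cohorts the shipped tree
attains mean sensitivity ≈ 0.92 and specificity ≈ 0.88 (published:
0.924 / 0.917); the residual specificity gap is expected, since the
synthetic dependence structure (one exchangeable factor) cannot encode
whichever conditional independencies the real cohort exploited.

## Diagnostic statistics

2x2 tables are oriented rows = condition (control/case), columns = test
(negative/positive). Fisher's exact two-sided p uses the
point-probability rule (sum of hypergeometric probabilities <= observed,
with a 1 + 1e-7 relative guard); a zero margin yields p = 1 with a
method note. Mann-Whitney uses exact enumeration when both groups have
n <= 8 without ties, else the tie-corrected normal approximation.
Proportion CIs are Wilson score intervals (exact coverage at n = 100 is
0.936-0.943 for p in {0.1, 0.5, 0.9}); ratio CIs (diagnostic odds
ratio, relative risk, likelihood ratios) use the log-normal (Woolf)
method. When any cell is zero, ratio measures use Haldane-Anscombe
+0.5 on all cells and are flagged; proportions are never corrected.
The relative risk is defined as PPV / (1 - NPV) — disease risk given a
positive versus a negative test — which is the definition that
reproduces the published values (15.54, 11.20) exactly from the
published tables; a row-wise risk ratio does not. Published "0.0001"
p-values are treated as "< 0.001" floors. The published CIs are not
internally consistent (e.g. a sensitivity interval excluding its point
estimate), so CIs are never equality-tested against them. ROC AUC uses
the rank (Mann-Whitney) formula with the Hanley-McNeil standard error;
the operating cut-off maximizes Youden's J, is reported as the midpoint
between adjacent distinct observed values, and breaks ties toward
higher specificity. No multiple-testing correction is applied by
default (the reference analysis applied none); Benjamini-Hochberg is
available via `statsmodels` if wanted.

## Synthetic cohort generator

Defaults are the published marginals, every prevalence an exact
fraction (e.g. dysuria 42/119 cases, 1/109 controls; group sizes
119/109). Mechanics:

* 33 binary items per group through a Gaussian copula with exchangeable
  latent correlation `copula_rho` (default 0.3): item *j* is true when
  Φ(√ρ·W + √(1-ρ)·E_j) < p_j, W a per-patient common factor. Marginals
  are honored exactly for any ρ.
* NRS scales: 0 when the presence indicator is false; otherwise a
  rounded truncated normal on [1, 10] with conditional mean
  mean/prevalence (clipped, warning if infeasible) and variance matched
  to the published unconditional SD. Dysmenorrhea additionally honors
  the published severity split (NRS > 3 among reporters) through a
  two-component conditional.
* PainDETECT: the >= 4 indicator is a copula item; conditional on it a
  band (4-12 / 13-18 / 19-38, published proportions) and an integer
  score are drawn, then decomposed into sensory items + pattern
  adjustment + radiating pain so re-scoring reproduces the drawn band
  exactly. Within-band means (cases 1.5 / 8.5 / 15 / 22; controls 0.5 /
  6.5 / 15 / 22) were set so the group means land near the published
  10.0 / 2.3; radiating-pain prevalence (0.25 cases / 0.08 controls) is
  a package default, unreported in the source.
* Timing and course pattern are single categorical draws at the
  published frequencies; demographics are clipped rounded normals;
  small per-item missing rates mirror the published missing-data
  counts.

What the generator does **not** emulate: the true inter-item dependence
(a single exchangeable factor is the simplest structure consistent with
marginal-only information), item-specific response styles, and any
nonlinearity in the real score distributions. Consequences observed and
documented rather than patched: the mean of the 33 directly-sampled
indicators is ρ-invariant (< 0.1 between ρ = 0 and 0.6 at n = 20 000 per
group), but the composite ΣVAS > 8.5 indicator is a threshold of a
correlated sum and shifts by ~0.1; the control-group ΣSP distribution is
more symmetric than the real (right-skewed, SD 5.94) one, so the
Youden-optimal ΣSP cut-off on synthetic cohorts lands at 11.5-13.5
rather than the published 8.5, and all tree-performance checks are band
checks, never equalities.

## Problem sizes and numerical choices

Simulation-based tests use: marginal recovery and calibration at 50-100x
the study size (one seed, vectorized copula); tree operating point over
50 study-size cohorts; ρ-invariance at 20 000 per group; Wilson coverage
computed exactly over the binomial outcome space plus a 2000-replicate
simulation cross-check; Fisher and AUC oracles by exhaustive enumeration
and O(n²) pair counting on tables of total <= 40 and samples n <= 50.
All random draws flow from a single `numpy` generator per run, seeded
explicitly; equal seeds give byte-identical serialized cohorts.

## Known limitations

* The reconstruction of the hand-crafted tree is constrained only by
  its parameter inventory and confusion matrix; other topologies with
  similar operating points exist, and the strongest-pain threshold
  (> 3) is a package default.
* The ΣVAS variant discrepancy (eight-item definition vs five-item-like
  published means) is unresolved by the source; the package defaults to
  the eight-item definition.
* One published case-group NRS mean (dysmenorrhea) is illegible in the
  source table; the generator default (6.3) is back-computed from the
  published grand mean of the eight scales and is not asserted as fact.
* Synthetic cohorts validate the pipeline's internal consistency and
  the marginal calibration; they cannot validate real-world diagnostic
  performance.
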