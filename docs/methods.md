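# Methods

This note documents the scoring rules, the statistical model, the synthetic
trial generator, and the numerical and design choices behind `foptrial`.

## Label engines

**Nutri-Score (foods).**  The engine implements the 2017 published point
bands of the French scheme, which derives from the British FSA
nutrient-profiling system.  Negative points (0–10 each) accrue per 100 g
from energy (kJ, bands of 335 kJ), sugars, saturated fat (bands of 1 g) and
sodium (bands of 90 mg); positive points (0–5 each) from
fruit/vegetable/nut/legume content (1/2/5 points above 40/60/80 %), AOAC
fiber and protein.  Protein is not counted when the negative block reaches
11 points without a maximal FVNL score.  Final points = negative − positive;
grades cut at ≤ −1 (A), ≤ 2 (B), ≤ 10 (C), ≤ 18 (D), else E.  All band
comparisons use strict ">" so a value exactly on a threshold stays in the
lower band; this convention is unit-tested.  The special-category variants
(cheeses, added fats, the 2023 revision) are out of scope: the store this
pipeline emulates did not invoke them.

**Beverages.**  Calorie/sugar-focused beverage grading systems used in
practice are proprietary.  The engine therefore implements a transparent
surrogate: zero-sugar drinks are always grade A; otherwise ascending
inclusive sugar thresholds (defaults 3/5/7 g per 100 mL) assign B/C/D, with
anything above the top threshold E, and a drink whose energy density
exceeds its sugar band's cap (defaults 120/160/200 kJ per 100 mL) is
demoted one grade.  The zero-sugar → A rule is fixed; everything else is
configurable through `BeverageRuleConfig`.  The defaults, together with the
generator's beverage sugar distribution, reproduce an A–E distribution of
roughly 29/11/3/3/54 % — heavy in A (sugar-free) and E (regular sweetened
drinks) — which is the pattern such schemes produce in real store
assortments.  Only the distribution is targeted; the surrogate makes no
claim to reproduce any proprietary rule's per-product decisions.

**Multiple Traffic Lights.**  Colors follow the UK 2016 front-of-pack
technical guidance.  Foods, per 100 g: fat green ≤ 3, red > 17.5; saturates
≤ 1.5 / > 5; sugars ≤ 5 / > 22.5; salt ≤ 0.3 / > 1.5 (amber between).
Boundary values are inclusive on the greener side.  Portions above 100 g
force red when per-portion content exceeds 21 g fat, 6 g saturates, 27 g
sugars or 1.8 g salt.  Drinks use the guidance's stricter bands — half the
food bands for fat, saturates and sugars (1.5/8.75, 0.75/2.5, 2.5/11.25)
and 0.3/0.75 for salt; note the drink salt green bound is the guidance's
0.3 g, not a mechanical halving.  Drink per-portion red thresholds are set
at half the food values.  Salt is derived from sodium at 2.5 g salt per
1000 mg sodium.  Percent-of-reference-intake figures use the EU adult
values (2000 kcal, 70 g fat, 20 g saturates, 90 g sugars, 6 g salt).

## Basket scoring

Weekly household baskets are scaled to per-person-per-day intakes by
dividing by the number of adult household members and by seven.  What
counts as an "adult" is whatever the participant table says; the divisor is
taken as given.

**Modified AHEI.**  Nine of the thirteen AHEI-2010 components are scored
0–10 and summed, maximum 90.  (Alcohol is excluded because the store sells
none, and polyunsaturated fat because nutrition panels do not carry it; the
two remaining omissions follow from building the index on purchase data.)
Anchors, linearly interpolated and clipped:

| component | worst (0) | best (10) | units/day |
|---|---|---|---|
| vegetables | 0 | ≥ 5 | servings |
| fruit | 0 | ≥ 4 | servings |
| whole grains | 0 | ≥ 90 | g |
| SSB + fruit juice | ≥ 1 | 0 | servings |
| nuts & legumes | 0 | ≥ 1 | servings |
| red/processed meat | ≥ 1.5 | 0 | servings |
| trans fat | ≥ 4 | ≤ 0.5 | % of energy |
| long-chain n−3 (EPA+DHA) | 0 | ≥ 250 | mg |
| sodium | highest decile | lowest decile | mg |

The whole-grain anchor uses the 90 g/day value (the published male anchor)
for the whole household, since baskets are not person-resolved.  Sodium is
scored by cohort deciles: the nine cut points default to the deciles of all
per-person-day basket sodium values in the analysis cohort and can be fixed
in configuration; decile d (1 = lowest) scores 10·(10 − d)/9.  Trans fat as
% of energy is 9 kcal/g times the basket's trans-fat grams over basket
kcal; a zero-energy basket is assigned 0 % by convention.  Component
intakes come from per-serving catalog annotations (`ahei_yields`), not from
product-name inference — mapping products to index food groups is
considered input data, and the synthetic generator supplies it.  An empty
basket is scored on zero intakes (absence components optimal, adequacy
components at the floor), not rejected.

**Average Nutri-Score.**  Grades map A=5 … E=1 and the basket value is the
serving-weighted mean, where a line contributes quantity ×
servings-per-pack servings.  "Weighted by serving size" is thus interpreted
as weighting by servings purchased rather than gram weight; a basket with
zero servings has no defined value (NaN).  Per-serving nutrient means use
the same weights.

**Other outcomes.**  Nutrient totals sum per-serving values over lines;
kcal per dollar divides basket energy by spend (rounded to cents).  Orders
are validated against an inclusive $50–$100 spend window, a design device
that keeps baskets representative of a weekly shop.

## First-difference crossover analysis

Every participant shops once under each of Control, MTL and NS, in one of
the six orderings assigned by permuted blocks.  For each treatment shop
with a same-person control shop, the analysis forms Δy = y(treatment) −
y(control), which removes time-invariant individual heterogeneity, and fits

    Δy_is = α + β_NS · NS_is + ε_is

by OLS.  Participants contribute up to two correlated differences (both
contain the same control shop), so the covariance is clustered on
participant with the CR1 small-sample scaling; p-values use a t reference
with (clusters − parameters) degrees of freedom.  Both choices are
configurable.  Estimates are reported with two-sided p-values by default;
the design's directional hypotheses (α > 0, β_NS > 0, α + β_NS > 0) are
available via a one-sided flag.  The NS-vs-Control contrast α + β_NS
carries its own standard error from the full covariance and satisfies the
identity α + β_NS exactly.

Moderator models add a binary moderator and its interaction with the NS
dummy.  Hunger and mood are median-split over all analyzed shops with ties
(value = median) coded 1; income and education are binary participant
attributes.  Moderator values are taken from the treatment shop of each
difference (which shop's survey should enter is genuinely ambiguous; the
treatment shop is the implemented and documented choice).

Stratified runs rescore baskets on food-only or beverage-only lines and
refit every outcome except the modified AHEI, whose components span food
and drink groups and are not scored in isolation; requesting it per stratum
raises an error.

**Power calculation.**  The paired normal approximation with a Bonferroni
adjustment over k comparisons: n = ⌈((z_{1−α/(2k)} + z_{power})/d)²⌉.  At
d = 0.30, α = 0.05, power 0.90 and k = 3 this gives 151 (117 uncorrected).
Trial reports computed with other software sometimes print slightly smaller
requirements for the same parameters; this implementation documents the
formula rather than reverse-engineering any particular tool.

**Risk extrapolation.**  Cohort studies in a comparable population estimate
~21 % lower coronary-artery-disease risk per 10 AHEI-2010 points.  Assuming
linearity, an index gain Δ maps to (Δ/10)·21 % — e.g. a 1.16-point gain to
a 2.4 % reduction — reported to one decimal.  This is an illustrative
extrapolation, not a causal estimate.

## Synthetic trial generator

The generator emulates the study conditions end to end from one integer
seed (hierarchically split so catalog, cohort and shops are independently
reproducible).

*Catalog.*  Default 4,175 products, ~20 % beverages.  Foods are drawn from
twelve archetypes (vegetables, fruit, fish, legumes, nuts, plain dairy,
bread, cereal, fresh and processed meat, sweet snacks, confectionery) whose
macronutrient ranges imply energy (4 kcal/g carbohydrate and protein,
9 kcal/g fat, 2 kcal/g fiber), so panels are internally consistent and
saturated fat never exceeds total fat by construction.  Each product first
draws a target grade from the store's distribution (26/12/26/25/9.8 % A–E
for foods), then rejection-samples a panel from a grade-compatible
archetype until the engine assigns that grade (≤ 60 tries; the rare
mismatch keeps its last draw, leaving the realized distribution within a
couple of points of target).  Beverages draw sugar band-conditionally
(29 % sugar-free) so the default grading rules reproduce the 29/11/3/3/54 %
pattern.  Archetypes also supply the AHEI component yields (e.g. one
vegetable serving per serving of a vegetable product, whole-grain grams as
a fraction of serving weight, n−3 milligrams for fish).

*Cohort.*  Default 168 recruits with age ~ N(34.69, 6.83²) truncated to
21+, BMI ~ N(23.31, 4.07²), 68.7 % female, 67.0 % university-educated,
32.7 % high-income, and a 1–4 adult household distribution (20/55/15/10 %,
a plausible urban mix; the household divisor only rescales intakes).
Sequences are assigned by permuted blocks over the six orderings: complete
blocks contain each sequence once; a final partial block samples without
replacement.

*Shops.*  Each recruit completes 0/1/2/3 shops with probabilities
14/7/2/145 out of 168 (the observed completion pattern), completing shops
in sequence order.  Within a shop, items are added one pack at a time with
probability ∝ exp(a_p + γ_c·h_c(p) − θ·price_p): a_p is a stable product
attractiveness (N(0,1)), θ = 0.08 a price sensitivity, and h_c the
product's numeric Nutri-Score (1–5) under NS or a traffic-light color score
(greens − reds mapped to 1–5) under MTL, with γ_Control = 0.  Draws are
restricted to products still affordable within the $100 cap and stop at the
$50 floor, so every generated order passes spend validation.  Post-shop
mood and hunger are uniform 1–5 ordinals.  The default effect sizes
γ_MTL = 0.05, γ_NS = 0.08 were calibrated once, at design time, to produce
label effects of the magnitude such trials report (roughly one modified-
AHEI point and ~0.1–0.3 average-Nutri-Score points).

The choice model is an artifact device: the real trial observed human
shoppers and specifies no behavioral model.  Because effects are injected
through utility, the label, scoring and analysis stages are genuinely
exercised; `shift_outcomes` additionally provides a direct outcome-level
injection with exact ground truth for statistical calibration, and
`simulate_null_differences` generates correlated difference observations
directly for fast Monte-Carlo work (e.g. the type-I-error check).

What the generator does **not** emulate: brand-level price structure,
within-category substitution patterns, repeat-purchase habits, seasonal or
promotional effects, or any correlation between demographics and taste.
Passing tests therefore demonstrate that the pipeline's algorithms are
correct and its estimator calibrated on data with known structure — not
that real shoppers behave like the utility model.

## Numerical choices and degenerate inputs

* Energy units: kJ and kcal interconvert at 4.184 kJ/kcal; when both are
  supplied they must agree within 2 %.
* Spend boundaries are inclusive and totals are rounded to cents before
  the window check.
* Band/threshold boundaries: Nutri-Score points use strict ">", traffic-
  light colors inclusive "≤" on the greener side, median splits code ties
  as 1 — each convention is unit-tested.
* Cluster-robust variance diagonals are clamped at zero before square
  roots (exact-zero variances can round negative).
* Empty baskets: totals 0, per-serving means and average Nutri-Score NaN
  (NaN differences are dropped from analysis), modified AHEI scored on
  zero intakes.
* Degenerate designs raise typed errors rather than returning numbers:
  a single treatment level or constant moderator (rank deficiency),
  duplicate conditions per participant, empty difference sets, fewer than
  nine sodium cut points.

## Problem sizes used in the checked examples

The test suite and acceptance script run everything at desk scale, chosen
to keep the demonstrations tight while leaving the statistics informative:
catalogs of 250–4,000 products, cohorts of 30–168, a 2,000-replication
null calibration at the analysis sample size (147 participants), and one
full-chain effect-recovery run at 150 participants × 3 shops with 400
products.

## Known limitations

* The beverage surrogate targets a grade distribution, not any proprietary
  scheme's per-product outputs.
* The nine-component index is a basket-level adaptation; AHEI anchors were
  derived for individual diets, and the household divisor assumes equal
  intra-household sharing.
* Whole-grain scoring uses a single (90 g/day) anchor rather than
  sex-specific anchors, since baskets are household-level.
* No carryover or period effects are modeled or estimated, matching the
  design being emulated; the estimator would not detect them.
* The discrete-choice generator is deliberately simple (see above); use it
  to validate pipelines, not to forecast consumer behavior.
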