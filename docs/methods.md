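# Methods

## Spine classification

The classifier is a fixed decision tree over a spine's measured geometry
(total length *L*, head diameter *h*, neck diameter *n*; µm). The first
split is the head-to-neck ratio at 1.1; the mushroom branch confirms
mushroom when *h* > 0.35 µm, the stubby branch confirms stubby when
*L*/*h* ≤ 3, and everything that falls through is filopodium when
*L* ≥ 3 µm and thin otherwise.

Boundary conventions, since the quoted comparators never assign equality:
*h*/*n* = 1.1 routes to the stubby branch (mushroom requires strict >);
*h* = 0.35 µm falls through to the filopodium determination (strict >);
*L*/*h* = 3 stays stubby ("does not exceed" reads as ≤); *L* = 3 µm is
filopodium ("3 µm or more" reads as ≥). Two degenerate-diameter
conventions complete the partition: *n* = 0 (no measurable neck) is treated
as an infinite head-to-neck ratio — a head with no neck is maximally
head-dominated — and *h* = 0 on the stubby branch as an infinite
length-to-head ratio — a headless protrusion is elongation-dominated.
Comparisons are exact on the stored values, with no epsilon tolerance:
determinism and testability outweigh any robustness argument at
measure-zero boundaries. The class set is closed at four; no
"other/branched" category exists.

Density is spines per µm of analysed dendrite internally; the CLI summary
also reports per 10 µm, purely a presentation choice.

## Screen decision rules

* Neuron maturity: mushroom fraction strictly greater than the cut
  (default 0.5). Equality is called immature — the conservative reading of
  "over 50%", giving fewer hits at the boundary.
* Well readout: 100 × mature / evaluable, damaged neurons removed from both
  sides. Wells with fewer than `min_evaluable` (default 10 of the 20 imaged)
  undamaged neurons are invalid and excluded from hit calling, with a log
  record; this avoids unstable percentages from heavily toxic wells.
* Reference: the arithmetic mean of a plate's two DMSO wells. Each plate
  carries its own duplicate vehicle wells and every compound well is
  referenced to its own plate, for both stages.
* Hit margin: strictly more than 10 **percentage points** over the
  reference, not a 10% relative increase — the calibration that motivated
  the criterion compares prevalences of 35.5% vs 24.7% and describes them
  as about 10% apart, which is only true on the points scale.
* Confirmation: a candidate is confirmed when at least
  `confirm_min_passing` (default 1) concentrations of its declared dilution
  ladder individually meet the hit criterion against the secondary plate's
  reference. The original procedure re-tested "at concentrations deemed
  optimal", which is not an algorithm; the ≥1-passing rule is the weakest
  rule consistent with a reproducibility re-test, and the threshold is
  configurable for stricter use.
* Hit rates are rounded half-up to one decimal (decimal arithmetic, so
  13.15 → 13.2).

`run_screen` is a pure function of a plate set and a library annotation.
Because candidates are only known after the primary read-out, the generator
side provides `run_two_stage_screen`, which generates the primary plates,
calls candidates, generates dilution-series plates for the candidates only,
and re-runs `run_screen` over the combined set.

## Synthetic-data generator

The generator is the analysis pipeline inverted, with the following
structure per neuron:

* spine count ~ zero-truncated Poisson(density × dendrite length); defaults
  1.0 spine/µm over 30 µm of dendrite, i.e. about 30 spines per neuron
  (inside the 20–40 range typical of such cultures);
* a per-neuron mushroom mixture weight ~ Beta(κm, κ(1−m)) with
  κ = 10 (`mixture_concentration`), giving realistic neuron-to-neuron
  heterogeneity in spine composition; the non-mushroom mass is split
  thin/stubby/filopodium as 0.60/0.25/0.15, a thin-dominated immature
  remainder;
* spine classes ~ the per-neuron mixture; geometries are drawn from
  per-class log-normal distributions and rejection-sampled until the
  classifier returns the intended class, so round-trip consistency is exact
  by construction. Per-class medians sit comfortably inside each class
  region (e.g. mushroom: head 0.6 µm, neck 0.3 µm, length 1.2 µm), so
  acceptance rates are high and the 1,000-round rejection cap is never
  approached under defaults.

**Calibration.** The Beta mean *m* is solved, per profile, so that the
probability that a neuron's *observed* mushroom fraction exceeds 1/2 equals
the profile's mature-neuron target (0.355 control-like, 0.247
disease-model-like). Because rejection sampling preserves class labels, the
observed mushroom count given *n* spines is exactly
beta-binomial(*n*, κm, κ(1−m)), and the prevalence is a finite sum over the
truncated Poisson count distribution; `calibrate_mushroom_mean` solves it by
Brent's method to 1e-10. The calibration is therefore analytic, not tuned
against simulations. Only the neuron-level prevalence is calibrated; the
spine-level class mixture itself is a free parameter (no printed numbers
constrain it) and is exposed rather than guessed.

**Compound effects** are three-parameter Hill shifts of the mushroom weight:
shift(c) = efficacy · c^hill / (EC50^hill + c^hill), in mixture-weight
points. The shift mass is taken from thin first, then stubby, then
filopodium — matching the observed pharmacology (mushroom up, thin down) —
and the mixture remains a valid probability vector by construction.
Toxicity is a per-neuron damage probability specified at 1 µM; with no
stated concentration-toxicity law, it scales linearly with concentration
and caps at 1. Damaged neurons still carry spines; they are excluded
downstream by the analysis, not by the generator.

**Behavioral cohorts.** The 600 s three-chamber session is allocated over
(novel mouse, centre, novel object) by a Dirichlet draw; by Dirichlet
aggregation the sociability index is Beta-distributed with mean equal to the
profile's `social_index_mean` (defaults: 0.62 control-like and treated,
0.44 disease-model vehicle — a social-avoidance tendency), with
animal-to-animal spread set by the concentration parameter (default 50,
index SD ≈ 0.08). Grooming is Gamma (shape 9) with group means 60 s
(control-like) and 150 s (model vehicle and treated — the treatment restores
sociability but not repetitive grooming), clipped to the session. Default
cohort sizes are 10 vehicle / 12 treated. All behavioral means are invented
plumbing: no per-animal data are published, so they encode the qualitative
group ordering only.

**mEPSC-style samples** are log-normal amplitudes (median 15 pA, log-SD
0.45) with an amplitude scale factor per group (disease-model-like < 1)
and exponential inter-event intervals. They exist to exercise the ECDF and
rank-test machinery, not to model channel physics.

**Randomness.** Every generator is a pure function of (parameters, seed).
Streams are split with `numpy.random.SeedSequence.spawn`, one child per
well, so wells are independent and the layout is order-insensitive;
`run_two_stage_screen` spawns separate primary and secondary streams from
the one top-level seed.

## Statistics

* Mann-Whitney U: midranks; the reported statistic is the smaller U. Exact
  p by full enumeration (via scipy's exact method) when the pooled sample
  is ≤ 16 with no ties, else the normal approximation with tie and
  continuity corrections. Two-sided throughout, as both increases and
  decreases are of interest.
* Kruskal-Wallis: tie-corrected H against chi-square (k−1 df). An all-tied
  dataset returns H = 0, p = 1 (a constant dataset carries no evidence
  against the null; the tie-correction denominator would otherwise vanish).
* Dunn's post hoc: pairwise z from pooled midranks with the tie-corrected
  variance factor N(N+1)/12 − Σ(t³−t)/(12(N−1)); family-wise adjustment is
  Bonferroni over all pairs by default (the convention of the common
  commercial statistics packages), with Holm and no-adjustment options;
  adjusted p capped at 1. The comparison family defaults to all pairs since
  the original selection of comparisons is not stated.
* ECDF: right-continuous, reaching exactly 1 at the sample maximum.
* mean ± SEM with the n−1 SD denominator; SEM requires n ≥ 2.

## Problem sizes used in the checks

The calibration check simulates 5,000 neurons per profile (binomial
3 SE ≈ 2.0 points at these prevalences); the type-I-error check runs 2,000
null replicates at n = 25 per group (Mann-Whitney) and 3 × 15
(Kruskal-Wallis), sizes that exercise the large-sample branches such
studies actually use; the screen power check runs 100 replicates of the
full 181-compound two-stage pipeline with five planted 30-point actives.

## Known limitations

* The generator emulates sampling structure (mixtures, Poisson counts,
  plate layout, duplicate vehicle wells), not imaging: no segmentation
  error, no spatial plate effects, no within-plate drift, no correlation
  between neighbouring neurons. Passing tests demonstrate the decision
  rules and calibration machinery, not robustness to those artefacts.
* Spine-level class mixtures are unconstrained by published numbers; any
  analysis sensitive to them should set `non_mushroom_split` and the
  geometry parameters explicitly.
* Neck diameter for stubby protrusions is accepted as given input; how it
  is measured is outside this package's scope, as is spine detection
  itself.
* The dilution-series confirmation rule is an explicit stand-in for a
  human judgement ("concentrations deemed optimal") and is deliberately
  configurable.
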