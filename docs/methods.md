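# Methods

This note documents the models, conventions and design choices behind
`paleowear`, in the spirit of a statistical package's model
documentation: what is computed, under which assumptions, which knobs
exist, and what the tests do and do not establish.

## Mesowear

A cusp observation is a (relief, shape) pair with relief ∈ {high, low,
none} and shape ∈ {sharp, rounded, blunt}; "no relief" is only
consistent with a blunt apex, so seven combinations exist and are mapped
bijectively onto stages 0–6:

| | sharp | rounded | blunt |
|---|---|---|---|
| **high relief** | 0 | 1 | 4 |
| **low relief** | 2 | 3 | 5 |
| **no relief** | — | — | 6 |

The table is the minimal complete ruler consistent with the published
anchors (0 = high/sharp, 6 = none/blunt) and is monotone: losing relief
or gaining bluntness never lowers the stage (checked exhaustively in the
tests). Per tooth, the default cusp rule keeps the sharpest usable
cusp (`mesowear.cusp_rule = "sharpest"`; `"mean"` is available) — the
sharpest apex is the least taphonomically degraded record of attrition.

Diet from the assemblage mean MWS uses cutpoints (1.5, 2.1, 3.6):
browser [0, 1.5), browse-dominated mixed [1.5, 2.1), grass-dominated
mixed [2.1, 3.6), grazer [3.6, 6]. These are the minimal piecewise
partition consistent with every anchored classification the package must
reproduce (1 → browser; 2.3, 2.7, 3 → grass-dominated mixed; 4, 4.36,
5.3 → grazer). The browse-dominated band has **no anchor**: no
published statement pins an MWS value inside [1.5, 2.1), so that
boundary is a convention, not a calibrated fact. Cutpoints are
configurable.

## Microwear

Per-tooth NS/NP are arithmetic means over replicate 0.16 mm² counting
fields and may be fractional. The low scratch range uses the inclusive
rule NS ≤ 17.0, so a tooth averaging exactly 17 counts as low-scratch.

LSR diagnostic bands (in % of teeth): browsers 72.73–100, mixed
20.93–70, grazers 0–22.2. Two awkward regions are made explicit rather
than hidden: the *gap* (70, 72.73) is reported as a boundary call
leaning browse-dominated, and the *overlap* [20.93, 22.2] as a boundary
call classed grass-dominated mixed. Within the mixed band the
dominance qualifier flips at `mixed_midpoint = 45.5` (grass-dominated
below, browse-dominated above); the midpoint reproduces the anchored
dominance statements on either side (28.57 → grass-dominated, 62.5 →
browse-dominated) and is configurable.

The bivariate classifier tests the assemblage (NS, NP) centroid against
p = 0.95 Gaussian ellipses (χ²₂ quantile 5.991) fitted by maximum
likelihood to reference points. **The bundled reference table
(`data/references/extant_microwear_synthetic.csv`) is synthetic**: the
original extant browser/grazer per-taxon averages are not
redistributable here, so the file contains invented values on the
correct scale, calibrated so the qualitative membership statements for
the fossil assemblages hold (deer centroids inside the browser ellipse;
horse/bovid centroids outside the grazer ellipse through pit excess
alone). Ellipse-membership results against this bundle validate the
algorithm and the calibration, not extant-ungulate biology; users with
access to real reference data should drop in their own CSV.

The "excess pits" flag fires when NS lies within a class's marginal NS
interval (the ellipse projection, mean ± √q·σ) while NP exceeds the
marginal NP maximum — separating "wrong diet" from "right diet, pit
excess (grit/dust)".

## Event-duration zoning

CV\* = (SD/mean)(1 + 1/(4n)) is the standard small-sample bias
correction of the coefficient of variation; it reproduces every printed
CV\* cell whose mean/SD/n are unambiguous, which is why this form (and
not, e.g., Sokal's √n variant) is used. Full precision is kept
internally; 2-decimal half-up rounding is applied only when writing
tables.

The zone surface is estimated by simulation because no numeric
boundaries are published: scratch counts are truncated-at-zero normals
(counts of 14–27 with SDs ≈ 1.6–3.8 are far under-dispersed relative to
Poisson, so a free-SD family is required); an assemblage is n i.i.d.
teeth; multi-season events are 50/50 mixtures with each tooth's season
drawn uniformly. Per simulated assemblage the (CV*, SD) pair is
computed exactly as for real data. Class probabilities on a 61×61 grid
come from per-case product-Gaussian KDEs (Scott bandwidths per
dimension; a product kernel is used because CV* and SD are nearly
collinear in simulation, making a full sample covariance
ill-conditioned) normalized with equal priors; nodes with negligible
density fall back to uniform 1/3. An isotonic-regression pass then
enforces that p(single) is non-increasing in SD at fixed CV* — larger
scratch dispersion never makes a single-season event *more* likely —
with the other two classes rescaled to keep node sums at 1.

Defaults of the packaged surface: reference mean 20 scratches, SD 2.4,
seasonal shift δ = 5.8 scratches, n = 15 teeth per assemblage, 1200
replicates per case, fixed seed. Mean and SD sit at the centre of the
fossil scratch statistics; δ is calibrated so the packaged surface
reproduces the published qualitative zone placements (all deer
assemblages and horse level 8 in zone A, horse level 7 in zone B, large
bovids level 7 on the A/B boundary). The surface is therefore a
*stated calibration*, not an estimate of the original authors'
boundaries; refit with your own parameters via `ZoneBoundarySimulator`
or `paleowear zones fit` (models serialize to JSON and reload
bit-identically).

Zone calls use argmax with boundary tolerance τ = 0.10: when the top
two class probabilities differ by less than τ the point is reported as
`boundary_AB`/`boundary_BC`. A degenerate request (δ = 0) warns and
returns the exactly equiprobable surface, since the three generators
are then identical.

The model's probabilities are deliberately conservative: KDE smoothing
flattens the posterior, so the argmax recovery rate of simulated
single-season events *exceeds* the mean posterior probability of the
single class. The self-consistency test is accordingly one-sided
(recovery ≥ mean p(single) − 3 pp).

## Wear discrepancy

The annual (mesowear) and last-weeks (microwear) diets are compared;
a flag is raised when the main classes differ, when exactly one side is
a boundary call, or when both are mixed with opposite dominance
qualifiers. The flag is recorded as evidence in the occupation report
but does not by itself drive any label: the rule cascade below uses
zones and cementum seasons, which subsume the discrepancy signal.

## Cementochronology

Pairs are counted as adjacent complete TB→OB couplets; a leading,
unpaired OB (an animal whose readable record begins with an annulus) is
tolerated and not counted; a trailing incomplete TB is flagged
separately and never counted. %Dev divides the incomplete TB by the
mean of *complete TBs only* — opaque bands are too thin to measure
reliably, so they never enter the reference; this reading of "mean
thickness of the older increments" is an interpretation and is
documented as such. %Dev > 100 (the final year outgrowing the average
of earlier years) is clamped to 100 with a flag rather than raised as an
error, since inter-annual thickness varies.

Season categories use the bounds beginning 1–33.3 / middle 33.4–66.6 /
end 66.7–100, applied after rounding %Dev to one decimal half-up (which
also resolves values falling inside the printed gaps 33.3–33.4 and
66.6–66.7). Values below 1 % are treated as a nascent TB, i.e.
beginning.

Age = pairs + pre-eruption age, widening to the half-open interval
[e + pairs, e + pairs + 1) when a partial year is present. The bundled
eruption-age table (`data/config/eruption_ages.csv`) carries rounded
literature-scale defaults per taxon and molar (e.g. red deer m1 0.5 y,
m2 1.25 y, m3 2.5 y) and is a config file, not a claim; whether the
innermost increment can itself be a partial year (birth-season effect)
is not modelled, adding a ±1 ambiguity the interval does not capture.
Calendar anchoring of the bad season (roughly December–February in the
actualistic sources) is presentation metadata only and never enters any
computation.

## Occupation rule cascade

Evidence per level: zone calls and discrepancy flags per taxon, pooled
season-of-death distributions per taxon. Rules fire in order:

1. any zone C → `non_consecutive_events`;
2. any zone B, or any season category set (per taxon or pooled across
   taxa) that cannot form a contiguous seasonal window →
   `long_or_repeated_multi_season`;
3. all zones A with a contiguous window → `single_short_seasonal` (one
   category) or `repeated_short_same_season` (several), carrying the
   window text;
4. all zones A without cementum evidence → `repeated_short_same_season`
   at `wear_only` confidence, with an explicit note that a long-term
   pattern cannot be excluded.

*Window contiguity.* The season order is bad → beginning → middle →
end of good season. A window is a linear run in that order; a cyclic
wrap across the year boundary (end → bad) is accepted only for
two-category windows (a fall-to-winter span). A three-category wrapped
arc — deaths at both shoulders of the good season *and* in winter —
covers most of the annual cycle and is treated as multi-season, not as a
window. This convention is what separates a winter-through-spring
window (bad, beginning, middle: contiguous) from a fall + winter +
spring-shoulder spread (end, bad, beginning: multi-season), matching the
anchored per-level outcomes.

The cascade deliberately does **not** separate "one long occupation"
from "repeated short occupations across seasons": dental data cannot
distinguish them, so one label keeps both and the report says so.
Confidence is `wear_plus_cementum` only when at least one season
distribution contributed a determination.

## Synthetic data

The generators emulate: per-diet-class NS/NP truncated normals
(browser 13.2/25.5, mixed 17.2/24.0, grazer 21.6/14.0, SDs 2.1–4.0),
seasonality as an NS mean shift δ (default 5.8, matching the zone
surface), Bernoulli qualitative features, categorical texture scores,
and annual cementum couplets (TB 60 ± 3 µm between years, OB 8 ± 1 µm)
with a death date that truncates the final TB at fraction f of that
year's width. Measurement error is proportional — one optical reading
has SD 10 % of band thickness — and each band is read on 3 replicate
thin sections whose mean is recorded, mirroring the standard practice of
cutting several sections per root. The season-recovery simulations in
the tests and the acceptance script run under exactly these conditions
(1000 replicates, 4–9 year lives, death fractions ≥ 5 points from
category bounds).

Not emulated: taphonomic signal erasure beyond boolean flags,
correlated features within teeth, unreadable/false increments,
between-individual age structure, and real extant reference biology (see
above). Passing tests therefore demonstrate correctness and internal
consistency of the pipeline under the stated generative model — not that
the classifiers are well-calibrated for any particular fossil
assemblage.

## Numerical conventions

* Presentation rounding: 2 decimals half-up (CV*, %Dev, percentages) in
  writers only; computation at double precision throughout.
* Missing statistics (SD/CV at n = 1) are represented as missing, never
  as 0.
* All stochastic operations require a seed; identical seeds give
  byte-identical outputs (site bundles, serialized models, pipeline
  products except the timestamped log).
* Simulation sizes (1200 replicates per case for surface fitting, 1000–
  2000 for the Monte-Carlo property checks, 61×61 grid) were chosen as
  the smallest sizes at which the fitted surfaces and measured rates are
  stable to well under the decision tolerances.
* A boundary-tolerance call (τ) sits on a knife edge by construction;
  re-entering the pipeline through 2-decimal summary tables can
  legitimately flip a within-τ call to the flanking zone. The
  round-trip tests treat a boundary call and its flanking zones as the
  same downstream statement.

## Known limitations

* The LSR bands, MWS cutpoints and zone surface are calibrated to
  reproduce anchored qualitative statements; they carry no uncertainty
  quantification of their own.
* One summary row per taxon × level is the analysis grain; multi-taxon
  joint zoning and inter-site comparison are out of scope.
* The published summary tables bundled as fixtures contain two cells
  whose original layout is ambiguous (flagged `layout_uncertain`), and
  per-taxon totals that disagree slightly between text and table; the
  fixtures transcribe the rows as printed and the flags travel with the
  data.
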