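# Methods

This note records the models, conventions and default parameters behind
`trophnet`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Growth calls and metabolic profiles

A strain × carbon-source well is scored as growth when the mean of its
replicate OD600 readings is strictly greater than the threshold (default
0.05, dimensionless optical density). The mean is computed in exact rational
arithmetic before a single rounding, so a replicate set whose mean equals
the threshold is scored as no growth rather than drifting across the strict
inequality through floating-point accumulation. Wells are aggregated by
mean rather than called individually because inputs ship replicate plates;
an optional blank subtraction can be applied upstream — readings are taken
as final corrected values.

Breadth classes cut the used-source fraction of the panel (46 sources by
default) at strict 25 % and 50 %: below the first cut a strain is a
*specialist*, above the second a *generalist*, and the closed band between
them *intermediate*. The intermediate class exists because the two named
classes cover only part of any realistic collection.

## Trophic patterns

**Niche overlap** between two binary profiles is reported as a percentage
under two denominators: `jaccard` (shared sources / union of sources, the
default, 0 when both profiles are empty) and `total` (shared sources /
panel size). The field phrase "percentage of species using the same carbon
source" does not fix a denominator, so both are computed and written to
output tables; the Jaccard form is used wherever a single overlap value is
needed (planted effects, regressions, group comparisons).

**Connectance** is C = L/S² with L the total number of species→resource
links and S the species richness. Note this is a bipartite link density
against S² rather than S × resources, so C may exceed 1 for small
communities on a large panel; it is reported exactly as defined.

**Nestedness** is NODF. For every unordered pair of rows with strictly
decreasing marginal totals, the paired contribution is 100 · |intersection|
/ (smaller marginal); ties contribute 0, as do pairs whose smaller marginal
is 0. Column pairs are treated symmetrically and the score is the mean over
all row and column pairs. Empty rows/columns therefore stay in the
denominator as zero-contribution pairs — the convention of the original
decreasing-fill definition and of the R implementations
(`vegan::nestednodf`, `bipartite::nested`), against which this
implementation is cross-checked in the test suite. The score is invariant
under row/column permutation; matrices with fewer than two non-empty rows
or columns are rejected as degenerate.

## Interaction classification

The null expectation for a pair is that coculture yield tracks its
monocultures. Operationally, with replicate A590 yields for monocultures A,
B and the coculture:

* *positive* — a one-sided Welch two-sample test of the coculture
  replicates against the best monoculture's replicates rejects at `alpha`
  **and** the coculture mean strictly exceeds the best monoculture mean;
* *negative* — a one-sided one-sample test of the coculture replicates
  against the monoculture average rejects at `alpha` **and** the coculture
  mean is strictly below that average;
* *unresolved* — otherwise. Because best ≥ average, positive and negative
  are mutually exclusive, and the band between average and best acts as a
  buffer for ambiguous pairs.

Defaults: `alpha = 0.05`; the 3 biological × 4 technical replicate design
is collapsed to biological means (n = 3) before testing to avoid
pseudo-replication (`pooling="wells"` uses all 12 wells instead). A tie in
monoculture means is broken by pooling both monocultures' replicates for
the positive test. When a sample has zero variance the test degenerates to
the exact mean comparison (p = 0 in the alternative's direction, else 1),
which is what makes the noise-free limit exactly recoverable. Setting
`alpha = 1` disables the significance requirement and leaves the pure
threshold rule. Replicate means use the same exact-rational single-rounding
scheme as growth calls, so equality cases (coculture exactly at the
monoculture average) resolve as unresolved instead of being decided by
summation order.

Intensity is the mean coculture A590 itself; A590 readings are assumed
dilution-corrected upstream.

## Networks

Resolved pairs become undirected edges carrying their sign and intensity as
weight; unresolved pairs are excluded (this is forced by the bookkeeping
identity edge count = positive + negative counts). Treatment networks
include cross-fraction edges; fraction subnetworks keep only edges whose
both endpoints sit in the fraction, so a treatment's subnetworks have
disjoint edge sets that are subsets of its network. Isolated strains are
dropped.

Metrics follow common graph-tool defaults: average degree 2E/N; average
weighted degree 2·Σw/N; clustering as the unweighted mean local clustering
coefficient; path length as the unweighted mean shortest path on the
largest connected component; modularity from a Louvain pass on edge weights
with resolution 1 and an explicit seed. Louvain is stochastic — a fixed
seed is exactly reproducible, and on the default synthetic networks the
across-seed spread is below 0.05 (checked as a regression-style property,
not an exact value). GraphML/GEXF exports carry node attributes (treatment,
fraction, breadth class) and edge attributes (sign, weight) and round-trip
exactly.

## Association statistics

Three simple OLS families: positive-edge percentage on connectance (one
observation per network — 12 under the full 3 × 3 design); intensity on
community nestedness; and intensity on pairwise niche overlap (one
observation per resolved pair, fitted separately within positive and
negative pairs, since the two signs sit on different intensity ranges).
Nestedness is a community-level statistic, so each pair inherits the NODF
of its treatment community — the only defensible per-pair assignment, and
an acknowledged granularity compromise. Slope p-values are two-sided; no
multiple-testing correction is applied across the three families (raw
p-values are reported). A response with zero variance yields the flat fit
(slope 0, R² 0, p 1) rather than an error.

Group comparisons are one-way ANOVA with Tukey HSD at `alpha = 0.05`. When
grouping by treatment, fractions are ignored, and vice versa. The compact
letter display assigns one letter per maximal clique of the pairwise
non-significance graph (equivalent to insert-and-absorb at these group
counts): groups sharing no letter differ. Per-pair overlap observations
share strains, so their letters describe separation of the realized
distributions, not independent-sample inference — the same caveat applies
to any all-pairs overlap comparison. Community-level comparisons
(connectance, NODF) use the 4 networks per treatment or the 3 subnetworks
per fraction.

## Synthetic communities

The generator emulates a culture-collection study design: 122 strains in 9
treatment × fraction cells (35/46/41 per treatment), 46 carbon sources,
within-treatment all-pairs cocultures (595 + 1035 + 820 = 2450), 3
biological × 4 technical replicates. Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `specialist_use_p` / `intermediate_use_p` / `generalist_use_p` | 0.15 / 0.40 / 0.62 | per-source use probability by breadth class, placing realized breadth near the class bands |
| `specialist_fraction` / `generalist_fraction` | 9/122, 27/122 | planted class mix |
| `treatment_shifts` | CK −0.08, M 0, NPK +0.08 | additive use-probability shifts planting the overlap ordering NPK > M > CK |
| `fraction_shifts` | macro +0.08, micro 0, silt −0.08 | same for macro > micro > silt; the magnitude is the smallest round value at which the planted orderings are reliably recoverable by Tukey letters across seeds, which is the design contract of the defaults |
| `od_positive_mean` / `od_negative_mean` / `od_noise_sd` | 0.30 / 0.01 / 0.01 (OD600) | growth wells sit far above the 0.05 threshold, non-growth wells far below |
| `mono_yield_mean` / `mono_yield_cv` | 0.5 / 0.3 (A590) | lognormal monoculture biofilm yields |
| `synergy_base` | 0.12 (A590) | baseline positive deviation of a coculture from the monoculture average at zero overlap; with the default overlap distribution this places the planted regime mix near the ~35/47/18 positive/negative/unresolved composition of the emulated screen |
| `interaction_effect_slope` | −0.5 (A590 per unit overlap fraction) | planted negative effect of niche overlap on coculture yield |
| `pair_noise_sd` | 0.12 (A590) | pair-level scatter around the planted deviation law |
| `noise_sd` | 0.05 (A590) | replicate noise, applied at both biological and technical levels |

Planted coculture means are `avg_mono + synergy_base + slope ·
overlap/100 + pair noise`, truncated at zero; truth regimes apply the pure
threshold rule to these planted means, which makes them the `alpha = 1`
limit of the classifier. `GeneratorConfig.noise_free()` switches off OD and
A590 replicate noise (pair-level scatter stays, as part of the planted
means), in which limit the pipeline recovers profiles, overlaps and regimes
exactly — the identifiability contract the tests assert.

What the generator does **not** emulate: phylogenetic signal in profiles,
heteroscedastic or plate-position measurement error, day effects beyond
exchangeable biological replicates, higher-order (3+ strain) interactions,
and any mechanistic biofilm growth dynamics. Passing recovery tests
therefore show the pipeline is correct and well-calibrated under the
planted statistical structure, not that real assay data meet that
structure.

## Problem sizes and determinism

Tests run the full 122-strain design where the contract concerns it
(orderings, recovery rates across 100 seeded replicates) and a 27-strain
3 × 3 design elsewhere; the acceptance script runs the full design once.
Everything is driven by `numpy.random.default_rng` seeded from a single
integer; identical config + seed reproduces bundles and result directories
byte for byte (run logs carry no timestamps for this reason).

## Known limitations

* Published count tables from comparable screens are reproducible in
  structure (pair totals, edge bookkeeping, derived percentages) but not in
  raw classification counts, which depend on unreleased replicate-level
  measurements and an unstated test/alpha choice.
* The hypothesis-test layer at n = 3 biological replicates is conservative;
  many truly non-null pairs land in *unresolved* at `alpha = 0.05`. This is
  by design (the buffer is part of the scheme), but comparisons of resolved
  fractions across settings should hold `alpha` and pooling fixed.
* Connectance under L/S² is scale-dependent; comparisons are meaningful
  only between communities assayed on the same panel.
* Gephi-style modularity/clustering/path-length values from other tools may
  differ by their weighting and directedness defaults; only average degree
  is arithmetically determined by printed node/edge counts.
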