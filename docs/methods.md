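# Methods

This note documents the statistical procedures, the synthetic-data model,
and the design choices that were genuinely open.

## Data model and conventions

Counts are NISP, or MNI at sites whose reports give only MNI; both enter
the same arithmetic, flagged by the site's `quantification_basis`. Sites
are graded by source quality: A (quantitative for all taxa), B
(quantitative for selected taxa), C (presence-only). Source C sites may
not carry counts; their taxa are recorded as presence-only rows (an empty
`count` cell in `counts.csv`) and contribute to occurrence and richness
but never to abundance. Latitude is stored as signed decimal degrees
(southern hemisphere negative) so trend fits are unambiguous.

Relative abundance excludes remains recorded only at class level from
both numerator and denominator, while total NISP keeps them; the share of
a class's remains identified beyond class level is reported separately as
`identified_fraction`. Richness follows the Minimal Level of Taxonomic
Identification: within an assemblage, a record subsumed by any present
descendant (matched through lineage names) is discarded, and class-level
records never count. Occurrence is hierarchical — a family occurs
wherever any member genus or species does — because supra-specific
occurrence must be able to exceed that of any single member.

Display rounding: percentages to one decimal, occurrence frequencies to
the nearest integer, p-values to four decimals in tables. Internal
arithmetic is always full precision.

Trophic level for supra-specific taxa is the mean TL of regional
archaeological species within the taxon, falling back to a configured
checklist when no regional member exists; unresolvable taxa are excluded
from WATL with a logged warning. WATL weights are the class-level-excluded
relative abundances renormalised over TL-resolvable taxa; a
presence-weighted variant is available because abundance weighting is a
modelling choice, not a logical necessity.

## Recovery-bias diagnostics

Mesh sizes 2 and 3 mm are pooled (both considered adequate for fish
remains); 4 and 5 mm stand alone. Group comparisons use one-way ANOVA
followed by Tukey's HSD on the studentized-range distribution, with the
Tukey–Kramer adjustment since group sizes are unbalanced. The SR ~
NISP/m³ association uses Pearson's r with a two-sided t-based p. The
endmember diagnostic removes the site simultaneously maximal in both
variables (falling back, flagged, to the largest Mahalanobis distance
when no such point exists) and reports both correlations, quantifying the
leverage a single rich site exerts.

## Trait null model

The total pool is the union of all period catch lists with the regional
assemblage list. For each trait × period, the observed values of the
period's *n* species are contrasted with 1000 random assemblages of *n*
species drawn from the pool without replacement within a draw
(richness-matched null). Size and mass are analysed on the natural-log
scale throughout (their raw distributions span orders of magnitude and
the log scale is where their allometric coupling is linear); trophic
level is analysed raw.

Two test constructions are implemented because the construction of a
"two-sided t-test against null values" is ambiguous:

* **welch** (default): Welch's t of the observed values against all
  pooled null values. This mirrors the common reporting style, but it
  treats the observed mean's sampling variance as σ²/n, ignoring the
  finite-population correction (N−n)/(N−1) of a without-replacement draw
  from a pool of N; at N = 365, n = 62 that correction is ≈ 0.83, so the
  test is mildly conservative (its realized type-I error sits below the
  nominal 5%).
* **empirical**: two-sided rank of the observed trait mean within the
  1000 null draw means, p = 2·min(rank tails)/(reps+1), capped at 1.
  Under the null the observed catch is exchangeable with the null draws,
  so this construction is exactly calibrated; the calibration and power
  guarantees in the acceptance suite are stated for it. The acceptance
  script reports both.

Across-period trait contrasts use the same ANOVA/Tukey machinery as the
recovery module (log scale for size and mass). Body-size classes follow
one-decimal binning with upper-inclusive breaks at 15.0, 30.0, 50.0 and
80.0 cm and a strict upper bound for "<7" — so 30.0 cm falls in
15.1–30.0 and 30.05 cm in 30.1–50.0. Functional entities are the guild ×
size-class pairs (at most 36). Proportion contrasts between two periods
use the exact two-tailed binomial test (minimum-likelihood two-siding,
via `scipy.stats.binomtest`), with the comparison period's observed
proportion as p0 and the focal period's k/n; both directions can be
reported since the null choice is a convention.

Null-model defaults: reps = 1000, seed = 20230525; every result records
its reps, seed and mode.

## Synthetic-assemblage generator

The generator encodes the study conditions the pipeline targets, so every
downstream stage can be tested against known ground truth.

* **Pool** (default n = 365): TL ~ 2.0 + 2.9·Beta(4, 3) (bounded, mildly
  top-heavy, as in a coastal fish fauna); log10 L_max ~ N(1.65, 0.35)
  (median ≈ 45 cm); log10 W_max = −2 + 3·log10 L_max + ε, the standard
  cubic length–weight allometry with W ≈ 0.01·L³ g, with
  sd(ε) = 3·0.35·√(1/r² − 1) so that the squared log size/mass
  correlation targets r² = 0.67. Feeding guilds are drawn from
  TL-conditional probabilities (herbivores/planktivores at low TL,
  invertivores in the middle, macrocarnivores/piscivores above TL 4).
  A synthetic taxonomy (species within genera, families and orders per
  class, ~20% cartilaginous) supports MLTI and occurrence tests.
* **Period catches** (defaults 62/34/94 species): sampled without
  replacement with inclusion weight ∝ exp(β_TL·TL + β_logL·ln L), via the
  Gumbel top-n trick on log weights (no overflow; β → ∞ degenerates to
  the n largest). Defaults: β = (1.0, 1.5) for the two pre-European
  periods, (0, 0) for the modern period — the selective-past /
  neutral-present contrast the null model is meant to detect.
* **Site assemblages**: total NISP ~ 10^U(2,5); specimens allocated over
  catch species by a lognormal species-abundance distribution (σ = 1.0)
  renormalised into a multinomial; each specimen retained with logistic
  probability in ln body size around a mesh-dependent midpoint
  (midpoint_cm = 4·mesh_mm; slope 2; midpoint 0 disables sieving);
  retained specimens identified beyond class with probability 0.17 (bony)
  or 0.567 (cartilaginous), otherwise recorded under the class taxon.
  Volumes are uniform on [0.06, 13.8] m³, latitudes on [−31.5, −25].
* **Reproducibility**: every generated object draws from its own
  `numpy` SeedSequence derived from (config seed, object id), so objects
  are independently reproducible and a fixed config yields byte-identical
  datasets.

What the generator does **not** emulate: bone fragmentation and
differential preservation, genus-level (as opposed to class-or-species)
identification, spatial autocorrelation among sites, within-species body
size variation (traits are species-level maxima), and real taxonomic
name structure. Passing tests therefore demonstrate the correctness and
calibration of the estimators under a plausible data-generating model,
not the historical conclusions drawn from any real dataset.

## Problem sizes and numerical choices

The acceptance suite uses 1000 simulated catches for the type-I
calibration (empirical mode, acceptance band 5% ± 2%), 200 for power
under β_logL = 1.5 at n = 62 (threshold 80%), 10,000 draws for the
finite-population moment checks (variance tolerance 6%, ≈ 4 Monte-Carlo
standard errors), and exhaustive enumeration of the binomial test for all
n ≤ 20. Unit tests use smaller replicate counts chosen to keep the suite
fast while leaving comfortable margins at the asserted tolerances.

Ties in the binomial minimum-likelihood two-siding are resolved with a
(1 + 1e−10) relative slack on the pmf comparison, matching standard
practice. Tukey p-values at k = 2 agree with the pooled t-test to the
1e−4 precision of the underlying studentized-range quadrature. OLS
confidence bands are pointwise 95% bands for the mean response.

## Known limitations

* The Welch null-model mode is conservative by construction (see above);
  significance decisions near the 0.05 boundary can differ between modes.
* Occurrence matching is by taxon name through lineages, so homonyms
  across classes would collide; synthetic names are unique by
  construction and real datasets should be checked.
* MNI and NISP are pooled in all arithmetic; no attempt is made to
  harmonise the two quantification bases.
* Plots are not produced; all outputs are CSV/JSON tables (the figures
  of a typical report are straightforward to build from them).
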