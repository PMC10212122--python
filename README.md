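# paleocatch

Quantitative analysis of zooarchaeological fish assemblages for marine
historical ecology: who was catching what, how the recovery methods distort
the record, and whether past catches were functionally different from
modern ones.

The package targets the kind of dataset produced by regional syntheses of
Middle/Late Holocene coastal sites: per-site, per-cultural-phase taxon
counts (NISP, occasionally MNI) at heterogeneous taxonomic ranks, site
recovery metadata (sieve mesh, excavated volume, chronology), a species
trait table (trophic level TL, maximum body length L<sub>max</sub>,
maximum body mass W<sub>max</sub>, feeding guild), and presence lists of
fisheries targets per time period.

## What it computes

**Abundance and richness** (`paleocatch.abundance`)
— relative abundance with class-level records (Actinopterygii /
Elasmobranchii) excluded from the denominator; hierarchical occurrence
frequency across sites; species richness under the Minimal Level of
Taxonomic Identification (MLTI: a record is subsumed by any present
descendant; class-level records never count); NISP/m³ and SR/NISP;
trophic-level attribution for supra-specific taxa (regional species means
with a configurable fallback list); abundance-weighted average trophic
level WATL = Σᵢ wᵢ·TLᵢ; OLS trend fits with 95% confidence bands.

**Recovery-bias diagnostics** (`paleocatch.recovery`)
— mesh classes (2–3 mm pooled, 4 mm, 5 mm), one-way ANOVA with Tukey HSD
(Tukey–Kramer for unbalanced groups), Pearson SR ~ NISP/m³, and endmember
sensitivity (the correlation with and without the site maximal in both
variables).

**Trait null model** (`paleocatch.nullmodel`) — the core inference. For a
period catch of *n* species, draw 1000 random assemblages of *n* species
(without replacement) from the total regional pool (fisheries targets ∪
regional assemblage list) and compare the observed trait distribution
(TL raw; ln L_max and ln W_max) against the null draws, two-sided. Also:
across-period ANOVA/Tukey, body-size classes (<7, 7–15.0, 15.1–30.0,
30.1–50.0, 50.1–80.0, >80 cm), trophic-group and functional-entity
(guild × size class) proportions with exact two-tailed binomial tests,
and per-period minimum trophic level.

**Synthetic assemblages** (`paleocatch.synthetic`) — a generator with
known ground truth: a 365-species pool with Beta-distributed TL on
[2.0, 4.9] and allometrically coupled log size/mass (corr² calibrated to
0.67); period catches of 62/34/94 species drawn with selectivity weight
exp(β_TL·TL + β_logL·ln L); site assemblages via lognormal species-abundance
allocation, logistic sieve retention in ln body size, and class-level
identification rates (17% of bony remains identified beyond class, 56.7%
of cartilaginous).

## Worked example

```python
from paleocatch.synthetic import GeneratorConfig, simulate_dataset
from paleocatch.nullmodel import build_total_pool, run_trait_null_model

dataset, truth = simulate_dataset(GeneratorConfig(seed=42))
pool = build_total_pool(dataset.periods.values(), dataset.traits.keys(),
                        dataset.traits)
for r in run_trait_null_model(pool, dataset.periods, dataset.traits,
                              reps=1000, seed=42):
    print(f"{r.period_id} {r.trait:<18} observed mean {r.observed_mean:6.3f} "
          f"null mean {r.null_mean:6.3f}  p = {r.p:.4g}")
```

prints

```
P1 trophic_level      observed mean  3.788 null mean  3.671  p = 0.07781
P1 max_body_size_cm   observed mean  4.585 null mean  3.855  p = 3.41e-11
P1 max_body_mass_g    observed mean  9.238 null mean  6.981  p = 6.713e-09
P2 trophic_level      observed mean  3.892 null mean  3.668  p = 0.007761
P2 max_body_size_cm   observed mean  4.592 null mean  3.847  p = 1.013e-06
P2 max_body_mass_g    observed mean  9.492 null mean  6.947  p = 2.342e-06
P3 trophic_level      observed mean  3.607 null mean  3.674  p = 0.1682
P3 max_body_size_cm   observed mean  3.914 null mean  3.853  p = 0.404
P3 max_body_mass_g    observed mean  7.095 null mean  6.960  p = 0.6011
```

The two pre-European periods (P1, P2) were generated with selectivity
toward large, high-trophic-level species and are detected as significantly
displaced from the null for size and mass (means are on natural-log
scales: observed mean ln L_max 4.59 ≈ 98 cm vs null 3.86 ≈ 47 cm); the
modern period (P3) was generated neutrally and is statistically
indistinguishable from random draws of the pool.

The same analyses are available from the shell:

```sh
paleocatch simulate --seed 42 --out data/
paleocatch validate --data data/
paleocatch traits --data data/ --reps 1000 --seed 42 --out tables/
paleocatch run-all --seed 42 --out run/        # everything + manifest.json
```

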