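"""Abundance, richness, trophic-level attribution and trend fits."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleocatch.abundance import (
    aggregate_counts,
    nisp_density,
    occurrence_frequency,
    relative_abundance,
    species_richness_mlti,
    sr_per_nisp,
    taxon_trophic_level,
    trend_fit,
    watl,
)
from paleocatch.types import (
    AssemblageRecord,
    Dataset,
    SiteRecord,
    TaxonRecord,
    TraitRecord,
)


def make_taxa(*specs):
    return {s[0]: TaxonRecord(*s) for s in specs}

HIER_TAXA = make_taxa(
    ("cl1", "Actinopterygii", "class", (), "bony"),
    ("or1", "Siluriformes", "order", ("Actinopterygii",), "bony"),
    ("fa1", "Ariidae", "family", ("Actinopterygii", "Siluriformes"), "bony"),
    ("ge1", "Genidens", "genus", ("Actinopterygii", "Siluriformes", "Ariidae"), "bony"),
    ("sp1", "Genidens barbus", "species",
     ("Actinopterygii", "Siluriformes", "Ariidae", "Genidens"), "bony"),
    ("sp2", "Bagre bagre", "species",
     ("Actinopterygii", "Siluriformes", "Ariidae", "Bagre"), "bony"),
    ("sp3", "Micropogonias furnieri", "species",
     ("Actinopterygii", "Perciformes", "Sciaenidae", "Micropogonias"), "bony"),
    ("cl2", "Elasmobranchii", "class", (), "cartilaginous"),
    ("ge2", "Sphyrna", "genus", ("Elasmobranchii", "Carcharhiniformes", "Sphyrnidae"),
     "cartilaginous"),
)


def _assemblage(counts, site="s1", phase="Sambaqui"):
    return AssemblageRecord(site, phase, counts)


class TestAggregate:
    def test_two_areas_sum(self):
        a = _assemblage({"sp1": 10, "sp2": 5})
        b = _assemblage({"sp1": 2})
        assert aggregate_counts([a, b]).counts == {"sp1": 12, "sp2": 5}

    def test_single_record_identity(self):
        a = _assemblage({"sp1": 7})
        assert aggregate_counts([a]).counts == a.counts

    def test_mixed_site_or_phase_rejected(self):
        with pytest.raises(ValueError, match="site/phase"):
            aggregate_counts([_assemblage({"sp1": 1}), _assemblage({"sp1": 1}, site="s2")])

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_partition_oracle(self, k, seed):
        """Summing a random k-way split of an assemblage recovers it."""
        rng = np.random.default_rng(seed)
        counts = {f"t{i}": int(rng.integers(1, 100)) for i in range(8)}
        parts = [dict() for _ in range(k)]
        for t, c in counts.items():
            split = rng.multinomial(c, np.ones(k) / k)
            for j, cj in enumerate(split):
                if cj > 0:
                    parts[j][t] = int(cj)
        records = [_assemblage(p) for p in parts if p]
        assert aggregate_counts(records).counts == counts


class TestRelativeAbundance:
    def test_printed_class_totals_give_printed_shares(self):
        """The two-class summary of the compiled record: bony NISP 876,622 and
        cartilaginous NISP 10,603 are 98.8% and 1.2% of all remains."""
        taxa = make_taxa(
            ("b", "Bony total", "order", ("Actinopterygii",), "bony"),
            ("c", "Cartilaginous total", "order", ("Elasmobranchii",), "cartilaginous"),
        )
        summ = relative_abundance(_assemblage({"b": 876_622, "c": 10_603}), taxa)
        assert summ.percent_display() == {"b": 98.8, "c": 1.2}
        assert summ.total_nisp == 887_225

    def test_class_level_counts_excluded_from_denominator(self):
        summ = relative_abundance(
            _assemblage({"cl1": 50, "sp1": 25, "sp3": 25}), HIER_TAXA
        )
        assert summ.percent_display() == {"sp1": 50.0, "sp3": 50.0}
        assert summ.total_nisp == 100 and summ.identified_nisp == 50
        assert summ.identified_fraction["bony"] == pytest.approx(0.5)

    def test_all_class_rank_yields_empty_percentages(self):
        summ = relative_abundance(_assemblage({"cl1": 10}), HIER_TAXA)
        assert summ.percent == {}
        assert summ.total_nisp == 10

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_percentages(self, seed):
        rng = np.random.default_rng(seed)
        ids = ["cl1", "sp1", "sp2", "sp3", "ge1"]
        counts = {t: int(rng.integers(1, 500)) for t in ids}
        summ = relative_abundance(_assemblage(counts), HIER_TAXA)
        denom = sum(c for t, c in counts.items() if HIER_TAXA[t].rank != "class")
        for t, c in counts.items():
            if HIER_TAXA[t].rank == "class":
                assert t not in summ.percent
            else:
                assert summ.percent[t] == pytest.approx(100.0 * c / denom)
        assert sum(summ.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_aggregate_commutes_with_relative_abundance(self):
        a = _assemblage({"cl1": 10, "sp1": 30, "sp2": 5})
        b = _assemblage({"sp1": 15, "sp3": 40})
        merged = relative_abundance(aggregate_counts([a, b]), HIER_TAXA)
        # summarise-the-aggregate from raw count sums
        total = {"cl1": 10, "sp1": 45, "sp2": 5, "sp3": 40}
        assert merged.nisp == total
        denom = 45 + 5 + 40
        assert merged.percent["sp1"] == pytest.approx(100.0 * 45 / denom)


def _occurrence_dataset(n_sites, occupied, taxon_ids=("sp1",)):
    """n_sites presence-only sites; the given taxa occur at the first
    `occupied` of them."""
    sites = {
        f"s{i}": SiteRecord(f"s{i}", f"Site {i}", -27.0, "C") for i in range(n_sites)
    }
    assemblages = []
    for i in range(n_sites):
        present = frozenset(taxon_ids) if i < occupied else frozenset({"sp3"})
        assemblages.append(
            AssemblageRecord(f"s{i}", "Sambaqui", {}, present_only=present)
        )
    return Dataset(taxa=dict(HIER_TAXA), sites=sites, assemblages=assemblages,
                   traits={}, periods={})


class TestOccurrence:
    def test_37_of_53_sites_rounds_to_70_percent(self):
        ds = _occurrence_dataset(53, 37)
        assert round(occurrence_frequency(ds, "Genidens barbus")) == 70

    def test_family_occurrence_counts_member_genera_and_species(self):
        """Ariidae occurs wherever any ariid does: 49 of 53 sites -> 92%."""
        ds = _occurrence_dataset(53, 49, taxon_ids=("sp1",))
        # make some of the occupied sites record the genus or family instead
        ds.assemblages[0].present_only = frozenset({"ge1"})
        ds.assemblages[1].present_only = frozenset({"fa1"})
        assert round(occurrence_frequency(ds, "Ariidae")) == 92

    def test_absent_taxon_scores_zero(self):
        ds = _occurrence_dataset(10, 0)
        assert occurrence_frequency(ds, "Genidens barbus") == 0.0

    def test_empty_universe_rejected(self):
        ds = _occurrence_dataset(5, 2)
        with pytest.raises(ValueError, match="universe"):
            occurrence_frequency(ds, "Genidens barbus", site_universe=[])


def _mlti_oracle(present_ids, taxa):
    """Independent forest-leaf count: build the full children relation from
    lineages, then count present non-class taxa with no present descendant."""
    present = [taxa[t] for t in present_ids]
    n = 0
    for t in present:
        if t.rank == "class":
            continue
        has_present_descendant = any(
            u.taxon_id != t.taxon_id and t.name in u.lineage for u in present
        )
        if not has_present_descendant:
            n += 1
    return n


class TestMlti:
    def test_nested_lineage_collapses_to_one(self):
        a = _assemblage({"fa1": 5, "ge1": 3, "sp1": 2})
        assert species_richness_mlti(a, HIER_TAXA) == 1

    def test_sibling_branches_both_count(self):
        a = _assemblage({"ge1": 3, "sp2": 2})
        assert species_richness_mlti(a, HIER_TAXA) == 2

    def test_class_rank_never_counts(self):
        assert species_richness_mlti(_assemblage({"cl1": 100}), HIER_TAXA) == 0
        assert species_richness_mlti(_assemblage({"cl1": 100, "sp1": 1}), HIER_TAXA) == 1

    def test_adding_an_ancestor_never_increases_richness(self):
        base = _assemblage({"sp1": 2, "sp3": 4})
        before = species_richness_mlti(base, HIER_TAXA)
        for anc in ("ge1", "fa1", "or1", "cl1"):
            extended = _assemblage({**base.counts, anc: 1})
            assert species_richness_mlti(extended, HIER_TAXA) == before
        # a new leaf on a fresh branch adds exactly one
        extended = _assemblage({**base.counts, "ge2": 1})
        assert species_richness_mlti(extended, HIER_TAXA) == before + 1

    def test_matches_forest_leaf_oracle_on_synthetic_pools(self, pool):
        rng = np.random.default_rng(0)
        ids = sorted(pool.taxa)
        for _ in range(200):
            chosen = rng.choice(ids, size=rng.integers(1, 25), replace=False)
            a = _assemblage({t: int(rng.integers(1, 50)) for t in chosen})
            assert species_richness_mlti(a, pool.taxa) == _mlti_oracle(chosen, pool.taxa)


class TestDensities:
    def test_nisp_density(self):
        site = SiteRecord("s1", "x", -27.0, "A", volume_m3=2.0)
        assert nisp_density(_assemblage({"sp1": 1000}), site) == 500.0

    def test_missing_volume_signals_exclusion(self):
        site = SiteRecord("s1", "x", -27.0, "A", volume_m3=None)
        assert nisp_density(_assemblage({"sp1": 1000}), site) is None

    def test_sr_per_nisp(self):
        a = _assemblage({"sp1": 500, "sp3": 500})
        assert sr_per_nisp(a, HIER_TAXA) == pytest.approx(2 / 1000)


TRAITS3 = {
    "Genidens barbus": TraitRecord("Genidens barbus", 3.0, "invertivore", 120.0, 12000.0),
    "Bagre bagre": TraitRecord("Bagre bagre", 4.0, "piscivore", 55.0, 2800.0),
    "Micropogonias furnieri": TraitRecord(
        "Micropogonias furnieri", 3.6, "invertivore", 60.0, 4600.0),
}


class TestTrophicLevel:
    def test_species_identity(self):
        tlv = taxon_trophic_level(HIER_TAXA["sp3"], TRAITS3, list(TRAITS3))
        assert tlv.value == 3.6 and tlv.provenance == "species"

    def test_genus_mean_of_regional_species(self):
        tlv = taxon_trophic_level(
            HIER_TAXA["fa1"], TRAITS3,
            {"Ariidae": ["Genidens barbus", "Bagre bagre"]},
        )
        assert tlv.value == pytest.approx(3.5)
        assert tlv.provenance == "regional_mean" and tlv.n_species == 2

    def test_lineage_resolved_membership_matches_explicit_list(self):
        via_lineage = taxon_trophic_level(
            HIER_TAXA["fa1"], TRAITS3, list(TRAITS3), taxa=HIER_TAXA
        )
        explicit = taxon_trophic_level(
            HIER_TAXA["fa1"], TRAITS3,
            {"Ariidae": ["Genidens barbus", "Bagre bagre"]},
        )
        assert via_lineage.value == pytest.approx(explicit.value)

    def test_fallback_list_used_when_no_regional_member(self):
        tlv = taxon_trophic_level(
            HIER_TAXA["fa1"], TRAITS3, {"Ariidae": []},
            taxa=HIER_TAXA, fallback_species=["Bagre bagre"],
        )
        assert tlv.value == pytest.approx(4.0)
        assert tlv.provenance == "fallback_mean"

    def test_unresolvable_returns_none(self):
        tlv = taxon_trophic_level(HIER_TAXA["ge2"], TRAITS3, {}, taxa=HIER_TAXA)
        assert tlv is None


class TestWatl:
    def test_single_taxon(self):
        a = _assemblage({"sp2": 9})
        assert watl(a, HIER_TAXA, TRAITS3) == pytest.approx(4.0)

    def test_equal_counts_average(self):
        a = _assemblage({"sp1": 5, "sp2": 5})
        assert watl(a, HIER_TAXA, TRAITS3) == pytest.approx(3.5)

    def test_dot_product_oracle_and_scale_invariance(self):
        a = _assemblage({"sp1": 30, "sp2": 10, "sp3": 60, "cl1": 500})
        w = np.array([30, 10, 60]) / 100
        expected = float(w @ np.array([3.0, 4.0, 3.6]))
        assert watl(a, HIER_TAXA, TRAITS3) == pytest.approx(expected, abs=1e-12)
        scaled = _assemblage({t: c * 7 for t, c in a.counts.items()})
        assert watl(scaled, HIER_TAXA, TRAITS3) == pytest.approx(expected, abs=1e-12)

    def test_presence_weighting(self):
        a = _assemblage({"sp1": 99, "sp2": 1})
        assert watl(a, HIER_TAXA, TRAITS3, weighting="presence") == pytest.approx(3.5)

    def test_bounded_by_min_max_tl(self, pool, sim_dataset):
        dataset, _ = sim_dataset
        tls = [t.trophic_level for t in dataset.traits.values()]
        for a in dataset.assemblages[:6]:
            w = watl(a, dataset.taxa, dataset.traits)
            assert min(tls) <= w <= max(tls)


class TestTrendFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = trend_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        fit = trend_fit(x, y)
        perm = rng.permutation(20)
        fit2 = trend_fit(x[perm], y[perm])
        assert fit2.slope == pytest.approx(fit.slope)
        assert fit2.p == pytest.approx(fit.p)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            trend_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_confidence_band_covers_true_mean_response(self):
        """~95% pointwise coverage of the true regression line at x = 0.5
        over 400 simulated datasets."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.uniform(0, 1, size=30)
            y = 1.0 + 2.0 * x + rng.normal(0, 0.5, size=30)
            lo, hi = trend_fit(x, y).conf_band([0.5])
            hits += lo[0] <= 2.0 <= hi[0]
        assert 0.92 <= hits / n_rep <= 0.98
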