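"""Assemblage-level abundance and richness metrics.

Conventions used throughout:

* Total NISP includes every identified remain regardless of rank (class to
  species), but *relative* abundances exclude remains recorded only at class
  level (Actinopterygii / Elasmobranchii) from both numerator and
  denominator.
* Species richness follows the Minimal Level of Taxonomic Identification
  (MLTI): within one assemblage a record is discarded when it is an ancestor
  of another present record, and class-level records never count.
* Internal arithmetic is full precision; display helpers round percentages
  to one decimal (occurrence frequencies to the nearest integer).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .types import (
    AssemblageRecord,
    Dataset,
    SiteRecord,
    TaxonRecord,
    TraitRecord,
)

log = logging.getLogger(__name__)


@dataclass
class AbundanceSummary:
    """Per-taxon NISP and class-level-excluded relative abundances."""

    nisp: dict[str, int]
    percent: dict[str, float]
    identified_fraction: dict[str, float]
    total_nisp: int
    identified_nisp: int

    def percent_display(self) -> dict[str, float]:
        return {t: round(p, 1) for t, p in self.percent.items()}


def aggregate_counts(records: Sequence[AssemblageRecord]) -> AssemblageRecord:
    """Sum counts over assemblage records of the same site and phase
    (e.g. separately published excavation areas)."""
    if not records:
        raise ValueError("no records to aggregate")
    key = (records[0].site_id, records[0].cultural_phase)
    counts: dict[str, int] = {}
    present: set[str] = set()
    for r in records:
        if (r.site_id, r.cultural_phase) != key:
            raise ValueError(
                f"cannot aggregate across site/phase: {key} vs "
                f"{(r.site_id, r.cultural_phase)}"
            )
        for t, c in r.counts.items():
            counts[t] = counts.get(t, 0) + c
        present |= r.present_only
    return AssemblageRecord(
        site_id=key[0], cultural_phase=key[1], counts=counts,
        present_only=frozenset(present),
    )


def relative_abundance(
    assemblage: AssemblageRecord, taxa: Mapping[str, TaxonRecord]
) -> AbundanceSummary:
    """Relative abundance after removing class-level records.

    Class-rank counts stay in ``total_nisp`` and drive the per-class
    ``identified_fraction`` (share of a class's remains identified beyond
    class level) but are excluded from the percentage denominator.
    """
    if not assemblage.counts:
        raise ValueError("assemblage has no counts")
    class_total = {"bony": 0, "cartilaginous": 0}
    class_identified = {"bony": 0, "cartilaginous": 0}
    included: dict[str, int] = {}
    for tid, c in assemblage.counts.items():
        taxon = taxa[tid]
        class_total[taxon.fish_class] += c
        if taxon.rank == "class":
            continue
        class_identified[taxon.fish_class] += c
        included[tid] = c

    identified_nisp = sum(included.values())
    if identified_nisp == 0:
        log.warning(
            "assemblage %s/%s: all counts at class rank; no relative abundances",
            assemblage.site_id,
            assemblage.cultural_phase,
        )
        percent: dict[str, float] = {}
    else:
        percent = {t: 100.0 * c / identified_nisp for t, c in included.items()}

    identified_fraction = {
        cls: (class_identified[cls] / class_total[cls]) if class_total[cls] else float("nan")
        for cls in class_total
    }
    return AbundanceSummary(
        nisp=dict(assemblage.counts),
        percent=percent,
        identified_fraction=identified_fraction,
        total_nisp=assemblage.total_count,
        identified_nisp=identified_nisp,
    )


def _occurs(assemblage: AssemblageRecord, taxon: TaxonRecord,
            taxa: Mapping[str, TaxonRecord]) -> bool:
    for tid in assemblage.present_taxa:
        t = taxa[tid]
        if t.taxon_id == taxon.taxon_id or taxon.name in t.lineage:
            return True
    return False


def occurrence_frequency(
    dataset: Dataset,
    taxon: TaxonRecord | str,
    site_universe: Iterable[str] | None = None,
) -> float:
    """Percentage of sites where the taxon (or any descendant) occurs.

    Counting is hierarchical: a family "occurs" wherever any member genus or
    species does. The universe defaults to all sites with any fish record
    (sources A, B and C). Full precision is returned; display convention is
    the nearest integer.
    """
    if isinstance(taxon, str):
        rec = dataset.taxa.get(taxon) or dataset.taxon_by_name(taxon)
        if rec is None:
            raise KeyError(f"unknown taxon {taxon!r}")
        taxon = rec
    if site_universe is None:
        site_universe = {a.site_id for a in dataset.assemblages if a.present_taxa}
    universe = set(site_universe)
    if not universe:
        raise ValueError("empty site universe")
    occupied = {
        a.site_id
        for a in dataset.assemblages
        if a.site_id in universe and _occurs(a, taxon, dataset.taxa)
    }
    return 100.0 * len(occupied) / len(universe)


def species_richness_mlti(
    assemblage: AssemblageRecord, taxa: Mapping[str, TaxonRecord]
) -> int:
    """Richness under the Minimal Level of Taxonomic Identification.

    Equivalent to counting the leaves of the presence forest induced by the
    recorded taxa: any record that is an ancestor of another present record
    is subsumed; class-level records never count.
    """
    present = [taxa[tid] for tid in assemblage.present_taxa]
    names_below = set()
    for t in present:
        names_below.update(t.lineage)
    n = 0
    for t in present:
        if t.rank == "class":
            continue
        if t.name in names_below:
            continue
        n += 1
    return n


def nisp_density(assemblage: AssemblageRecord, site: SiteRecord) -> float | None:
    """NISP per m^3 of excavated sediment; None (logged) when the site lacks
    a usable volume, signalling exclusion from density analyses."""
    if site.volume_m3 is None or site.volume_m3 <= 0:
        log.warning("site %s: no excavated volume; excluded from NISP/m^3", site.site_id)
        return None
    return assemblage.total_count / site.volume_m3


def sr_per_nisp(assemblage: AssemblageRecord, taxa: Mapping[str, TaxonRecord]) -> float:
    """MLTI richness normalised by the contextual total NISP."""
    total = assemblage.total_count
    if total <= 0:
        raise ValueError("total NISP must be positive")
    return species_richness_mlti(assemblage, taxa) / total


@dataclass(frozen=True)
class TrophicLevelValue:
    value: float
    provenance: str  # "species" | "regional_mean" | "fallback_mean"
    n_species: int


def taxon_trophic_level(
    taxon: TaxonRecord,
    traits: Mapping[str, TraitRecord],
    regional_species: Iterable[str] | Mapping[str, Iterable[str]],
    taxa: Mapping[str, TaxonRecord] | None = None,
    fallback_species: Iterable[str] = (),
) -> TrophicLevelValue | None:
    """Trophic level of a taxon at any sub-class rank.

    Species take their trait-table value directly. Order/family/genus records
    take the mean TL of regional archaeological species within the taxon;
    if none exist, the mean over a configured fallback species list (e.g. a
    regional biodiversity checklist). ``regional_species`` is either a flat
    species list (membership resolved through the ``taxa`` lineages) or a
    ready-made mapping of taxon name -> member species. Returns None
    (logged) when no TL is resolvable, which excludes the taxon from WATL.
    """
    if taxon.rank == "class":
        raise ValueError("trophic level is not attributed at class rank")
    if taxon.rank == "species":
        rec = traits.get(taxon.name)
        if rec is None:
            log.warning("no trait record for species %s; excluded", taxon.name)
            return None
        return TrophicLevelValue(rec.trophic_level, "species", 1)

    species_by_name: dict[str, TaxonRecord] = {}
    if taxa is not None:
        species_by_name = {
            t.name: t for t in taxa.values() if t.rank == "species"
        }

    def members(candidates: Iterable[str] | Mapping[str, Iterable[str]]) -> list[float]:
        if isinstance(candidates, Mapping):
            pool = candidates.get(taxon.name, [])
            return [traits[sp].trophic_level for sp in pool if sp in traits]
        vals = []
        for sp in candidates:
            rec = traits.get(sp)
            if rec is None:
                continue
            sp_taxon = species_by_name.get(sp)
            if sp_taxon is None or taxon.name not in sp_taxon.lineage:
                continue
            vals.append(rec.trophic_level)
        return vals

    vals = members(regional_species)
    if vals:
        return TrophicLevelValue(float(np.mean(vals)), "regional_mean", len(vals))
    vals = members(fallback_species)
    if vals:
        return TrophicLevelValue(float(np.mean(vals)), "fallback_mean", len(vals))
    log.warning("no trophic level resolvable for %s; excluded from WATL", taxon.name)
    return None


def watl(
    assemblage: AssemblageRecord,
    taxa: Mapping[str, TaxonRecord],
    traits: Mapping[str, TraitRecord],
    regional_species: Iterable[str] | None = None,
    fallback_species: Iterable[str] = (),
    weighting: str = "nisp",
) -> float:
    """Weighted Average Trophic Level of an assemblage.

    Weights are class-level-excluded relative abundances renormalised over
    the TL-resolvable taxa (``weighting="nisp"``, default) or equal weights
    over those taxa (``weighting="presence"``).
    """
    if weighting not in {"nisp", "presence"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    if regional_species is None:
        regional_species = list(traits)
    regional_species = list(regional_species)
    weights: list[float] = []
    tls: list[float] = []
    for tid, c in assemblage.counts.items():
        taxon = taxa[tid]
        if taxon.rank == "class" or c <= 0:
            continue
        tlv = taxon_trophic_level(taxon, traits, regional_species, taxa, fallback_species)
        if tlv is None:
            continue
        weights.append(float(c) if weighting == "nisp" else 1.0)
        tls.append(tlv.value)
    if not weights:
        raise ValueError("no taxon with resolvable trophic level")
    w = np.asarray(weights) / np.sum(weights)
    return float(np.dot(w, tls))


@dataclass
class TrendFit:
    """Ordinary least-squares fit of a metric against latitude or age."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int
    _results: object = field(repr=False, default=None)

    def conf_band(self, x_new: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% confidence band for the mean response at x_new."""
        X = sm.add_constant(np.asarray(x_new, dtype=float), has_constant="add")
        pred = self._results.get_prediction(X)
        ci = pred.conf_int(alpha=0.05)
        return ci[:, 0], ci[:, 1]


def trend_fit(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS trend with 95% confidence band, Pearson r and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: trend is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    r = float(np.corrcoef(x, y)[0, 1])
    return TrendFit(
        slope=slope,
        intercept=float(res.params[0]),
        r=r,
        p=float(res.pvalues[1]),
        n=int(x.size),
        _results=res,
    )
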