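"""Domain records for zooarchaeological fish-assemblage analysis.

The vocabulary follows standard zooarchaeological usage: counts are NISP
(Number of Identified Specimens) or, for a few sites, MNI (Minimum Number
of Individuals); taxa are recorded at whatever rank the skeletal material
allowed (class down to species); fish fall into two classes, bony
(Actinopterygii) and cartilaginous (Elasmobranchii).
"""
from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("class", "order", "family", "genus", "species")
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

FISH_CLASSES = ("bony", "cartilaginous")
#: scientific class names and the fish_class attribute they imply
CLASS_NAMES = {"Actinopterygii": "bony", "Elasmobranchii": "cartilaginous"}

TROPHIC_GROUPS = (
    "invertivore",
    "herbivore",
    "macrocarnivore",
    "omnivore",
    "piscivore",
    "planktivore",
)

SOURCE_CATEGORIES = ("A", "B", "C")
QUANTIFICATION_BASES = ("NISP", "MNI")

#: trophic levels of the fishes considered span this closed interval
TROPHIC_LEVEL_RANGE = (2.0, 4.9)

#: default study periods: two pre-European cultural phases and modern catches
PERIOD_LABELS = {
    "P1": "4500-1150 cal BP",
    "P2": "1050-600 cal BP",
    "P3": "AD 1994-2015",
}


@dataclass(frozen=True)
class TaxonRecord:
    """A named taxon at a given rank with its (possibly gappy) lineage.

    ``lineage`` lists ancestor names ordered class -> species, excluding the
    taxon itself; missing intermediate levels are simply absent.
    """

    taxon_id: str
    name: str
    rank: str
    lineage: tuple[str, ...]
    fish_class: str


@dataclass(frozen=True)
class SiteRecord:
    """An archaeological site and its recovery metadata.

    Latitude is signed decimal degrees (southern hemisphere negative).
    ``source_category`` grades the underlying report: A quantitative for all
    taxa, B quantitative for selected taxa, C presence-only.
    """

    site_id: str
    name: str
    latitude: float
    source_category: str
    mesh_mm: float | None = None
    volume_m3: float | None = None
    median_age_cal_bp: float | None = None
    quantification_basis: str = "NISP"


@dataclass
class AssemblageRecord:
    """Per-site, per-cultural-phase taxon counts.

    ``counts`` maps taxon_id to NISP (or MNI where the site's basis is MNI).
    ``present_only`` holds taxa reported without counts; only qualitative
    (source C) records may use it.
    """

    site_id: str
    cultural_phase: str
    counts: dict[str, int] = field(default_factory=dict)
    present_only: frozenset[str] = frozenset()

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def present_taxa(self) -> frozenset[str]:
        return frozenset(t for t, c in self.counts.items() if c > 0) | self.present_only


@dataclass(frozen=True)
class TraitRecord:
    """Functional traits of one species: trophic level (dimensionless,
    FishBase convention, within [2.0, 4.9] here), feeding guild, and maximum
    body size (cm) / mass (g)."""

    species: str
    trophic_level: float
    trophic_group: str
    max_body_size_cm: float
    max_body_mass_g: float


@dataclass(frozen=True)
class PeriodCatch:
    """The set of species documented as fisheries targets in one period."""

    period_id: str
    species: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(
                self, "label", PERIOD_LABELS.get(self.period_id, self.period_id)
            )


@dataclass(frozen=True)
class Violation:
    """One invariant breach found by validation; data, not an exception."""

    record_type: str
    record_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record_type}[{self.record_id}]: {self.message}"


@dataclass
class Dataset:
    """The in-memory join of the five input tables."""

    taxa: dict[str, TaxonRecord]
    sites: dict[str, SiteRecord]
    assemblages: list[AssemblageRecord]
    traits: dict[str, TraitRecord]
    periods: dict[str, PeriodCatch]

    def taxon_by_name(self, name: str) -> TaxonRecord | None:
        for t in self.taxa.values():
            if t.name == name:
                return t
        return None

    def assemblages_of(self, site_id: str) -> list[AssemblageRecord]:
        return [a for a in self.assemblages if a.site_id == site_id]
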