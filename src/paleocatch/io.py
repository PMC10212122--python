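"""Read, validate and write the CSV tables the pipeline consumes.

Dialect: UTF-8, comma-separated, mandatory header row, "." decimal
separator, empty cell = missing. Lineages are ";"-joined ancestor names.
All writers sort rows so that a write -> read round trip is deterministic.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    CLASS_NAMES,
    FISH_CLASSES,
    QUANTIFICATION_BASES,
    RANK_DEPTH,
    RANKS,
    SOURCE_CATEGORIES,
    TROPHIC_GROUPS,
    TROPHIC_LEVEL_RANGE,
    AssemblageRecord,
    Dataset,
    PeriodCatch,
    SiteRecord,
    TaxonRecord,
    TraitRecord,
    Violation,
)

log = logging.getLogger(__name__)


class DataError(Exception):
    """Base class for input-table problems."""


class SchemaError(DataError):
    """A table is missing a required column."""


class ParseError(DataError):
    """A cell could not be parsed; the message carries the file row number."""


class IntegrityError(DataError):
    """Cross-table references do not resolve."""


TAXA_COLUMNS = ["taxon_id", "name", "rank", "lineage", "fish_class"]
SITES_COLUMNS = [
    "site_id",
    "name",
    "latitude",
    "source_category",
    "mesh_mm",
    "volume_m3",
    "median_age_cal_bp",
    "quantification_basis",
]
COUNTS_COLUMNS = ["site_id", "cultural_phase", "taxon_id", "count"]
TRAITS_COLUMNS = [
    "species",
    "trophic_level",
    "trophic_group",
    "max_body_size_cm",
    "max_body_mass_g",
]
PERIODS_COLUMNS = ["period_id", "species", "present"]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {', '.join(missing)}")


def _read_csv(path: str | Path, columns: list[str], table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, columns, table)
    return df


def _opt_float(cell: str, table: str, row: int, column: str) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"{table} row {row}: non-numeric {column} value {cell!r}"
        ) from None


def read_dataset(
    taxa_csv: str | Path,
    sites_csv: str | Path,
    counts_csv: str | Path,
    traits_csv: str | Path,
    periods_csv: str | Path,
) -> Dataset:
    """Load the five tables into a referentially consistent :class:`Dataset`.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError` for
    unparseable cells (with the file row number), and :class:`IntegrityError`
    when count rows reference unknown sites/taxa or a period lists a species
    absent from the trait table.
    """
    taxa_df = _read_csv(taxa_csv, TAXA_COLUMNS, "taxa")
    sites_df = _read_csv(sites_csv, SITES_COLUMNS, "sites")
    counts_df = _read_csv(counts_csv, COUNTS_COLUMNS, "counts")
    traits_df = _read_csv(traits_csv, TRAITS_COLUMNS, "traits")
    periods_df = _read_csv(periods_csv, PERIODS_COLUMNS, "periods")

    taxa: dict[str, TaxonRecord] = {}
    for i, row in taxa_df.iterrows():
        lineage = tuple(s.strip() for s in row["lineage"].split(";") if s.strip())
        taxa[row["taxon_id"]] = TaxonRecord(
            taxon_id=row["taxon_id"],
            name=row["name"],
            rank=row["rank"],
            lineage=lineage,
            fish_class=row["fish_class"],
        )

    sites: dict[str, SiteRecord] = {}
    for i, row in sites_df.iterrows():
        n = int(i) + 2  # header is row 1
        sites[row["site_id"]] = SiteRecord(
            site_id=row["site_id"],
            name=row["name"],
            latitude=_opt_float(row["latitude"], "sites", n, "latitude") or 0.0,
            source_category=row["source_category"],
            mesh_mm=_opt_float(row["mesh_mm"], "sites", n, "mesh_mm"),
            volume_m3=_opt_float(row["volume_m3"], "sites", n, "volume_m3"),
            median_age_cal_bp=_opt_float(
                row["median_age_cal_bp"], "sites", n, "median_age_cal_bp"
            ),
            quantification_basis=row["quantification_basis"] or "NISP",
        )

    grouped: dict[tuple[str, str], dict[str, int]] = {}
    presence: dict[tuple[str, str], set[str]] = {}
    bad_sites: list[str] = []
    bad_taxa: list[str] = []
    for i, row in counts_df.iterrows():
        n = int(i) + 2
        key = (row["site_id"], row["cultural_phase"])
        if row["site_id"] not in sites:
            bad_sites.append(row["site_id"])
            continue
        if row["taxon_id"] not in taxa:
            bad_taxa.append(row["taxon_id"])
            continue
        cell = row["count"]
        if cell == "":
            presence.setdefault(key, set()).add(row["taxon_id"])
            continue
        try:
            count = int(float(cell)) if float(cell) == int(float(cell)) else None
        except ValueError:
            count = None
        if count is None:
            raise ParseError(f"counts row {n}: non-numeric count value {cell!r}")
        grouped.setdefault(key, {})
        grouped[key][row["taxon_id"]] = grouped[key].get(row["taxon_id"], 0) + count
    if bad_sites or bad_taxa:
        parts = []
        if bad_sites:
            parts.append(f"unknown site_id(s): {sorted(set(bad_sites))}")
        if bad_taxa:
            parts.append(f"unknown taxon_id(s): {sorted(set(bad_taxa))}")
        raise IntegrityError("counts: " + "; ".join(parts))

    keys = sorted(set(grouped) | set(presence))
    assemblages = [
        AssemblageRecord(
            site_id=s,
            cultural_phase=p,
            counts=grouped.get((s, p), {}),
            present_only=frozenset(presence.get((s, p), set())),
        )
        for s, p in keys
    ]

    traits: dict[str, TraitRecord] = {}
    for i, row in traits_df.iterrows():
        n = int(i) + 2
        traits[row["species"]] = TraitRecord(
            species=row["species"],
            trophic_level=_opt_float(row["trophic_level"], "traits", n, "trophic_level"),
            trophic_group=row["trophic_group"],
            max_body_size_cm=_opt_float(
                row["max_body_size_cm"], "traits", n, "max_body_size_cm"
            ),
            max_body_mass_g=_opt_float(
                row["max_body_mass_g"], "traits", n, "max_body_mass_g"
            ),
        )

    periods: dict[str, PeriodCatch] = {}
    per_species: dict[str, set[str]] = {}
    for i, row in periods_df.iterrows():
        if str(row["present"]).strip() in {"1", "1.0", "true", "True", "x", "X"}:
            per_species.setdefault(row["period_id"], set()).add(row["species"])
        else:
            per_species.setdefault(row["period_id"], set())
    missing_traits = sorted(
        {s for sp in per_species.values() for s in sp if s not in traits}
    )
    if missing_traits:
        raise IntegrityError(
            f"periods: species absent from trait table: {missing_traits}"
        )
    for pid in sorted(per_species):
        periods[pid] = PeriodCatch(period_id=pid, species=frozenset(per_species[pid]))

    ds = Dataset(
        taxa=taxa, sites=sites, assemblages=assemblages, traits=traits, periods=periods
    )
    log.info(
        "read_dataset: %d taxa, %d sites, %d assemblages, %d trait rows, %d periods",
        len(taxa),
        len(sites),
        len(assemblages),
        len(traits),
        len(periods),
    )
    return ds


def read_period_presence(path: str | Path) -> dict[str, set[str]]:
    """Shim for wide presence/absence layouts (one species column followed by
    one 0/1 column per period), as distributed with published supplements.

    The species column is taken to be the first column whose header is not a
    recognisable period label; remaining columns become period ids. Truthy
    cells are {1, x, p, present, yes, true} case-insensitively.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError("period presence table needs >= 2 columns")
    species_col = df.columns[0]
    truthy = {"1", "1.0", "x", "p", "present", "yes", "true"}
    out: dict[str, set[str]] = {}
    for col in df.columns[1:]:
        out[str(col)] = {
            str(sp).strip()
            for sp, v in zip(df[species_col], df[col])
            if str(v).strip().lower() in truthy
        }
    return out


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the five tables under ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def fmt(v: float | None) -> str:
        return "" if v is None else repr(float(v))

    taxa_rows = [
        {
            "taxon_id": t.taxon_id,
            "name": t.name,
            "rank": t.rank,
            "lineage": ";".join(t.lineage),
            "fish_class": t.fish_class,
        }
        for t in sorted(dataset.taxa.values(), key=lambda t: t.taxon_id)
    ]
    sites_rows = [
        {
            "site_id": s.site_id,
            "name": s.name,
            "latitude": fmt(s.latitude),
            "source_category": s.source_category,
            "mesh_mm": fmt(s.mesh_mm),
            "volume_m3": fmt(s.volume_m3),
            "median_age_cal_bp": fmt(s.median_age_cal_bp),
            "quantification_basis": s.quantification_basis,
        }
        for s in sorted(dataset.sites.values(), key=lambda s: s.site_id)
    ]
    counts_rows = []
    for a in sorted(dataset.assemblages, key=lambda a: (a.site_id, a.cultural_phase)):
        for tid in sorted(a.counts):
            counts_rows.append(
                {
                    "site_id": a.site_id,
                    "cultural_phase": a.cultural_phase,
                    "taxon_id": tid,
                    "count": str(a.counts[tid]),
                }
            )
        for tid in sorted(a.present_only):
            counts_rows.append(
                {
                    "site_id": a.site_id,
                    "cultural_phase": a.cultural_phase,
                    "taxon_id": tid,
                    "count": "",
                }
            )
    traits_rows = [
        {
            "species": t.species,
            "trophic_level": fmt(t.trophic_level),
            "trophic_group": t.trophic_group,
            "max_body_size_cm": fmt(t.max_body_size_cm),
            "max_body_mass_g": fmt(t.max_body_mass_g),
        }
        for t in sorted(dataset.traits.values(), key=lambda t: t.species)
    ]
    periods_rows = [
        {"period_id": pid, "species": sp, "present": "1"}
        for pid in sorted(dataset.periods)
        for sp in sorted(dataset.periods[pid].species)
    ]

    paths = {}
    for name, rows, cols in [
        ("taxa", taxa_rows, TAXA_COLUMNS),
        ("sites", sites_rows, SITES_COLUMNS),
        ("counts", counts_rows, COUNTS_COLUMNS),
        ("traits", traits_rows, TRAITS_COLUMNS),
        ("periods", periods_rows, PERIODS_COLUMNS),
    ]:
        p = out / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(p, index=False)
        paths[name] = p
    return paths


def validate_dataset(dataset: Dataset) -> list[Violation]:
    """Check every record invariant; returns violations (empty iff clean).

    Deterministic and order-independent over rows: violations are collected
    per record and sorted by (record_type, record_id, message).
    """
    v: list[Violation] = []

    for t in dataset.taxa.values():
        if t.rank not in RANKS:
            v.append(Violation("taxon", t.taxon_id, f"unknown rank {t.rank!r}"))
            continue
        if t.fish_class not in FISH_CLASSES:
            v.append(
                Violation("taxon", t.taxon_id, f"unknown fish_class {t.fish_class!r}")
            )
        if len(t.lineage) > RANK_DEPTH[t.rank]:
            v.append(
                Violation(
                    "taxon",
                    t.taxon_id,
                    f"lineage depth {len(t.lineage)} inconsistent with rank {t.rank}",
                )
            )
        if t.lineage and t.lineage[0] in CLASS_NAMES:
            if CLASS_NAMES[t.lineage[0]] != t.fish_class:
                v.append(
                    Violation(
                        "taxon",
                        t.taxon_id,
                        f"fish_class {t.fish_class!r} contradicts lineage class "
                        f"{t.lineage[0]!r}",
                    )
                )

    for s in dataset.sites.values():
        if s.source_category not in SOURCE_CATEGORIES:
            v.append(
                Violation("site", s.site_id, f"unknown source_category {s.source_category!r}")
            )
        if s.quantification_basis not in QUANTIFICATION_BASES:
            v.append(
                Violation(
                    "site",
                    s.site_id,
                    f"unknown quantification_basis {s.quantification_basis!r}",
                )
            )
        if s.mesh_mm is not None and s.mesh_mm <= 0:
            v.append(Violation("site", s.site_id, f"mesh_mm must be > 0, got {s.mesh_mm}"))
        if s.volume_m3 is not None and s.volume_m3 <= 0:
            v.append(
                Violation("site", s.site_id, f"volume_m3 must be > 0, got {s.volume_m3}")
            )
        if s.median_age_cal_bp is not None and s.median_age_cal_bp < 0:
            v.append(
                Violation(
                    "site",
                    s.site_id,
                    f"median_age_cal_bp must be >= 0, got {s.median_age_cal_bp}",
                )
            )
        if not -90.0 <= s.latitude <= 90.0:
            v.append(Violation("site", s.site_id, f"latitude out of range: {s.latitude}"))

    for a in dataset.assemblages:
        rid = f"{a.site_id}/{a.cultural_phase}"
        site = dataset.sites.get(a.site_id)
        if site is None:
            v.append(Violation("assemblage", rid, "unknown site_id"))
        for tid, c in a.counts.items():
            if tid not in dataset.taxa:
                v.append(Violation("assemblage", rid, f"unresolved taxon_id {tid!r}"))
            if c < 0:
                v.append(Violation("assemblage", rid, f"negative count for {tid!r}"))
        for tid in a.present_only:
            if tid not in dataset.taxa:
                v.append(Violation("assemblage", rid, f"unresolved taxon_id {tid!r}"))
        if site is not None:
            if site.source_category == "C" and a.total_count > 0:
                v.append(
                    Violation(
                        "assemblage",
                        rid,
                        "source C sites are qualitative and carry no counts",
                    )
                )
            if site.source_category != "C" and a.total_count == 0 and not a.present_only:
                v.append(Violation("assemblage", rid, "no positive count"))

    lo, hi = TROPHIC_LEVEL_RANGE
    for t in dataset.traits.values():
        if t.trophic_level is None or not lo <= t.trophic_level <= hi:
            v.append(
                Violation(
                    "trait",
                    t.species,
                    f"trophic_level {t.trophic_level} outside [{lo}, {hi}]",
                )
            )
        if t.trophic_group not in TROPHIC_GROUPS:
            v.append(
                Violation("trait", t.species, f"unknown trophic_group {t.trophic_group!r}")
            )
        for attr in ("max_body_size_cm", "max_body_mass_g"):
            val = getattr(t, attr)
            if val is None or not (val > 0) or math.isinf(val):
                v.append(Violation("trait", t.species, f"{attr} must be positive, got {val}"))

    for p in dataset.periods.values():
        for sp in p.species:
            if sp not in dataset.traits:
                v.append(
                    Violation("period", p.period_id, f"species {sp!r} not in trait table")
                )

    return sorted(v, key=lambda x: (x.record_type, x.record_id, x.message))
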