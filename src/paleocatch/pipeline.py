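"""Orchestrate validate -> (simulate | load) -> abundance -> recovery ->
traits into one reproducible run with a self-describing manifest."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .abundance import (
    nisp_density,
    relative_abundance,
    species_richness_mlti,
    sr_per_nisp,
    watl,
)
from .io import read_dataset, validate_dataset, write_dataset
from .nullmodel import (
    DEFAULT_REPS,
    DEFAULT_SEED,
    TRAITS,
    across_period_anova,
    build_total_pool,
    min_trophic_level,
    proportion_by_category,
    run_trait_null_model,
)
from .recovery import anova_tukey, endmember_sensitivity, mesh_class, pearson_sr_nisp
from .synthetic import GeneratorConfig, simulate_dataset
from .types import Dataset

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """One reproducible run: either a data directory with the five input
    CSVs, or a simulation config; plus analysis settings."""

    data_dir: str | None = None
    simulate: GeneratorConfig | None = None
    reps: int = Field(DEFAULT_REPS, ge=1)
    seed: int = DEFAULT_SEED
    null_mode: str = "welch"
    out_dir: str = "paleocatch_out"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.data_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of data_dir / simulate must be given")
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load(config: RunConfig) -> Dataset:
    if config.simulate is not None:
        dataset, _ = simulate_dataset(config.simulate)
        return dataset
    d = Path(config.data_dir)
    return read_dataset(
        d / "taxa.csv", d / "sites.csv", d / "counts.csv", d / "traits.csv",
        d / "periods.csv",
    )


def abundance_tables(dataset: Dataset) -> dict[str, pd.DataFrame]:
    """Per-assemblage summary, per-taxon relative abundances and hierarchical
    occurrence frequencies."""
    summary_rows = []
    abundance_rows = []
    for a in sorted(dataset.assemblages, key=lambda a: (a.site_id, a.cultural_phase)):
        site = dataset.sites[a.site_id]
        if not a.counts:
            continue
        summ = relative_abundance(a, dataset.taxa)
        sr = species_richness_mlti(a, dataset.taxa)
        dens = nisp_density(a, site)
        try:
            w = watl(a, dataset.taxa, dataset.traits)
        except ValueError:
            w = float("nan")
        summary_rows.append(
            {
                "site_id": a.site_id,
                "cultural_phase": a.cultural_phase,
                "latitude": site.latitude,
                "median_age_cal_bp": site.median_age_cal_bp,
                "mesh_mm": site.mesh_mm,
                "total_nisp": summ.total_nisp,
                "identified_nisp": summ.identified_nisp,
                "identified_fraction_bony": summ.identified_fraction["bony"],
                "identified_fraction_cartilaginous": summ.identified_fraction[
                    "cartilaginous"
                ],
                "sr_mlti": sr,
                "nisp_per_m3": dens,
                "sr_per_nisp": sr_per_nisp(a, dataset.taxa),
                "watl": w,
            }
        )
        for tid, pct in sorted(summ.percent.items()):
            abundance_rows.append(
                {
                    "site_id": a.site_id,
                    "cultural_phase": a.cultural_phase,
                    "taxon_id": tid,
                    "taxon": dataset.taxa[tid].name,
                    "nisp": summ.nisp[tid],
                    "percent": round(pct, 1),
                }
            )
    occurrence_rows = []
    universe = {a.site_id for a in dataset.assemblages if a.present_taxa}
    if universe:
        from .abundance import occurrence_frequency

        for tid in sorted(dataset.taxa):
            t = dataset.taxa[tid]
            freq = occurrence_frequency(dataset, t, universe)
            if freq > 0:
                occurrence_rows.append(
                    {
                        "taxon_id": tid,
                        "taxon": t.name,
                        "rank": t.rank,
                        "occurrence_pct": round(freq),
                        "n_sites": round(freq * len(universe) / 100.0),
                    }
                )
    return {
        "assemblage_summary": pd.DataFrame(summary_rows),
        "relative_abundance": pd.DataFrame(abundance_rows),
        "occurrence": pd.DataFrame(occurrence_rows),
    }


def recovery_tables(dataset: Dataset, summary: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mesh-class ANOVA/Tukey for NISP/m^3 and SR/NISP, and the SR ~ NISP/m^3
    correlation with endmember sensitivity."""
    df = summary.dropna(subset=["mesh_mm", "nisp_per_m3"]).copy()
    df["mesh_class"] = [mesh_class(m) for m in df["mesh_mm"]]
    anova_rows = []
    for metric in ("nisp_per_m3", "sr_per_nisp"):
        groups = {
            mc: sub[metric].to_numpy()
            for mc, sub in df.groupby("mesh_class")
            if len(sub) >= 2
        }
        if len(groups) < 2:
            log.warning("recovery: fewer than 2 usable mesh classes for %s", metric)
            continue
        res = anova_tukey(groups)
        for (a, b), pair in sorted(res.pairwise.items()):
            anova_rows.append(
                {
                    "metric": metric,
                    "group_a": a,
                    "group_b": b,
                    "anova_f": round(res.f, 4),
                    "anova_p": round(res.p, 4),
                    "mean_diff": pair.mean_diff,
                    "tukey_p": round(pair.p_adj, 4),
                }
            )
    corr_rows = []
    pts = list(zip(df["sr_mlti"], df["nisp_per_m3"]))
    if len(pts) >= 4:
        res = pearson_sr_nisp(pts)
        corr_rows.append(
            {"subset": "all", "r": round(res.r, 4), "p": round(res.p, 4), "n": res.n}
        )
        sens = endmember_sensitivity(pts)
        corr_rows.append(
            {
                "subset": "without_endmember",
                "r": round(sens.without_point.r, 4),
                "p": round(sens.without_point.p, 4),
                "n": sens.without_point.n,
            }
        )
    return {
        "mesh_anova_tukey": pd.DataFrame(anova_rows),
        "sr_nisp_correlation": pd.DataFrame(corr_rows),
    }


def trait_tables(dataset: Dataset, reps: int, seed: int, mode: str) -> dict[str, pd.DataFrame]:
    """Null-model summaries, across-period ANOVA/Tukey, category proportions
    and per-period minimum trophic level."""
    pool = build_total_pool(
        dataset.periods.values(), dataset.traits.keys(), dataset.traits
    )
    results = run_trait_null_model(
        pool, dataset.periods, dataset.traits, reps=reps, seed=seed, mode=mode
    )
    null_rows = [
        {
            "trait": r.trait,
            "period_id": r.period_id,
            "n_species": r.observed.size,
            "observed_mean": r.observed_mean,
            "null_mean": r.null_mean,
            "p": r.p,
            "reps": r.reps,
            "seed": r.seed,
            "mode": r.mode,
        }
        for r in results
    ]
    anova_rows = []
    for trait, (extractor, logt) in TRAITS.items():
        values = {
            pid: [extractor(dataset.traits[s]) for s in sorted(c.species)]
            for pid, c in dataset.periods.items()
            if len(c.species) >= 2
        }
        if len(values) < 2:
            continue
        res = across_period_anova(values, log_transform=logt)
        for (a, b), pair in sorted(res.pairwise.items()):
            anova_rows.append(
                {
                    "trait": trait,
                    "period_a": a,
                    "period_b": b,
                    "anova_p": round(res.p, 4),
                    "tukey_p": round(pair.p_adj, 4),
                }
            )
    prop_rows = []
    for pid in sorted(dataset.periods):
        for classifier in ("size_class", "trophic_group", "functional_entity"):
            props = proportion_by_category(
                dataset.periods[pid], dataset.traits, classifier
            )
            for label, (count, pct) in props.items():
                prop_rows.append(
                    {
                        "period_id": pid,
                        "classifier": classifier,
                        "category": label,
                        "n_species": count,
                        "percent": round(pct, 1),
                    }
                )
    mintl_rows = [
        {
            "period_id": pid,
            "min_tl": round(min_trophic_level(dataset.periods[pid], dataset.traits), 1),
        }
        for pid in sorted(dataset.periods)
    ]
    return {
        "trait_null_model": pd.DataFrame(null_rows),
        "trait_anova_tukey": pd.DataFrame(anova_rows),
        "trait_proportions": pd.DataFrame(prop_rows),
        "min_trophic_level": pd.DataFrame(mintl_rows),
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write CSV tables plus a JSON manifest.

    The manifest records the full config, its hash, the seed, the package
    version and a checksum per output table, so a run is self-describing
    and replay differences are detectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        dataset = _load(config)
        stage = "validate"
        violations = validate_dataset(dataset)
        if violations:
            ids = [f"{v.record_type}[{v.record_id}]" for v in violations[:20]]
            raise ValueError(f"validation failed for {len(violations)} record(s): {ids}")
        if config.simulate is not None:
            write_dataset(dataset, out / "data")
        stage = "abundance"
        tables = abundance_tables(dataset)
        stage = "recovery"
        tables.update(recovery_tables(dataset, tables["assemblage_summary"]))
        stage = "traits"
        tables.update(
            trait_tables(dataset, reps=config.reps, seed=config.seed, mode=config.null_mode)
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    checksums: dict[str, str] = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        checksums[f"{name}.csv"] = _sha256(p)

    config_dump = json.loads(config.model_dump_json())
    # hash identifies the analysis, not the output location
    hashed = {k: v for k, v in config_dump.items() if k != "out_dir"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "reps": config.reps,
        "config": config_dump,
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "tables": checksums,
        "counts": {
            "taxa": len(dataset.taxa),
            "sites": len(dataset.sites),
            "assemblages": len(dataset.assemblages),
            "trait_rows": len(dataset.traits),
            "periods": len(dataset.periods),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d tables under %s", len(tables), out)
    return manifest
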