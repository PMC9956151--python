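"""End-to-end orchestration: cohort manifest in, analysis artifacts out.

A run consumes a manifest (TSV: species, group, the three fraction FASTA
paths, optionally assembly_level and seed) and writes, per species, the
"large JSON" (per-sequence composition, one file per fraction) and a
"summary JSON" (per-fraction roll-up), then cohort-level products: the
group-summary table with Delta statistics, a long-format delta table for
charting, the curated min/max GC bounds table, and the unit-cube
visualization bundle. A species whose inputs are missing or malformed is
skipped with a logged reason; the run continues. Processing is streaming
and per-file: no whole-genome sequence set is held in memory at once.

All JSON is written with sorted keys and all tables with fixed column
order, so re-running on identical inputs reproduces the outputs bitwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import schemas
from .composition import FractionBatch, read_fraction
from .cube import export_bundle, normalize_to_cube
from .curation import (SpeciesRecord, assemble_minmax_table, curate_congeners,
                       detect_gc_gap)
from .profiles import SpeciesProfile, build_species_profile, group_table, summarize_groups

logger = logging.getLogger("gclandscape")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "write_large_json",
    "write_summary_json",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Run settings; CLI flags override values loaded from YAML."""

    manifest: Path
    out_dir: Path
    fractions: tuple[str, ...] = ("DNA", "cDNA", "cds")
    whisker: float = 1.5
    max_per_genus: int = 1
    min_gap: float = 2.0
    cube_mode: str = "fixed_0_100"
    tree: Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw["manifest"] = Path(raw["manifest"])
        raw["out_dir"] = Path(raw["out_dir"])
        if raw.get("tree"):
            raw["tree"] = Path(raw["tree"])
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)


@dataclass
class RunReport:
    """Per-species status plus the artifact index of one run."""

    processed: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        doc = {
            "processed": sorted(self.processed),
            "skipped": [{"species": s, "reason": r} for s, r in
                        sorted(self.skipped)],
            "outputs": dict(sorted(self.outputs.items())),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _dump_json(doc: dict, path: Path) -> None:
    # canonical form: sorted keys, fixed indent -> bitwise-stable re-writes
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_large_json(batch: FractionBatch, path: str | Path) -> dict:
    """Per-sequence composition array for one species × fraction."""
    doc = {
        "species": batch.species,
        "fraction": batch.fraction,
        "sequences": [
            {
                "id": s.seq_id, "length": s.length_total,
                "a": s.count_a, "c": s.count_c, "g": s.count_g, "t": s.count_t,
                "n": s.count_n, "other": s.count_other_ambiguous,
                "gc_percent": s.gc_percent, "at_percent": s.at_percent,
            }
            for s in batch.sequences
        ],
    }
    schemas.validate(doc, schemas.LARGE_JSON_SCHEMA)
    _dump_json(doc, Path(path))
    return doc


def write_summary_json(
    species: str, group: str, batches: dict[str, FractionBatch], path: str | Path
) -> dict:
    """Per-species roll-up: n_seqs/length/GC%/N per fraction."""
    doc = {
        "species": species,
        "group": group,
        "fractions": {
            tag: {
                "n_seqs": b.n_sequences,
                "total_length": b.total_length,
                "gc_percent": b.batch_gc_percent,
                "at_percent": b.batch_at_percent,
                "n_total": b.batch_n_total,
            }
            for tag, b in batches.items()
        },
    }
    schemas.validate(doc, schemas.SUMMARY_JSON_SCHEMA)
    _dump_json(doc, Path(path))
    return doc


def _delta_long_table(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for name, value in zip(("delta1_cdna_dna", "delta2_cds_cdna",
                                "delta3_cds_dna"), s.deltas.rounded()):
            rows.append({"group": s.group, "delta": name, "value": value})
    return pd.DataFrame(rows, columns=["group", "delta", "value"])


_FRACTION_COLS = {"DNA": "dna", "cDNA": "cdna", "cds": "cds"}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage over a cohort manifest; see the module docstring.

    Raises on an empty manifest; individual species failures are isolated
    into the report's ``skipped`` list.
    """
    manifest = pd.read_csv(config.manifest, sep="\t")
    if manifest.empty:
        raise ValueError(f"empty cohort manifest: {config.manifest}")
    root = config.manifest.parent
    out = Path(config.out_dir)
    (out / "large_json").mkdir(parents=True, exist_ok=True)
    (out / "summary_json").mkdir(parents=True, exist_ok=True)

    report = RunReport()
    profiles: list[SpeciesProfile] = []
    records: list[SpeciesRecord] = []
    for row in manifest.itertuples(index=False):
        species = row.species
        stem = species.replace(" ", "_")
        try:
            batches: dict[str, FractionBatch] = {}
            for tag in config.fractions:
                rel = getattr(row, _FRACTION_COLS[tag])
                batches[tag] = read_fraction(root / rel, species, tag)
                write_large_json(
                    batches[tag], out / "large_json" / f"{stem}.{tag}.json"
                )
                logger.info("%s %s composed: %d seqs, GC %.2f%%", species, tag,
                            batches[tag].n_sequences, batches[tag].batch_gc_percent)
            write_summary_json(species, row.group, batches,
                               out / "summary_json" / f"{stem}.json")
            profile = build_species_profile(
                batches["DNA"], batches["cDNA"], batches["cds"], row.group
            )
            profiles.append(profile)
            records.append(SpeciesRecord(
                species=species,
                group=row.group,
                assembly_level=getattr(row, "assembly_level", "scaffold"),
                gc_dna=profile.gc_dna,
            ))
            report.processed.append(species)
        except Exception as exc:  # noqa: BLE001 - error isolation contract
            logger.warning("skipping %s: %s", species, exc)
            report.skipped.append((species, str(exc)))
    if not profiles:
        raise ValueError("no species could be processed")

    summaries = summarize_groups(profiles, whisker=config.whisker)
    table = group_table(summaries)
    table.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    _delta_long_table(summaries).to_csv(out / "deltas.tsv", sep="\t", index=False)

    curated = curate_congeners(records, max_per_genus=config.max_per_genus)
    for line in curated.log_lines:
        logger.info("curation: %s", line)
    proposals = []
    by_group: dict[str, list[SpeciesRecord]] = {}
    for r in curated.retained:
        by_group.setdefault(r.group, []).append(r)
    for grp, members in sorted(by_group.items()):
        if len(members) < 3:
            logger.info("bounds: %s has <3 curated species, skipped", grp)
            continue
        for side in ("lower", "upper"):
            proposals.append(detect_gc_gap(members, min_gap=config.min_gap,
                                           side=side, group=grp))
    bounds = assemble_minmax_table(proposals)
    bounds.to_csv(out / "gc_bounds.tsv", sep="\t", index=False)

    coords, axis_ranges = normalize_to_cube(profiles, mode=config.cube_mode)
    tree_text = config.tree.read_text() if config.tree else None
    export_bundle(coords, out / "cube_bundle.json", axis_ranges=axis_ranges,
                  mode=config.cube_mode, tree=tree_text)

# artifact index is relative to out_dir so reports are location-independent
    report.outputs = {
        "group_summary": "group_summary.tsv",
        "deltas": "deltas.tsv",
        "gc_bounds": "gc_bounds.tsv",
        "cube_bundle": "cube_bundle.json",
        "large_json_dir": "large_json",
        "summary_json_dir": "summary_json",
    }
    report.to_json(out / "run_report.json")
    return report
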