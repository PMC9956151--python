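"""Dataset curation and gap-based clade GC% bounds.

Two curation concerns arise when assembling a many-species GC dataset from
public archives. First, heavily sequenced genera (rodents, primates, farm
animals) are over-represented, so congeners are pruned to a per-genus cap,
preferring chromosome-level assemblies. Second, the extreme GC% values of a
clade are often contributed by incomplete scaffold-level assemblies; a
defensible clade bound is therefore set by scanning the sorted GC% values
from the extreme inward and cutting at the first sufficiently large gap —
the bound is the first value beyond the gap, preferring the first
chromosome-level assembly at or beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ASSEMBLY_LEVELS",
    "SpeciesRecord",
    "CurationResult",
    "BoundProposal",
    "curate_congeners",
    "detect_gc_gap",
    "assemble_minmax_table",
]

#: Assembly completeness tiers, least to most complete.
ASSEMBLY_LEVELS = ("contig", "scaffold", "chromosome")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' curation-relevant metadata and whole-genome GC%."""

    species: str
    group: str
    assembly_level: str
    gc_dna: float
    genus: str = ""
    is_model_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValueError(
                f"assembly_level must be one of {ASSEMBLY_LEVELS}, "
                f"got {self.assembly_level!r}"
            )
        if not self.genus:
            # genus defaults to the binomial's first token
            object.__setattr__(self, "genus", self.species.split()[0].split("_")[0])

    @property
    def assembly_rank(self) -> int:
        return ASSEMBLY_LEVELS.index(self.assembly_level)


@dataclass
class CurationResult:
    """Outcome of congener pruning: what survived and why the rest did not."""

    retained: list[SpeciesRecord]
    removed: list[tuple[SpeciesRecord, str]] = field(default_factory=list)

    @property
    def log_lines(self) -> list[str]:
        return [f"removed {r.species} ({r.genus}): {reason}" for r, reason in self.removed]


def curate_congeners(
    records: list[SpeciesRecord], max_per_genus: int = 1
) -> CurationResult:
    """Keep at most ``max_per_genus`` species per genus.

    Retention priority within a genus: higher assembly level first
    (chromosome > scaffold > contig), then alphabetical species name as a
    deterministic tie-break. Input order of the retained records is
    preserved. Idempotent: curating an already-curated list is a no-op.
    """
    if max_per_genus < 1:
        raise ValueError("max_per_genus must be >= 1")
    by_genus: dict[str, list[SpeciesRecord]] = {}
    for r in records:
        by_genus.setdefault(r.genus, []).append(r)
    keep: set[str] = set()
    removed: list[tuple[SpeciesRecord, str]] = []
    for genus, members in by_genus.items():
        ranked = sorted(members, key=lambda r: (-r.assembly_rank, r.species))
        for r in ranked[:max_per_genus]:
            keep.add(r.species)
        for r in ranked[max_per_genus:]:
            removed.append(
                (r, f"redundant congener in {genus} "
                    f"(kept {', '.join(k.species for k in ranked[:max_per_genus])})")
            )
    return CurationResult(
        retained=[r for r in records if r.species in keep], removed=removed
    )


@dataclass(frozen=True)
class BoundProposal:
    """A proposed lower or upper GC% bound for one group.

    ``gap_interval`` is the (low GC, high GC) pair flanking the gap that
    justified the cut, or ``None`` when no qualifying gap exists and the
    bound is simply the extreme value. ``excluded`` lists the records beyond
    the gap (on the extreme side) with the reason they were set aside.
    """

    group: str
    side: str  # "lower" | "upper"
    bound_gc: float
    supporting_species: str
    gap_interval: tuple[float, float] | None
    excluded: tuple[tuple[SpeciesRecord, str], ...] = ()


def detect_gc_gap(
    records: list[SpeciesRecord],
    min_gap: float = 2.0,
    side: str = "lower",
    group: str | None = None,
) -> BoundProposal:
    """Propose a clade GC% bound by gap scanning.

    Sorts records by ``gc_dna`` and walks from the extreme on the chosen
    side toward the middle. The first inter-value gap of at least
    ``min_gap`` percentage points splits off the suspect tail; the bound is
    placed at the first value beyond the gap, preferring the first
    chromosome-level assembly at or beyond that position (incomplete
    scaffold/contig assemblies make untrustworthy extremes). With no
    qualifying gap the bound is the extreme value itself.

    The result is invariant under permutation of the input. Requires at
    least 3 records; ``min_gap`` must be positive.
    """
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    group = group if group is not None else records[0].group

    # orient so index 0 is the extreme on the chosen side
    ordered = sorted(records, key=lambda r: r.gc_dna, reverse=(side == "upper"))
    cut = 0  # first index at/beyond the gap
    gap_interval: tuple[float, float] | None = None
    for i in range(len(ordered) - 1):
        a, b = ordered[i].gc_dna, ordered[i + 1].gc_dna
        if abs(b - a) >= min_gap:
            cut = i + 1
            gap_interval = (min(a, b), max(a, b))
            break

    candidates = ordered[cut:]
    support = next(
        (r for r in candidates if r.assembly_level == "chromosome"), candidates[0]
    )
    excluded = tuple(
        (r, f"beyond {side}-side gap {gap_interval}, assembly={r.assembly_level}")
        for r in ordered[:cut]
    )
    return BoundProposal(
        group=group,
        side=side,
        bound_gc=support.gc_dna,
        supporting_species=support.species,
        gap_interval=gap_interval,
        excluded=excluded,
    )


def assemble_minmax_table(proposals: list[BoundProposal]) -> pd.DataFrame:
    """Combine bound proposals into a per-group min/max GC% table.

    One row per group, sorted by group name; columns hold the bounding
    species and its GC% for each side. At most one proposal per
    (group, side) — duplicates are a caller error.
    """
    seen: set[tuple[str, str]] = set()
    for p in proposals:
        key = (p.group, p.side)
        if key in seen:
            raise ValueError(f"conflicting duplicate proposal for {key}")
        seen.add(key)
    groups = sorted({p.group for p in proposals})
    rows = []
    for g in groups:
        row: dict[str, object] = {"group": g, "min_species": "", "min_gc": None,
                                  "max_species": "", "max_gc": None}
        for p in proposals:
            if p.group != g:
                continue
            if p.side == "lower":
                row["min_species"] = p.supporting_species
                row["min_gc"] = p.bound_gc
            else:
                row["max_species"] = p.supporting_species
                row["max_gc"] = p.bound_gc
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["group", "min_species", "min_gc", "max_species", "max_gc"]
    )
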