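"""Species GC triples, Delta statistics, and per-group summaries.

A species is reduced to the triple (GC%_DNA, GC%_cDNA, GC%_cds) — one value
per genome fraction, each length-weighted over the whole fraction. Groups
(fish, birds, mammals, ...) are summarized by unweighted means and Tukey
boxplot statistics per fraction, and by the Delta triple computed from the
three group means:

    Delta1 = GC%_cDNA − GC%_DNA     (non-coding dilution removed by splicing)
    Delta2 = GC%_cds  − GC%_cDNA    (UTR contribution)
    Delta3 = GC%_cds  − GC%_DNA     (= Delta1 + Delta2, exactly)

Delta3 is stored as the sum of the first two so additivity is exact in
floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import FractionBatch

__all__ = [
    "SpeciesProfile",
    "DeltaTriple",
    "FractionStats",
    "GroupSummary",
    "GCHistogram",
    "build_species_profile",
    "compute_deltas",
    "summarize_group",
    "summarize_groups",
    "group_table",
    "gc_histogram",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """The unit of analysis: one species' GC% triple plus metadata."""

    species: str
    group: str
    gc_dna: float
    gc_cdna: float
    gc_cds: float
    abbreviation: str = ""

    def __post_init__(self) -> None:
        for name in ("gc_dna", "gc_cdna", "gc_cds"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.species}: {name}={v} outside [0, 100]")

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.gc_dna, self.gc_cdna, self.gc_cds)

    @property
    def deltas(self) -> "DeltaTriple":
        return compute_deltas(self.gc_dna, self.gc_cdna, self.gc_cds)


@dataclass(frozen=True)
class DeltaTriple:
    """Pairwise GC% differences between fractions, in percentage points."""

    delta1: float  # cDNA − DNA
    delta2: float  # cds − cDNA
    delta3: float  # cds − DNA == delta1 + delta2

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """Presentation precision: one decimal, with the third delta printed
        as the sum of the first two so additivity survives rounding."""
        d1, d2 = round(self.delta1, ndigits), round(self.delta2, ndigits)
        return (d1, d2, round(d1 + d2, ndigits))


def compute_deltas(gc_dna: float, gc_cdna: float, gc_cds: float) -> DeltaTriple:
    """Delta triple from a (DNA, cDNA, cds) GC% triple.

    Inputs must lie in [0, 100]. Additivity delta1 + delta2 == delta3 holds
    exactly by construction.
    """
    for name, v in (("gc_dna", gc_dna), ("gc_cdna", gc_cdna), ("gc_cds", gc_cds)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    d1 = gc_cdna - gc_dna
    d2 = gc_cds - gc_cdna
    return DeltaTriple(delta1=d1, delta2=d2, delta3=d1 + d2)


def build_species_profile(
    dna: FractionBatch,
    cdna: FractionBatch,
    cds: FractionBatch,
    group: str,
    *,
    abbreviation: str = "",
) -> SpeciesProfile:
    """Assemble a species profile from its three fraction batches.

    All three batches must carry the same species label and the expected
    fraction tags; an all-ambiguous batch (undefined GC%) is an error.
    """
    batches = {"DNA": dna, "cDNA": cdna, "cds": cds}
    species = dna.species
    for tag, batch in batches.items():
        if batch.species != species:
            raise ValueError(
                f"species mismatch: {batch.species!r} ({tag}) vs {species!r}"
            )
        if batch.fraction != tag:
            raise ValueError(f"expected fraction {tag}, got {batch.fraction!r}")
        if batch.batch_gc_percent is None:
            raise ValueError(f"{species}/{tag}: GC% undefined (no unambiguous bases)")
    return SpeciesProfile(
        species=species,
        group=group,
        gc_dna=dna.batch_gc_percent,
        gc_cdna=cdna.batch_gc_percent,
        gc_cds=cds.batch_gc_percent,
        abbreviation=abbreviation,
    )


@dataclass(frozen=True)
class FractionStats:
    """Boxplot statistics of one fraction's GC% across a group's species.

    Quantiles use linear interpolation between order statistics; whiskers
    follow Tukey's rule (most extreme observation within 1.5×IQR of the box).
    """

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    min: float
    max: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _fraction_stats(values: np.ndarray, whisker: float = 1.5) -> FractionStats:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - whisker * iqr, q3 + whisker * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return FractionStats(
        n=int(values.size),
        mean=float(values.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        min=float(values.min()),
        max=float(values.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in values[(values < lo_fence) | (values > hi_fence)]),
    )


@dataclass(frozen=True)
class GroupSummary:
    """One group's per-fraction statistics and mean-based Delta triple."""

    group: str
    n_species: int
    dna: FractionStats
    cdna: FractionStats
    cds: FractionStats
    deltas: DeltaTriple = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "deltas",
            compute_deltas(self.dna.mean, self.cdna.mean, self.cds.mean),
        )


def summarize_group(
    profiles: list[SpeciesProfile], group: str, *, whisker: float = 1.5
) -> GroupSummary:
    """Summarize one group: unweighted means (one species, one vote),
    linear-interpolation quantiles, Tukey whiskers, and the Delta triple
    computed from the three group means."""
    members = [p for p in profiles if p.group == group]
    if not members:
        raise ValueError(f"no profiles in group {group!r}")
    cols = {
        "dna": np.array([p.gc_dna for p in members], dtype=float),
        "cdna": np.array([p.gc_cdna for p in members], dtype=float),
        "cds": np.array([p.gc_cds for p in members], dtype=float),
    }
    stats = {k: _fraction_stats(v, whisker) for k, v in cols.items()}
    return GroupSummary(group=group, n_species=len(members), **stats)


def summarize_groups(
    profiles: list[SpeciesProfile], *, whisker: float = 1.5
) -> list[GroupSummary]:
    """Summaries for every group present, in first-appearance order."""
    seen: list[str] = []
    for p in profiles:
        if p.group not in seen:
            seen.append(p.group)
    return [summarize_group(profiles, g, whisker=whisker) for g in seen]


def group_table(summaries: list[GroupSummary], ndigits: int = 1) -> pd.DataFrame:
    """Group-summary table: mean GC% per fraction and the three Deltas.

    Column order mirrors the standard presentation (DNA, cDNA, cds,
    Delta1, Delta2, Delta3); values rounded for display only.
    """
    rows = []
    for s in summaries:
        d1, d2, d3 = s.deltas.rounded(ndigits)
        rows.append(
            {
                "group": s.group,
                "n_species": s.n_species,
                "gc_dna": round(s.dna.mean, ndigits),
                "gc_cdna": round(s.cdna.mean, ndigits),
                "gc_cds": round(s.cds.mean, ndigits),
                "delta1_cdna_dna": d1,
                "delta2_cds_cdna": d2,
                "delta3_cds_dna": d3,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_species", "gc_dna", "gc_cdna", "gc_cds",
                 "delta1_cdna_dna", "delta2_cds_cdna", "delta3_cds_dna"],
    )


@dataclass(frozen=True)
class GCHistogram:
    """Per-sequence GC% histogram of one batch (validation view)."""

    species: str
    fraction: str
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_undefined: int

    @property
    def n_defined(self) -> int:
        return int(sum(self.counts))


def gc_histogram(batch: FractionBatch, bin_width: float = 1.0) -> GCHistogram:
    """Histogram of per-sequence GC% over [0, 100].

    Bins are half-open [lo, hi) except the last, which is closed at 100 so
    a pure-GC sequence is counted. Sequences with undefined GC% (no
    unambiguous base) are tallied separately, not binned.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    edges = np.arange(0.0, 100.0, bin_width)
    edges = np.append(edges, 100.0)  # final edge exactly 100 even if width doesn't divide
    values = [s.gc_percent for s in batch.sequences]
    defined = np.array([v for v in values if v is not None], dtype=float)
    counts, _ = np.histogram(defined, bins=edges)  # numpy closes the last bin
    return GCHistogram(
        species=batch.species,
        fraction=batch.fraction,
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        n_undefined=len(values) - defined.size,
    )
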