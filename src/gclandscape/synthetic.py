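"""Synthetic species with controllable genome-fraction composition.

Real inputs to the pipeline are three Ensembl-style multi-FASTA files per
species: the whole-genome DNA, the cDNA (spliced transcripts with UTRs) and
the cds (coding exons only). This module fabricates all three with a known
compositional truth so every downstream stage can be tested for parameter
recovery.

The generative model is deliberately minimal: a genome is a chain of
segments (intergenic, transposable-element, UTR, exon, intron, N-run), and
bases within a segment are sampled i.i.d. at the segment's GC target. TE
segments are AT-rich and attached to intergenic and intronic sequence only,
so they dilute the GC of the DNA and (via introns, which are excised) never
touch the cds — the compositional structure in which coding sequence is the
GC-richest fraction and whole-genome DNA the poorest. No codon structure,
splice signals, or TE families are modelled; soft-masking (lowercase) marks
TE and some intergenic segments, and N-runs emulate assembly gaps.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import compose_sequence

__all__ = [
    "SyntheticSpeciesSpec",
    "Segment",
    "SyntheticTruth",
    "SyntheticSpecies",
    "generate_species",
    "write_species_fasta",
    "generate_cohort",
    "demo_cohort_specs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """Parameters of one synthetic species.

    GC targets are percentages in [0, 100]; length distributions are
    (mean, sd) of a normal truncated at a floor of 10 bases (1 for exon
    counts). ``te_fraction_noncoding`` is the fraction of non-coding
    (intergenic + intron) sequence contributed by TE segments;
    ``n_run_rate`` the fraction of intergenic sequence replaced by N runs;
    ``softmask_rate`` the probability an intergenic segment is emitted in
    lowercase (TE segments are always lowercase, as repeat maskers would
    leave them).
    """

    species_name: str
    group: str
    seed: int
    n_genes: int = 150
    exon_gc_target: float = 52.0
    intron_gc_target: float = 42.0
    utr_gc_target: float = 46.0
    intergenic_gc_target: float = 38.0
    te_gc_target: float = 32.0
    te_fraction_noncoding: float = 0.3
    exon_len: tuple[float, float] = (200.0, 60.0)
    intron_len: tuple[float, float] = (500.0, 150.0)
    utr_len: tuple[float, float] = (150.0, 40.0)
    intergenic_len: tuple[float, float] = (1200.0, 300.0)
    exons_per_gene: tuple[float, float] = (7.0, 2.0)
    n_run_rate: float = 0.01
    softmask_rate: float = 0.1
    genes_per_chromosome: int = 50
    include_unspliced: bool = False  # stress-test flag: keep introns in cDNA

    def __post_init__(self) -> None:
        for name in ("exon_gc_target", "intron_gc_target", "utr_gc_target",
                     "intergenic_gc_target", "te_gc_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for name in ("te_fraction_noncoding", "n_run_rate", "softmask_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.te_fraction_noncoding >= 1.0:
            raise ValueError("te_fraction_noncoding must be < 1")
        for name in ("exon_len", "intron_len", "utr_len", "intergenic_len"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} mean must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass(frozen=True)
class Segment:
    """One compositional segment of a DNA record; segments tile the record."""

    record: str
    start: int  # 0-based, half-open
    end: int
    kind: str  # intergenic | te | n_run | utr5 | exon | intron | utr3
    gene: str | None = None


@dataclass
class SyntheticTruth:
    """Ground truth of a generated species, recomputable from the FASTA.

    ``realized_gc`` is recomputed from the emitted sequences; ``expected_gc``
    is the length-weighted mixture of the spec's per-segment GC targets over
    the realized segment lengths (N runs excluded). Their difference is pure
    binomial sampling noise.
    """

    realized_gc: dict[str, float]  # fraction -> realized batch GC%
    expected_gc: dict[str, float]  # fraction -> target mixture GC%
    segments: list[Segment]
    gene_table: pd.DataFrame  # gene, record, n_exons, cds_len, cdna_len
    te_registry: list[Segment]


@dataclass
class SyntheticSpecies:
    """In-memory generated species: records per fraction plus the truth."""

    spec: SyntheticSpeciesSpec
    dna: list[tuple[str, str]]  # (record id, sequence)
    cdna: list[tuple[str, str]]
    cds: list[tuple[str, str]]
    truth: SyntheticTruth


def _sample_bases(rng: np.random.Generator, length: int, gc_percent: float) -> str:
    if length <= 0:
        return ""
    g = gc_percent / 100.0
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _draw_len(rng: np.random.Generator, dist: tuple[float, float], floor: int = 10) -> int:
    return max(floor, int(round(rng.normal(*dist))))


def _te_len(segment_len: int, f: float) -> int:
    # appended TE length so TE bases are fraction f of (segment + TE)
    return int(round(segment_len * f / (1.0 - f))) if f > 0 else 0


def generate_species(spec: SyntheticSpeciesSpec) -> SyntheticSpecies:
    """Generate one species' three fractions and its ground truth.

    Deterministic under a fixed seed. Gene structure and genic/intergenic
    bases come from the main RNG stream; TE bases from a second stream
    derived from the same seed, so the emitted cds and cDNA are byte-wise
    independent of ``te_fraction_noncoding`` (TEs never touch exons). The
    truth's segments exactly tile each DNA record; the realized GC% per
    fraction is recomputed from the emitted sequences, not from targets.
    """
    ss_main, ss_te = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(ss_main)
    te_rng = np.random.default_rng(ss_te)
    f_te = spec.te_fraction_noncoding

    dna_records: list[tuple[str, str]] = []
    cdna_records: list[tuple[str, str]] = []
    cds_records: list[tuple[str, str]] = []
    segments: list[Segment] = []
    gene_rows: list[dict] = []

    n_chrom = -(-spec.n_genes // spec.genes_per_chromosome)  # ceil
    gene_no = 0
    for ci in range(n_chrom):
        record = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0

        def emit(kind: str, seq: str, gene: str | None = None) -> None:
            nonlocal pos
            if not seq:
                return
            segments.append(Segment(record, pos, pos + len(seq), kind, gene))
            parts.append(seq)
            pos += len(seq)

        def noncoding_block(kind: str, dist: tuple[float, float], gene: str | None,
                            gc: float, with_n: bool, maskable: bool) -> None:
            length = _draw_len(rng, dist)
            seq = _sample_bases(rng, length, gc)
            if maskable and rng.random() < spec.softmask_rate:
                seq = seq.lower()
            emit(kind, seq, gene)
            te = _te_len(length, f_te)
            if te:
                emit("te", _sample_bases(te_rng, te, spec.te_gc_target).lower(), gene)
            if with_n and spec.n_run_rate > 0:
                n_len = int(round(length * spec.n_run_rate / (1 - spec.n_run_rate)))
                if n_len:
                    emit("n_run", "N" * n_len, gene)

        genes_here = min(spec.genes_per_chromosome, spec.n_genes - gene_no)
        for _ in range(genes_here):
            gene_no += 1
            gene = f"gene{gene_no:05d}"
            noncoding_block("intergenic", spec.intergenic_len, None,
                            spec.intergenic_gc_target, with_n=True, maskable=True)
            n_exons = max(1, int(round(rng.normal(*spec.exons_per_gene))))
            utr5 = _sample_bases(rng, _draw_len(rng, spec.utr_len), spec.utr_gc_target)
            utr3 = _sample_bases(rng, _draw_len(rng, spec.utr_len), spec.utr_gc_target)
            exons = [
                _sample_bases(rng, _draw_len(rng, spec.exon_len), spec.exon_gc_target)
                for _ in range(n_exons)
            ]
            emit("utr5", utr5, gene)
            transcript_introns: list[str] = []
            for i, exon in enumerate(exons):
                emit("exon", exon, gene)
                if i < n_exons - 1:
                    length = _draw_len(rng, spec.intron_len)
                    intron = _sample_bases(rng, length, spec.intron_gc_target)
                    emit("intron", intron, gene)
                    transcript_introns.append(intron)
                    te = _te_len(length, f_te)
                    if te:
                        emit("te",
                             _sample_bases(te_rng, te, spec.te_gc_target).lower(),
                             gene)
            emit("utr3", utr3, gene)

            cds_seq = "".join(exons)
            if spec.include_unspliced:
                body = "".join(
                    e + (transcript_introns[i] if i < len(transcript_introns) else "")
                    for i, e in enumerate(exons)
                )
            else:
                body = cds_seq
            cdna_seq = utr5 + body + utr3
            cdna_records.append((f"{gene}.t1", cdna_seq))
            cds_records.append((f"{gene}.cds", cds_seq))
            gene_rows.append(
                {"gene": gene, "record": record, "n_exons": n_exons,
                 "cds_len": len(cds_seq), "cdna_len": len(cdna_seq)}
            )
        # trailing intergenic closes the chromosome
        noncoding_block("intergenic", spec.intergenic_len, None,
                        spec.intergenic_gc_target, with_n=False, maskable=True)
        dna_records.append((record, "".join(parts)))

    def realized(records: list[tuple[str, str]]) -> float:
        comps = [compose_sequence(rid, seq) for rid, seq in records]
        gc = sum(c.count_g + c.count_c for c in comps)
        acgt = sum(c.unambiguous for c in comps)
        return 100.0 * gc / acgt

    kind_target = {
        "intergenic": spec.intergenic_gc_target,
        "te": spec.te_gc_target,
        "intron": spec.intron_gc_target,
        "utr5": spec.utr_gc_target,
        "utr3": spec.utr_gc_target,
        "exon": spec.exon_gc_target,
    }

    def expected(kinds: set[str]) -> float:
        num = sum((s.end - s.start) * kind_target[s.kind]
                  for s in segments if s.kind in kinds)
        den = sum(s.end - s.start for s in segments if s.kind in kinds)
        return num / den

    cdna_kinds = {"utr5", "utr3", "exon"} | ({"intron"} if spec.include_unspliced
                                             else set())
    truth = SyntheticTruth(
        realized_gc={
            "DNA": realized(dna_records),
            "cDNA": realized(cdna_records),
            "cds": realized(cds_records),
        },
        expected_gc={
            "DNA": expected(set(kind_target)),
            "cDNA": expected(cdna_kinds),
            "cds": expected({"exon"}),
        },
        segments=segments,
        gene_table=pd.DataFrame(gene_rows),
        te_registry=[s for s in segments if s.kind == "te"],
    )
    return SyntheticSpecies(
        spec=spec, dna=dna_records, cdna=cdna_records, cds=cds_records, truth=truth
    )


def _write_fasta_gz(path: Path, records: list[tuple[str, str]], wrap: int = 60) -> None:
    # mtime=0 and no filename in the gzip header -> byte-identical re-runs
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            for rid, seq in records:
                gz.write(f">{rid}\n".encode())
                for i in range(0, len(seq), wrap):
                    gz.write(seq[i:i + wrap].encode() + b"\n")


def write_species_fasta(species: SyntheticSpecies, out_dir: str | Path) -> dict[str, Path]:
    """Write the three fractions in Ensembl-like naming; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = species.spec.species_name.replace(" ", "_")
    paths = {
        "DNA": out_dir / f"{stem}.dna.fa.gz",
        "cDNA": out_dir / f"{stem}.cdna.fa.gz",
        "cds": out_dir / f"{stem}.cds.fa.gz",
    }
    _write_fasta_gz(paths["DNA"], species.dna)
    _write_fasta_gz(paths["cDNA"], species.cdna)
    _write_fasta_gz(paths["cds"], species.cds)
    return paths


def generate_cohort(
    specs: list[SyntheticSpeciesSpec], out_root: str | Path
) -> pd.DataFrame:
    """Generate a whole cohort into a pipeline-ready directory layout.

    One subdirectory per species with the three gzip FASTA files, plus a
    ``manifest.tsv`` (species, group, seed, assembly_level and the three
    file paths relative to the manifest) consumable by the pipeline
    unchanged. Returns the manifest frame.
    """
    if not specs:
        raise ValueError("empty cohort")
    names = [s.species_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in cohort")
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in specs:
        sp = generate_species(spec)
        stem = spec.species_name.replace(" ", "_")
        paths = write_species_fasta(sp, out_root / stem)
        rows.append(
            {
                "species": spec.species_name,
                "group": spec.group,
                "seed": spec.seed,
                "assembly_level": "chromosome",
                "dna": str(paths["DNA"].relative_to(out_root)),
                "cdna": str(paths["cDNA"].relative_to(out_root)),
                "cds": str(paths["cds"].relative_to(out_root)),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_root / "manifest.tsv", sep="\t", index=False)
    return manifest


def demo_cohort_specs(
    seed: int,
    n_wide: int = 12,
    n_narrow: int = 12,
    n_genes: int = 150,
) -> list[SyntheticSpeciesSpec]:
    """Two-group demonstration cohort with contrasting GC dispersion.

    The "fish-like" group spreads its whole-genome GC targets widely across
    species (broad inter-quartile range); the "mammal-like" group is
    compositionally constrained (narrow IQR). Within every species the GC
    targets enforce the canonical fraction ordering DNA < cDNA < cds via
    AT-rich intergenic/intronic/TE sequence. Per-species seeds derive
    deterministically from the cohort seed.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in
                   ss.spawn(n_wide + n_narrow)]
    specs: list[SyntheticSpeciesSpec] = []
    wide_bases = np.linspace(36.0, 46.0, n_wide)
    narrow_bases = np.linspace(40.6, 41.6, n_narrow)
    for i, base in enumerate(wide_bases):
        specs.append(SyntheticSpeciesSpec(
            species_name=f"Ichthys{i + 1:02d} syntheticus",
            group="fish_like",
            seed=child_seeds[i],
            n_genes=n_genes,
            intergenic_gc_target=base - 3.0,
            intron_gc_target=base,
            utr_gc_target=base + 4.0,
            exon_gc_target=base + 12.0,
            te_gc_target=max(20.0, base - 8.0),
        ))
    for i, base in enumerate(narrow_bases):
        specs.append(SyntheticSpeciesSpec(
            species_name=f"Therium{i + 1:02d} syntheticum",
            group="mammal_like",
            seed=child_seeds[n_wide + i],
            n_genes=n_genes,
            intergenic_gc_target=base - 3.0,
            intron_gc_target=base,
            utr_gc_target=base + 5.0,
            exon_gc_target=base + 11.0,
            te_gc_target=max(20.0, base - 8.0),
        ))
    return specs
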