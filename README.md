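# gclandscape

Compositional cytogenomics of animal genomes: exact GC content of the three
Ensembl-style genome fractions — whole-genome **DNA**, spliced transcripts
with UTRs (**cDNA**), and coding exons (**cds**) — per species, with Delta
statistics, per-clade summaries, gap-curated GC bounds, and normalized 3D
"GC landscape" coordinates.

## Who this is for

Researchers in molecular evolution and cytogenomics who want to compare the
base composition of coding and non-coding genome fractions across many
species. Transposable elements and other repeats are typically AT-rich and
dilute the GC content of large non-coding regions, so GC% generally rises
along the trajectory DNA → cDNA → cds; the size of that rise, and how
tightly a clade is constrained around its mean, are the quantities this
package computes.

## The statistics

For a sequence set, GC% = 100·(G+C)/(A+C+G+T) over pooled counts —
length-weighted, case-insensitive (soft-masked lowercase counts), with `N`
and other IUPAC ambiguity codes excluded from the denominator (a set with no
unambiguous base has *undefined* GC%, never 0). Per species this yields the
triple (GC%\_DNA, GC%\_cDNA, GC%\_cds). Per group (unweighted means across
member species, x̄):

- **Δ1 = x̄(cDNA) − x̄(DNA)** — GC enrichment from removing intergenic and
  intronic sequence,
- **Δ2 = x̄(cds) − x̄(cDNA)** — enrichment from removing UTRs,
- **Δ3 = x̄(cds) − x̄(DNA) = Δ1 + Δ2** (additivity holds exactly).

Dispersion is summarized by the inter-quartile range (IQR, Tukey boxplot
conventions). Clade min/max GC bounds are proposed by a gap rule: sort
species by GC%, scan from the extreme inward, cut at the first gap of at
least `min_gap` percentage points (default 2.0), and place the bound at the
first value beyond the gap, preferring a chromosome-level assembly —
incomplete scaffold-level assemblies make untrustworthy extremes. For 3D
visualization each species' triple is normalized into the unit cube
(x ← DNA, y ← cDNA, z ← cds, matching red/green/blue axes).

A synthetic genome-fraction generator (segment model: intergenic / TE /
UTR / exon / intron / N-run, i.i.d. bases per segment at a target GC) makes
the whole pipeline testable offline with known ground truth.

## Worked example

```sh
gcland synth --out cohort --seed 11 --n-wide 4 --n-narrow 4 --n-genes 40
printf 'manifest: cohort/manifest.tsv\nout_dir: out\n' > config.yaml
gcland run --config config.yaml
cat out/group_summary.tsv
```

prints

```
group        n_species  gc_dna  gc_cdna  gc_cds  delta1_cdna_dna  delta2_cds_cdna  delta3_cds_dna
fish_like    4          41.0    51.6     53.0    10.6             1.4              12.0
mammal_like  4          40.9    51.0     52.0    10.1             1.0              11.1
```

Each row is one group: mean GC% per fraction across its species, then the
Delta triple computed from those means — GC rises from whole-genome DNA to
cDNA to cds in both groups, and Δ1 + Δ2 = Δ3 in every row. The run also
writes, under `out/`: per-sequence composition JSON per species × fraction
(`large_json/`), per-species roll-ups (`summary_json/`), a long-format delta
table (`deltas.tsv`), the gap-curated bounds table (`gc_bounds.tsv`), and
the unit-cube bundle (`cube_bundle.json`), e.g. the first coordinate

```
Ichthys01 syntheticus  Isyn  x=0.361  y=0.468  z=0.482  #1f77b4
```

— this synthetic species sits at GC 36.1 / 46.8 / 48.2 on the DNA / cDNA /
cds axes of the fixed 0–100 cube. Every stage is also importable
(`gclandscape.compute_deltas`, `read_fraction`, `detect_gc_gap`,
`normalize_to_cube`, ...) and available as its own subcommand
(`compose`, `profile`, `curate`, `bounds`, `cube`, `synth`, `run`).

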