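# Methods

## Composition counting

Every statistic reduces to exact per-sequence base counts (A, C, G, T, N,
other-IUPAC), tallied once per sequence with case-insensitive matching.
Conventions, chosen where common practice varies:

- **Denominator.** GC% = 100·(G+C)/(A+C+G+T). `N` and all other ambiguity
  codes are excluded, which keeps GC% + AT% = 100 and matches the NCBI
  convention; `N` counts are tracked separately per sequence and per batch.
  A sequence or batch with zero unambiguous bases has *undefined* GC%
  (`None`), which callers must handle — it never collapses to 0.
- **Soft masking.** Lowercase bases mark repeats, not absence, so they are
  counted identically to uppercase. `read_fasta(..., hard_mask=True)`
  converts lowercase to `N` before counting for repeat-excluded analyses.
- **RNA alphabet.** `U` is counted as `T`, so cDNA files in either alphabet
  give identical results.
- **Batch GC%.** Always computed from pooled counts (length-weighted),
  never as a mean of per-sequence GC% — a 4 bp all-G sequence plus a 12 bp
  all-AT sequence is 25% GC, not 50%.
- **FASTA dialect.** `>` headers, arbitrary line wrapping, blank lines
  tolerated, plain or gzip; the record id is the header up to the first
  whitespace. An empty file, or sequence text before any header, is an
  error rather than an empty success. Parsing is streaming and per-file;
  memory is bounded by the largest single record, not the file.

## Delta statistics and group summaries

A species is the triple (GC%\_DNA, GC%\_cDNA, GC%\_cds). Deltas are
Δ1 = cDNA − DNA, Δ2 = cds − cDNA, Δ3 = cds − DNA. Δ3 is stored as Δ1 + Δ2
so the additivity invariant is exact in floating point (it differs from the
directly computed difference by at most one ulp). Display rounding is one
decimal, and the printed Δ3 is the sum of the printed Δ1 and Δ2, so
additivity also survives rounding (worst-case distortion 0.05 points —
far below the statistic's meaningful precision).

Group summaries use **unweighted** means (one species, one vote; genome
sizes should not weight a between-species comparison). Deltas are computed
from the three group means, not as means of per-species deltas — the two
differ only by linearity when the same species enter each fraction, but the
mean-based definition is the one the group tables use. Quantiles use linear
interpolation between order statistics (the common boxplot default);
whiskers follow Tukey's 1.5×IQR rule; both choices are parameters of
`summarize_group`. Per-sequence GC histograms (validation views) use
half-open bins `[lo, hi)` of default width 1 point with the final bin
closed at 100; undefined-GC sequences are tallied separately.

## Curation and gap-based bounds

Congener pruning caps each genus (parsed as the binomial's first token) at
`max_per_genus` (default 1) to remove the over-sequencing bias of model
genera. Retention prefers the most complete assembly
(chromosome > scaffold > contig), then alphabetical order as a
deterministic tie-break. The operation is idempotent and returns removals
with reasons.

Clade bounds: sort species by whole-genome GC%, scan from the chosen
extreme inward, and cut at the first inter-value gap ≥ `min_gap` (default
2.0 points — the magnitude separating suspect scaffold-level extremes from
the continuous bulk in practice). The bound is the first value beyond the
gap, advanced if necessary to the first chromosome-level assembly, because
incomplete assemblies under-represent GC-rich regions and make extremes
unreliable. With no qualifying gap the bound is the extreme value. The
result is permutation-invariant and the bound never falls inside the
reported gap.

## Unit-cube export

Coordinates are (gc − lo)/(hi − lo) clamped to [0,1], with x ← DNA,
y ← cDNA, z ← cds (the red/green/blue axis convention). The default mode
`fixed_0_100` uses (0, 100) on every axis so cubes are comparable across
datasets; `minmax_per_axis` stretches each axis over the observed range
(error on zero spread) for single-dataset exploration. The mode and axis
ranges are stored in the bundle, making denormalization lossless (round
trip < 1e-9 points). Species labels abbreviate to genus initial + three
epithet letters with numeric suffixes on collision; group colors are
assigned deterministically in sorted-group order. A newick tree is passed
through verbatim for renderers that draw the phylogeny in the bottom
plane; species missing from its leaf set are recorded as bundle warnings,
not errors.

## Synthetic genome-fraction generator

The generator emulates the compositional structure that produces the
DNA < cDNA < cds GC ordering: genomes are chains of segments — intergenic,
transposable-element (TE), 5'/3' UTR, exon, intron, N-run — and bases
within a segment are i.i.d. at the segment's GC target. TE segments are
AT-rich (default target 32%) and attached only to intergenic and intronic
sequence, never exons or UTRs, so the cds is independent of the TE load by
construction; TE bases are drawn from a second RNG stream derived from the
same seed, making the emitted cds and cDNA byte-identical across
`te_fraction_noncoding` values. The cDNA convention is UTR5 + exons + UTR3
(introns excised); an `include_unspliced` flag retains introns for stress
tests. N-runs (assembly gaps) and soft-masking are injected into DNA
records only; TE segments are emitted lowercase, as a repeat masker would
leave them.

Defaults model a generic vertebrate: 150 genes (≈1.1 Mb DNA, ≈300 kb
cDNA, ≈210 kb cds), exons 200±60 bp at GC 52%, introns 500±150 bp at 42%,
UTRs 150±40 bp at 46%, intergenic 1200±300 bp at 38%, 7±2 exons per gene,
30% TE fraction of non-coding sequence, 1% N-run rate, 10% soft-mask rate.
At these sizes binomial sampling noise keeps each fraction's realized GC
within ±0.5 points of its target mixture (the truth object records both the
realized and the expected value, plus segment coordinates that exactly tile
every DNA record). The demonstration cohort contrasts a high-dispersion
"fish_like" group (whole-genome GC targets spread over ~10 points across
species) with a constrained "mammal_like" group (~1 point spread), giving
the designed IQR contrast; per-species seeds derive deterministically from
the cohort seed.

What the generator does **not** model: dinucleotide composition, codon
structure, splice signals, isochore-scale GC heterogeneity along
chromosomes, TE families, and assembly artifacts other than N-runs. Tests
passing on synthetic cohorts therefore validate the *bookkeeping and
statistics* — exact counting, pooling, summaries, curation, normalization
— not biological realism of any particular clade's values.

## Pipeline determinism and problem sizes

JSON is written with sorted keys and fixed indentation, tables with fixed
column order, and gzip FASTA with a zeroed timestamp, so identical inputs
and config reproduce every artifact bitwise. A species whose inputs are
missing or malformed is skipped with a recorded reason and the run
continues; a run in which no species survives is an error. The test suite
exercises a 10-species × 30-gene cohort; the acceptance script runs the
full 24-species × 150-gene (~1 Mb DNA each) cohort, the package's standard
demonstration scale.

## Known limitations

- Genus parsing assumes binomial species names; subspecies or strain
  suffixes fold into the epithet.
- The gap rule takes assembly level as given input; it does not verify
  assembly metadata.
- Group summaries report no significance tests; the dispersion comparison
  is descriptive (IQR), by design.
- The bundle's tree is passthrough text; no layout or reconciliation is
  attempted.
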