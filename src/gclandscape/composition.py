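"""Exact base-composition statistics for multi-FASTA genome fractions.

Every downstream quantity in the package — species GC triples, Delta
statistics, clade bounds, cube coordinates — reduces to the counts computed
here. Counting is exact and single-pass: each sequence is tallied once with
``str.count`` over its upper-cased text, so lowercase (soft-masked) bases are
counted identically to uppercase ones and ``U`` is treated as ``T``.

The GC%% denominator is the number of unambiguous bases (A+C+G+T): ``N`` and
other IUPAC ambiguity codes are excluded, which keeps GC%% + AT%% = 100 and
matches the NCBI convention. A sequence with no unambiguous base has an
*undefined* GC%% (``None``), never a silent 0.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "FastaFormatError",
    "SequenceComposition",
    "FractionBatch",
    "FRACTIONS",
    "compose_sequence",
    "read_fasta",
    "gc_percent",
    "at_percent",
    "batch_stats",
]

#: The three Ensembl-style genome fractions this package analyses.
FRACTIONS = ("DNA", "cDNA", "cds")


class FastaFormatError(ValueError):
    """Raised for empty FASTA files or sequence data before any header."""


@dataclass(frozen=True)
class SequenceComposition:
    """Base counts and GC% of a single FASTA record.

    Attributes
    ----------
    seq_id : str
        Header text up to the first whitespace.
    length_total : int
        Total record length in bases; always equals the sum of the six
        count fields.
    count_a, count_c, count_g, count_t : int
        Case-insensitive unambiguous base counts (``U`` counted as ``T``).
    count_n : int
        ``N``/``n`` bases, tracked separately from other ambiguity codes.
    count_other_ambiguous : int
        Non-ACGTN IUPAC codes (R, Y, S, W, ...).
    """

    seq_id: str
    length_total: int
    count_a: int
    count_c: int
    count_g: int
    count_t: int
    count_n: int
    count_other_ambiguous: int

    def __post_init__(self) -> None:
        total = (
            self.count_a + self.count_c + self.count_g + self.count_t
            + self.count_n + self.count_other_ambiguous
        )
        if total != self.length_total:
            raise ValueError(
                f"count fields sum to {total}, expected length {self.length_total}"
            )

    @property
    def unambiguous(self) -> int:
        """Number of A/C/G/T bases — the GC% denominator."""
        return self.count_a + self.count_c + self.count_g + self.count_t

    @property
    def gc_percent(self) -> float | None:
        """GC% over unambiguous bases, or ``None`` when there are none."""
        if self.unambiguous == 0:
            return None
        return 100.0 * (self.count_g + self.count_c) / self.unambiguous

    @property
    def at_percent(self) -> float | None:
        if self.unambiguous == 0:
            return None
        return 100.0 * (self.count_a + self.count_t) / self.unambiguous


def compose_sequence(seq_id: str, sequence: str) -> SequenceComposition:
    """Tally one sequence string into a :class:`SequenceComposition`."""
    s = sequence.upper()
    a = s.count("A")
    c = s.count("C")
    g = s.count("G")
    t = s.count("T") + s.count("U")  # RNA alphabet folded onto DNA
    n = s.count("N")
    return SequenceComposition(
        seq_id=seq_id,
        length_total=len(s),
        count_a=a,
        count_c=c,
        count_g=g,
        count_t=t,
        count_n=n,
        count_other_ambiguous=len(s) - (a + c + g + t + n),
    )


def gc_percent(comp: SequenceComposition) -> float | None:
    """GC% of a composition; ``None`` (undefined) when A+C+G+T is zero."""
    return comp.gc_percent


def at_percent(comp: SequenceComposition) -> float | None:
    return comp.at_percent


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _checked_records(handle: IO[str], name: str) -> Iterator[tuple[str, str]]:
    # SimpleFastaParser silently skips junk before the first '>' and yields
    # nothing for empty input; enforce the stricter contract here.
    lines = iter(handle)
    first = None
    for line in lines:
        if line.strip():
            first = line
            break
    if first is None:
        raise FastaFormatError(f"{name}: empty FASTA file")
    if not first.startswith(">"):
        raise FastaFormatError(f"{name}: sequence data before any '>' header")
    yield from SimpleFastaParser(itertools.chain([first], lines))


def read_fasta(
    path: str | Path,
    *,
    hard_mask: bool = False,
) -> list[SequenceComposition]:
    """Parse a (possibly gzipped) multi-FASTA file into per-record compositions.

    Record order is preserved; ``seq_id`` is the header up to the first
    whitespace. Sequence lines may be wrapped, mixed-case, and separated by
    blank lines.

    Parameters
    ----------
    hard_mask : bool
        When True, soft-masked (lowercase) bases are converted to ``N``
        before counting — mask-aware counting for repeat-sensitive analyses.
        Default False: masked bases count like any other (masking marks
        repeats, not absence).

    Raises
    ------
    FileNotFoundError
        Missing input file.
    FastaFormatError
        Empty file, or sequence data before the first header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[SequenceComposition] = []
    with _open_text(path) as handle:
        for header, seq in _checked_records(handle, path.name):
            if hard_mask:
                seq = "".join(ch if ch.isupper() else "N" for ch in seq)
            out.append(compose_sequence(header.split()[0] if header.split() else "", seq))
    return out


@dataclass
class FractionBatch:
    """All sequence compositions of one species × one genome fraction.

    ``batch_gc_percent`` is length-weighted: it is computed from the pooled
    base counts of the whole batch, never as a mean of per-sequence GC%
    values.
    """

    species: str
    fraction: str
    sequences: list[SequenceComposition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(s.length_total for s in self.sequences)

    @property
    def batch_n_total(self) -> int:
        return sum(s.count_n for s in self.sequences)

    @property
    def pooled_counts(self) -> dict[str, int]:
        keys = ("count_a", "count_c", "count_g", "count_t", "count_n",
                "count_other_ambiguous")
        return {k: sum(getattr(s, k) for s in self.sequences) for k in keys}

    @property
    def batch_gc_percent(self) -> float | None:
        c = self.pooled_counts
        denom = c["count_a"] + c["count_c"] + c["count_g"] + c["count_t"]
        if denom == 0:
            return None
        return 100.0 * (c["count_g"] + c["count_c"]) / denom

    @property
    def batch_at_percent(self) -> float | None:
        gc = self.batch_gc_percent
        return None if gc is None else 100.0 - gc


def batch_stats(
    species: str,
    fraction: str,
    seqs: Iterable[SequenceComposition],
) -> FractionBatch:
    """Pool per-sequence compositions into a :class:`FractionBatch`.

    Raises ``ValueError`` on an empty sequence list — a fraction with no
    records is an input error, not an empty success.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError(f"{species}/{fraction}: empty sequence list")
    return FractionBatch(species=species, fraction=fraction, sequences=seqs)


def read_fraction(
    path: str | Path, species: str, fraction: str, *, hard_mask: bool = False
) -> FractionBatch:
    """Convenience: parse a FASTA file directly into a batch."""
    return batch_stats(species, fraction, read_fasta(path, hard_mask=hard_mask))
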