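"""Sequence input/output, masking-aware trimming and base composition.

Coordinates are stored 0-based half-open internally; every public report
and file format uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# IUPAC nucleotide one-letter codes (uppercase); lowercase variants are
# accepted and interpreted as masked sequence.
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")


class SequenceError(ValueError):
    """Raised on malformed sequence input."""


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence.

    Lowercase letters and ``N`` mark masked bases; case is preserved so
    that masking state survives a read/write round trip.
    """

    id: str
    seq: str
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("contig id must be non-empty")
        bad = set(self.seq.upper()) - IUPAC_CODES
        if bad:
            raise SequenceError(
                f"contig {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def upper(self) -> "Contig":
        return Contig(self.id, self.seq.upper(), self.source_tag)


@dataclass(frozen=True)
class MaskedRegion:
    """A 1-based inclusive interval to exclude from composition counts."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise SequenceError(
                f"invalid masked region [{self.start},{self.end}] on {self.contig_id}"
            )


def read_fasta(path: str | Path | TextIO) -> list[Contig]:
    """Read a FASTA file into contigs.

    The header token before the first whitespace becomes the contig id;
    sequence case is preserved.  Duplicate ids raise ``SequenceError``.
    An empty file yields an empty list (with a warning logged).
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if line.strip():
                    if not line.startswith(">"):
                        raise SequenceError(
                            f"line {ln}: expected FASTA header starting with '>'"
                        )
                    break
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        logger.warning("no FASTA records found in %s", path)
        return []
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, seq=str(rec.seq)))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path | TextIO) -> None:
    """Write contigs as FASTA, wrapped at 80 columns."""
    records = (SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs)
    SeqIO.write(records, path, "fasta")


def _unmasked_runs(seq: str) -> Iterator[tuple[int, int]]:
    """Yield 0-based half-open runs of unmasked (uppercase, non-N) bases."""
    start: int | None = None
    for i, ch in enumerate(seq):
        masked = ch.islower() or ch.upper() == "N"
        if masked:
            if start is not None:
                yield start, i
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, len(seq)


def longest_unmasked_region(contig: Contig) -> Contig:
    """Extract the longest contiguous run of unmasked bases.

    Masked bases are lowercase letters or ``N``.  Ties are broken by the
    leftmost run.  A fully masked contig yields an empty-sequence result
    whose id carries an ``|empty`` suffix so callers can exclude it.
    """
    if not contig.seq:
        return contig
    best: tuple[int, int] | None = None
    for s, e in _unmasked_runs(contig.seq):
        if best is None or (e - s) > (best[1] - best[0]):
            best = (s, e)
    if best is None:
        logger.warning("contig %s is fully masked", contig.id)
        return _empty_trimmed(contig)
    s, e = best
    # 1-based inclusive suffix, once per trim (idempotent on untouched input)
    if (s, e) == (0, len(contig.seq)):
        return contig
    return Contig(
        id=f"{contig.id}:{s + 1}-{e}",
        seq=contig.seq[s:e],
        source_tag=contig.source_tag,
    )


def _empty_trimmed(contig: Contig) -> Contig:
    return Contig(id=f"{contig.id}:0-0", seq="", source_tag=contig.source_tag)


def min_length_filter(
    contigs: Sequence[Contig], min_len: int, discard_log: TextIO | None = None
) -> list[Contig]:
    """Keep contigs of at least ``min_len`` bp; log discards as TSV rows."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[Contig] = []
    n_discarded = 0
    for c in contigs:
        if c.length >= min_len:
            kept.append(c)
        else:
            n_discarded += 1
            if discard_log is not None:
                discard_log.write(f"{c.id}\ttoo_short(<{min_len}bp)\n")
    if n_discarded:
        logger.info("discarded %d contigs shorter than %d bp", n_discarded, min_len)
    return kept


def read_quality(path: str | Path) -> dict[str, list[int]]:
    """Read a phred-style quality file (FASTA-like headers, integer runs).

    Quality values are informational only; nothing downstream consumes
    them yet.
    """
    out: dict[str, list[int]] = {}
    current: str | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in out:
                    raise SequenceError(f"line {ln}: duplicate id {current!r}")
                out[current] = []
            elif current is None:
                raise SequenceError(f"line {ln}: quality values before any header")
            else:
                try:
                    out[current].extend(int(tok) for tok in line.split())
                except ValueError as exc:
                    raise SequenceError(f"line {ln}: non-integer quality") from exc
    return out


def gc_percent(
    contig: Contig, mask_intervals: Iterable[MaskedRegion] | None = None
) -> float | None:
    """GC content, in percent, of bases outside ``mask_intervals``.

    Only unambiguous A/C/G/T bases are counted (case-insensitive); N and
    other ambiguity codes contribute to neither numerator nor denominator.
    Returns ``None`` when no countable base remains.
    """
    masked = bytearray(contig.length)
    for iv in mask_intervals or ():
        if iv.contig_id != contig.id:
            continue
        if iv.end > contig.length:
            raise SequenceError(
                f"masked region [{iv.start},{iv.end}] exceeds contig "
                f"{contig.id} length {contig.length}"
            )
        for i in range(iv.start - 1, iv.end):
            masked[i] = 1
    gc = at = 0
    for i, ch in enumerate(contig.seq.upper()):
        if masked[i]:
            continue
        if ch in "GC":
            gc += 1
        elif ch in "AT":
            at += 1
    total = gc + at
    if total == 0:
        return None
    return 100.0 * gc / total
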