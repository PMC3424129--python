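"""Coding-region coordinates and genic location calls for SSR loci.

Coding coordinates are an input contract (4-column TSV or GFF3 CDS
lines); a six-frame longest-ORF finder is provided as a stand-in so the
pipeline can run end to end without external gene predictions.  Each
locus is classified as 5'UTR / coding / 3'UTR / undetermined relative to
a single CDS interval per contig.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from .sequence_io import Contig
from .ssr_miner import SSRLocus, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AnnotationError(ValueError):
    """Raised for inconsistent coding annotations."""


class LocationCall(enum.Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    CODING = "coding"
    THREE_PRIME_UTR = "three_prime_utr"
    UNDETERMINED = "undetermined"
    NO_ANNOTATION = "no_annotation"


@dataclass(frozen=True)
class CodingAnnotation:
    """One CDS interval on the sense-oriented contig (1-based inclusive)."""

    contig_id: str
    cds_start: int
    cds_end: int
    strand: str = "+"
    source: str = "user"

    def __post_init__(self) -> None:
        if not 1 <= self.cds_start <= self.cds_end:
            raise AnnotationError(
                f"invalid CDS [{self.cds_start},{self.cds_end}] on {self.contig_id}"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")


def _orfs_in_frame(seq: str, frame: int) -> Iterable[tuple[int, int, bool]]:
    """Yield 0-based half-open stop-free codon runs in one frame.

    The third element records whether the run is terminated by an
    in-frame stop codon (which the reported CDS interval then includes).
    """
    start = frame
    i = frame
    n = len(seq)
    while i + 3 <= n:
        if seq[i : i + 3] in STOP_CODONS:
            if i > start:
                yield start, i, True
            start = i + 3
        i += 3
    if i > start:
        yield start, i, False


def find_longest_orf(
    contig: Contig, min_codons: int = 30, require_atg: bool = False
) -> CodingAnnotation | None:
    """Longest open reading frame across all six frames.

    An ORF is a maximal run of codons free of TAA/TAG/TGA, optionally
    required to begin at an ATG.  Minus-strand hits are reported with
    ``strand='-'`` and coordinates on the reverse-complemented
    orientation.  Returns ``None`` below ``min_codons``.
    """
    seq = contig.seq.upper()
    # (start0, end0_excl of stop-free run, has_stop, strand)
    best: tuple[int, int, bool, str] | None = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            for a, b, has_stop in _orfs_in_frame(s, frame):
                if require_atg:
                    while a < b and s[a : a + 3] != "ATG":
                        a += 3
                if b - a < 3:
                    continue
                # reported interval includes the terminal stop codon;
                # equal spans prefer the stop-terminated (complete) ORF
                end = b + 3 if has_stop else b
                if best is None or (end - a, has_stop) > (
                    best[1] - best[0],
                    best[2],
                ):
                    best = (a, end, has_stop, strand)
    if best is None or (best[1] - best[0]) // 3 < min_codons:
        return None
    a, end, has_stop, strand = best
    return CodingAnnotation(
        contig_id=contig.id,
        cds_start=a + 1,
        cds_end=end,
        strand=strand,
        source="orf_standin",
    )


def classify_location(
    locus: SSRLocus, annotation: CodingAnnotation | None
) -> LocationCall:
    """Place a locus relative to the CDS interval of its contig.

    Containment is inclusive: a locus touching cds_start or cds_end but
    not crossing it is coding.  A locus straddling either boundary is
    undetermined; absent annotation yields no_annotation.
    """
    if annotation is None:
        return LocationCall.NO_ANNOTATION
    if annotation.contig_id != locus.contig_id:
        raise AnnotationError(
            f"annotation contig {annotation.contig_id!r} != locus contig "
            f"{locus.contig_id!r}"
        )
    if locus.start < 1:
        raise AnnotationError(f"locus start {locus.start} out of bounds")
    if locus.end < annotation.cds_start:
        return LocationCall.FIVE_PRIME_UTR
    if locus.start > annotation.cds_end:
        return LocationCall.THREE_PRIME_UTR
    if locus.start >= annotation.cds_start and locus.end <= annotation.cds_end:
        return LocationCall.CODING
    return LocationCall.UNDETERMINED


def classify_all(
    loci: Iterable[SSRLocus],
    annotations: Mapping[str, CodingAnnotation],
) -> dict[str, LocationCall]:
    """Map each locus key to its LocationCall."""
    return {
        loc.key: classify_location(loc, annotations.get(loc.contig_id))
        for loc in loci
    }


def read_annotations(path: str | Path) -> dict[str, CodingAnnotation]:
    """Read CDS coordinates from 4-column TSV or GFF3.

    GFF3 input uses lines with feature type CDS.  Exactly one CDS
    interval per contig is accepted; a second raises ``AnnotationError``.
    """
    annotations: dict[str, CodingAnnotation] = {}

    def _add(ann: CodingAnnotation) -> None:
        if ann.contig_id in annotations:
            raise AnnotationError(
                f"multiple CDS intervals for contig {ann.contig_id!r}; "
                "one interval per contig is supported"
            )
        annotations[ann.contig_id] = ann

    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##gff-version") or first.count("\t") >= 8:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8 or fields[2] != "CDS":
                    continue
                _add(
                    CodingAnnotation(
                        contig_id=fields[0],
                        cds_start=int(fields[3]),
                        cds_end=int(fields[4]),
                        strand=fields[6] if fields[6] in "+-" else "+",
                    )
                )
        else:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise AnnotationError(f"line {ln}: expected 4 columns")
                _add(
                    CodingAnnotation(
                        contig_id=fields[0],
                        cds_start=int(fields[1]),
                        cds_end=int(fields[2]),
                        strand=fields[3],
                    )
                )
    return annotations


def write_calls(calls: Mapping[str, LocationCall], handle: TextIO) -> None:
    handle.write("locus\tlocation\n")
    for key, call in calls.items():
        handle.write(f"{key}\t{call.value}\n")
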