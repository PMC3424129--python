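"""Perfect microsatellite detection and canonical motif classification.

Detects maximal perfect tandem repeats of primitive 2-6 bp units,
applying per-unit-length minimum repeat counts (6/5/4/3/3 by default).
Adjacent qualifying runs closer than a configurable interruption distance
are merged into compound records.  Motifs are normalized into canonical
classes closed under cyclic rotation and reverse complementation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .sequence_io import Contig

COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 4, 5: 3, 6: 3}

# Some published motif tables label classes by a rotation/complement of
# the lexicographic minimum; this alias table maps our canonical form to
# those display labels so external tables join cleanly.
DISPLAY_LABELS: dict[str, str] = {"ATC": "ATG", "CCG": "GGC", "ACT": "AGT"}


class MotifError(ValueError):
    """Raised for invalid repeat units."""


@dataclass(frozen=True)
class MiningConfig:
    """Detection thresholds for the repeat miner."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_interruption: int = 0

    def __post_init__(self) -> None:
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 2")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """One detected microsatellite (1-based inclusive coordinates).

    Pure loci (``ssr_type`` p2..p6) satisfy
    ``length_bp == unit_length * repeat_count``; compound records
    (``ssr_type`` 'c') span their constituent runs, kept in ``children``.
    """

    contig_id: str
    unit: str | None
    canonical_class: str | None
    repeat_count: int | None
    start: int
    end: int
    ssr_type: str
    children: tuple["SSRLocus", ...] = ()

    @property
    def unit_length(self) -> int | None:
        return len(self.unit) if self.unit else None

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"

    def motif_string(self) -> str:
        """MISA-style motif, e.g. ``(AT)7`` or ``(AT)6(AAG)5`` for compounds."""
        if self.ssr_type == "c":
            parts = []
            prev_end = None
            for ch in self.children:
                if prev_end is not None and ch.start <= prev_end:
                    parts.append("*")  # overlapping constituent runs
                parts.append(f"({ch.unit}){ch.repeat_count}")
                prev_end = ch.end
            return "".join(parts)
        return f"({self.unit}){self.repeat_count}"


def is_primitive(unit: str) -> bool:
    """True when ``unit`` is not a concatenation of a shorter repeat."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def canonical_class(unit: str) -> str:
    """Lexicographically smallest rotation of ``unit`` or its reverse complement.

    Deterministic representative of the motif class closed under cyclic
    rotation and strand exchange.
    """
    if not 2 <= len(unit) <= 6:
        raise MotifError(f"unit length must be 2-6, got {unit!r}")
    if set(unit) - set("ACGT"):
        raise MotifError(f"unit must be over ACGT, got {unit!r}")
    if not is_primitive(unit):
        raise MotifError(f"unit {unit!r} is not primitive")
    rc = reverse_complement(unit)
    candidates = [unit[i:] + unit[:i] for i in range(len(unit))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def display_label(canonical: str) -> str:
    """Published-table label for a canonical class (identity for most)."""
    return DISPLAY_LABELS.get(canonical, canonical)


def all_canonical_classes(unit_length: int) -> list[str]:
    """Exhaustive canonical classes for one unit length (sorted)."""
    from itertools import product

    classes = set()
    for tup in product("ACGT", repeat=unit_length):
        unit = "".join(tup)
        if is_primitive(unit):
            classes.add(canonical_class(unit))
    return sorted(classes)


def _pure_runs(seq: str, cfg: MiningConfig) -> list[tuple[int, int, str, int]]:
    """All maximal qualifying pure runs as 0-based (start, end_excl, unit, reps)."""
    n = len(seq)
    runs: list[tuple[int, int, str, int]] = []
    acgt = [c in "ACGT" for c in seq]
    for k, min_rep in sorted(cfg.min_repeats.items()):
        min_span = k * min_rep
        i = 0
        while i + min_span <= n:
            unit = seq[i : i + k]
            if not all(acgt[i : i + k]) or not is_primitive(unit):
                i += 1
                continue
            # left-maximality: a run already counted would cover this start
            if i >= k and seq[i - k : i] == unit:
                i += 1
                continue
            j = i + k
            while seq[j : j + k] == unit:
                j += k
            reps = (j - i) // k
            if reps >= min_rep:
                runs.append((i, i + reps * k, unit, reps))
                i = i + reps * k
            else:
                i += 1
    runs.sort()
    return runs


def detect_ssrs(contig: Contig, cfg: MiningConfig | None = None) -> list[SSRLocus]:
    """Detect all microsatellites in one contig, in ascending start order.

    Runs never span a non-ACGT base.  Runs whose gap is at most
    ``cfg.max_interruption`` bp are merged into a single compound record
    spanning all of them, with the pure runs retained as children.
    """
    cfg = cfg or MiningConfig()
    seq = contig.seq.upper()
    runs = _pure_runs(seq, cfg)
    loci: list[SSRLocus] = []
    i = 0
    while i < len(runs):
        group = [runs[i]]
        group_end = runs[i][1]
        j = i + 1
        while j < len(runs) and runs[j][0] - group_end <= cfg.max_interruption:
            group.append(runs[j])
            group_end = max(group_end, runs[j][1])
            j += 1
        if len(group) == 1:
            s, e, unit, reps = group[0]
            loci.append(
                SSRLocus(
                    contig_id=contig.id,
                    unit=unit,
                    canonical_class=canonical_class(unit),
                    repeat_count=reps,
                    start=s + 1,
                    end=e,
                    ssr_type=f"p{len(unit)}",
                )
            )
        else:
            children = tuple(
                SSRLocus(
                    contig_id=contig.id,
                    unit=unit,
                    canonical_class=canonical_class(unit),
                    repeat_count=reps,
                    start=s + 1,
                    end=e,
                    ssr_type=f"p{len(unit)}",
                )
                for s, e, unit, reps in group
            )
            loci.append(
                SSRLocus(
                    contig_id=contig.id,
                    unit=None,
                    canonical_class=None,
                    repeat_count=None,
                    start=group[0][0] + 1,
                    end=max(e for _, e, _, _ in group),
                    ssr_type="c",
                    children=children,
                )
            )
        i = j
    return loci


def mine(
    contigs: Iterable[Contig], cfg: MiningConfig | None = None
) -> list[SSRLocus]:
    """Detect microsatellites across a contig collection."""
    cfg = cfg or MiningConfig()
    out: list[SSRLocus] = []
    for c in contigs:
        out.extend(detect_ssrs(c, cfg))
    return out


def decompose(loci: Iterable[SSRLocus]) -> list[SSRLocus]:
    """Expand compound records into their constituent pure runs."""
    out: list[SSRLocus] = []
    for loc in loci:
        if loc.ssr_type == "c":
            out.extend(loc.children)
        else:
            out.append(loc)
    return out


def ssr_frequency_density(
    contigs: Sequence[Contig], loci: Sequence[SSRLocus]
) -> tuple[float, float]:
    """(frequency %, density per 10 kbp) of a locus set over a contig set.

    Frequency is the percentage of contigs containing at least one locus;
    density is loci per 10 kbp of total contig sequence.
    """
    if not contigs:
        raise ValueError("empty contig collection")
    ids = {c.id for c in contigs}
    unknown = {l.contig_id for l in loci} - ids
    if unknown:
        raise ValueError(f"loci reference unknown contigs: {sorted(unknown)[:3]}")
    with_ssr = {l.contig_id for l in loci}
    total_bp = sum(c.length for c in contigs)
    frequency = 100.0 * len(with_ssr) / len(contigs)
    density = len(loci) / (total_bp / 10_000.0)
    return frequency, density


def repeat_length_spectrum(
    loci: Iterable[SSRLocus],
) -> dict[tuple[str, int], int]:
    """Cross-tabulate pure loci by (canonical_class, repeat_count).

    Compound records are decomposed first.  Zero cells inside the
    observed repeat-count range of each class are included.
    """
    counts: dict[tuple[str, int], int] = {}
    for loc in decompose(loci):
        key = (loc.canonical_class, loc.repeat_count)
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        return {}
    # fill zero cells within each class's observed range
    by_class: dict[str, list[int]] = {}
    for cls, rep in counts:
        by_class.setdefault(cls, []).append(rep)
    for cls, reps in by_class.items():
        for r in range(min(reps), max(reps) + 1):
            counts.setdefault((cls, r), 0)
    return dict(sorted(counts.items()))


def write_misa_tsv(loci: Sequence[SSRLocus], handle: TextIO) -> None:
    """MISA-compatible table: ID, SSR nr., SSR type, SSR, size, start, end."""
    writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
    writer.writerow(["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"])
    counters: dict[str, int] = {}
    for loc in loci:
        counters[loc.contig_id] = counters.get(loc.contig_id, 0) + 1
        writer.writerow(
            [
                loc.contig_id,
                counters[loc.contig_id],
                loc.ssr_type,
                loc.motif_string(),
                loc.length_bp,
                loc.start,
                loc.end,
            ]
        )


def write_gff3(loci: Sequence[SSRLocus], handle: TextIO) -> None:
    """GFF3 output with feature type ``microsatellite`` (1-based inclusive)."""
    handle.write("##gff-version 3\n")
    counters: dict[str, int] = {}
    for loc in loci:
        counters[loc.contig_id] = counters.get(loc.contig_id, 0) + 1
        attrs = f"ID={loc.contig_id}.ssr{counters[loc.contig_id]};motif={loc.motif_string()};ssr_type={loc.ssr_type}"
        handle.write(
            "\t".join(
                [
                    loc.contig_id,
                    "estssr",
                    "microsatellite",
                    str(loc.start),
                    str(loc.end),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
            + "\n"
        )
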