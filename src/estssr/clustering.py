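"""Greedy identity clustering of input sequences and single-linkage
clustering of amplicons.

Identity is defined by dynamic programming, not by a heuristic: the
shorter sequence is globally aligned against the best window of the
longer (free end gaps on the longer), and identity is matches divided by
alignment columns over the shorter sequence's aligned span.  The k-mer
prefilter is a pure optimization — it only skips pairs that provably
cannot reach the identity threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from Bio import Align

from .sequence_io import Contig
from .ssr_miner import reverse_complement


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for both clustering flavors."""

    identity_threshold: float = 0.80
    coverage_threshold: float = 0.5
    both_strands: bool = True
    word_size: int = 4
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0,1]")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0,1]")
        if not 3 <= self.word_size <= 12:
            raise ValueError("word_size must be in [3,12]")


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def _semiglobal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aligner.end_deletion_score = 0.0  # longer-sequence overhangs are free
    return aligner


def _local_aligner(p: ClusterParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    return aligner


def _identity_from_rows(row_long: str, row_short: str) -> tuple[int, int]:
    """(matches, columns) over the shorter sequence's aligned span."""
    lo = 0
    hi = len(row_short)
    while lo < hi and row_short[lo] == "-":
        lo += 1
    while hi > lo and row_short[hi - 1] == "-":
        hi -= 1
    matches = sum(
        1 for a, b in zip(row_long[lo:hi], row_short[lo:hi]) if a == b and a != "-"
    )
    return matches, hi - lo


def _kmer_prefilter_passes(short: str, long: str, threshold: float, k: int) -> bool:
    """True unless shared k-mer counting proves identity < threshold.

    Any alignment at identity >= c has at least ceil(c*m) match columns
    split into at most E+1 runs (E = non-match columns <= m*(1-c)/c), so
    at least c*m - (k-1)*(E+1) positions of the shorter sequence carry a
    k-mer present in the longer.  Below that bound the pair cannot reach
    the threshold; when the bound is non-positive the filter is a no-op.
    """
    m = len(short)
    if m < k:
        return True
    e_max = math.floor(m * (1 - threshold) / threshold)
    bound = math.ceil(threshold * m) - (k - 1) * (e_max + 1)
    if bound <= 0:
        return True
    kmers = {long[i : i + k] for i in range(len(long) - k + 1)}
    hits = sum(1 for i in range(m - k + 1) if short[i : i + k] in kmers)
    return hits >= bound


def global_identity(
    a: str, b: str, p: ClusterParams, use_prefilter: bool = True
) -> float:
    """Identity of the shorter of ``a``/``b`` against the longer.

    Best over both strands when ``p.both_strands``.
    """
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    if not short:
        return 0.0
    aligner = _semiglobal_aligner()
    best = 0.0
    candidates = [short]
    if p.both_strands:
        candidates.append(reverse_complement(short))
    for q in candidates:
        if use_prefilter and not _kmer_prefilter_passes(
            q, long, p.identity_threshold, p.word_size
        ):
            continue
        aln = aligner.align(long, q)[0]
        matches, columns = _identity_from_rows(aln[0], aln[1])
        if columns:
            best = max(best, matches / columns)
    return best


def local_score(a: str, b: str, p: ClusterParams | None = None) -> float:
    """Best local alignment score of ``a`` vs ``b`` (either strand)."""
    p = p or ClusterParams()
    aligner = _local_aligner(p)
    best = aligner.align(a, b).score
    if p.both_strands:
        best = max(best, aligner.align(a, reverse_complement(b)).score)
    return best


def greedy_cluster(
    contigs: Sequence[Contig], p: ClusterParams | None = None
) -> list[Cluster]:
    """Representative-based greedy clustering, longest sequences first.

    Sequences are processed in descending length order (ties by id); each
    joins the first cluster whose representative it matches at
    ``identity_threshold`` over its own length, else founds a new
    cluster.  Representatives are therefore the longest member of each
    cluster, and the result is independent of input order.
    """
    if not contigs:
        raise ValueError("empty input")
    p = p or ClusterParams(identity_threshold=0.80)
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    reps: list[Contig] = []
    members: list[list[str]] = []
    for c in ordered:
        placed = False
        for idx, rep in enumerate(reps):
            if global_identity(c.seq.upper(), rep.seq.upper(), p) >= p.identity_threshold:
                members[idx].append(c.id)
                placed = True
                break
        if not placed:
            reps.append(c)
            members.append([c.id])
    return [
        Cluster(representative_id=r.id, member_ids=tuple(m))
        for r, m in zip(reps, members)
    ]


def _link_prescreen_passes(a: str, b: str, p: ClusterParams) -> bool:
    """Skip-safe k-mer screen for the local-linkage test.

    A linking alignment spans >= coverage * min-length columns at
    identity >= t, so the shorter sequence must carry at least
    t*c - (k-1)*((1-t)*c + 1) k-mers present in the longer (k chosen so
    the bound is monotone in alignment length).  Below that the pair
    cannot link; a non-positive bound disables the screen.
    """
    t = p.identity_threshold
    if t >= 1.0:
        k = p.word_size
    else:
        k = min(p.word_size, max(2, int(1.0 / (1.0 - t))))
    c_min = p.coverage_threshold * min(len(a), len(b))
    bound = t * c_min - (k - 1) * ((1.0 - t) * c_min + 1.0)
    if bound <= 0:
        return True
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    kmers = {long[i : i + k] for i in range(len(long) - k + 1)}
    hits = sum(1 for i in range(len(short) - k + 1) if short[i : i + k] in kmers)
    return hits >= bound


def _local_link(a: str, b: str, p: ClusterParams) -> bool:
    """BLAST-style linkage: local alignment at >= identity threshold
    covering >= coverage_threshold of either sequence."""
    aligner = _local_aligner(p)
    candidates = [b]
    if p.both_strands:
        candidates.append(reverse_complement(b))
    for q in candidates:
        if not _link_prescreen_passes(a, q, p):
            continue
        alignments = aligner.align(a, q)
        if not alignments or alignments.score <= 0:
            continue
        aln = alignments[0]
        row_a, row_q = aln[0], aln[1]
        columns = len(row_a)
        if columns == 0:
            continue
        matches = sum(
            1 for x, y in zip(row_a, row_q) if x == y and x != "-"
        )
        span_a = sum(1 for x in row_a if x != "-")
        span_q = sum(1 for y in row_q if y != "-")
        if matches / columns < p.identity_threshold:
            continue
        if (
            span_a / len(a) >= p.coverage_threshold
            or span_q / len(b) >= p.coverage_threshold
        ):
            return True
    return False


def single_linkage_cluster(
    contigs: Sequence[Contig], p: ClusterParams | None = None
) -> list[Cluster]:
    """Connected components under the pairwise local-alignment linkage.

    Components are labeled deterministically: member lists are sorted and
    the representative is the smallest member id.
    """
    if not contigs:
        raise ValueError("empty input")
    p = p or ClusterParams(identity_threshold=0.90, coverage_threshold=0.5)
    ids = [c.id for c in contigs]
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            if _local_link(contigs[i].seq.upper(), contigs[j].seq.upper(), p):
                union(ids[i], ids[j])

    groups: dict[str, list[str]] = {}
    for cid in ids:
        groups.setdefault(find(cid), []).append(cid)
    clusters = [
        Cluster(representative_id=min(mem), member_ids=tuple(sorted(mem)))
        for mem in groups.values()
    ]
    clusters.sort(key=lambda c: c.representative_id)
    return clusters


def write_clusters_tsv(clusters: Iterable[Cluster], handle: TextIO) -> None:
    handle.write("cluster_id\trepresentative_id\tmember_id\n")
    for i, cl in enumerate(clusters):
        for member in cl.member_ids:
            handle.write(f"{i}\t{cl.representative_id}\t{member}\n")
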