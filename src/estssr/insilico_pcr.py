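"""In-silico PCR and the marker selection pipeline.

Amplicons are predicted by scanning every template (both orientations)
for a forward-primer binding site with at most ``max_mismatch``
substitutions and an exact 3'-terminal base, paired with a downstream
reverse-primer site under the same rule.  Candidates are then triaged to
those amplifying a single product across the whole collection, clustered
by amplicon similarity with the shortest product per cluster selected,
and screened against known marker sequences by local-alignment score.

The end-to-end driver chains: SSR mining (100 bp interruption) ->
greedy clustering (identity 0.8, longest representative) -> primer
design -> in-silico PCR against all retained sequences -> unique-product
triage -> per-cluster shortest-product selection -> known-marker
exclusion.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

from .clustering import Cluster, ClusterParams, greedy_cluster, local_score, single_linkage_cluster
from .primer_design import DesignConstraints, PrimerPair, design_primers
from .sequence_io import Contig
from .ssr_miner import MiningConfig, SSRLocus, detect_ssrs, reverse_complement

logger = logging.getLogger(__name__)


class Status(enum.Enum):
    PENDING = "pending"
    NO_PRODUCT = "no_product"
    MULTI_PRODUCT = "multi_product"
    UNIQUE = "unique"
    OVERSIZE = "oversize"
    KNOWN_MARKER = "known_marker"
    SELECTED = "selected"


@dataclass(frozen=True)
class Amplicon:
    """A predicted product (1-based inclusive on the plus strand)."""

    template_id: str
    start: int
    end: int
    mismatches_forward: int
    mismatches_reverse: int
    strand: str = "+"

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MarkerCandidate:
    pair: PrimerPair
    source_id: str
    amplicons: tuple[Amplicon, ...] = ()
    status: Status = Status.PENDING
    cluster_id: int | None = None


def _mismatch_sites(
    seq: str, primer: str, max_mismatch: int, anchor_last: bool
) -> list[tuple[int, int]]:
    """(position, mismatches) of primer windows with an exact anchor base."""
    n, lp = len(seq), len(primer)
    if n < lp:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, lp)
    pvec = np.frombuffer(primer.encode(), dtype=np.uint8)
    mm = (windows != pvec).sum(axis=1)
    anchor = lp - 1 if anchor_last else 0
    ok = (mm <= max_mismatch) & (windows[:, anchor] == pvec[anchor])
    return [(int(i), int(mm[i])) for i in np.nonzero(ok)[0]]


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _scan_strand(
    fwd: str, rev_rc: str, seq: str, max_mismatch: int, max_len: int
) -> Iterable[tuple[int, int, int, int]]:
    """Yield (start0, end0_excl, mm_f, mm_r) products on one strand."""
    n = len(seq)
    lf, lr = len(fwd), len(rev_rc)
    if max_mismatch == 0:
        # exact matching in C via str.find
        fwd_sites = [(i, 0) for i in _find_all(seq, fwd)]
        if not fwd_sites:
            return
        rev_sites = [(j, 0) for j in _find_all(seq, rev_rc)]
    else:
        # vectorized window mismatch counts; the 3'-anchor base (last of
        # the forward primer, first of the reverse-complemented reverse
        # primer on this strand) must match exactly
        fwd_sites = _mismatch_sites(seq, fwd, max_mismatch, anchor_last=True)
        if not fwd_sites:
            return
        rev_sites = _mismatch_sites(seq, rev_rc, max_mismatch, anchor_last=False)
    for i, mm_f in fwd_sites:
        for j, mm_r in rev_sites:
            if j < i + lf:  # reverse footprint must follow the forward one
                continue
            length = j + lr - i
            if length <= max_len:
                yield i, j + lr, mm_f, mm_r


def find_amplicons(
    pair: PrimerPair,
    templates: Sequence[Contig],
    max_mismatch: int = 0,
    max_length: int = 5000,
) -> list[Amplicon]:
    """All predicted products of a primer pair over a template collection.

    Both template orientations are scanned; minus-strand hits are
    reported in plus-strand coordinates with ``strand='-'``.
    """
    if not templates:
        raise ValueError("empty template collection")
    fwd = pair.forward_seq.upper()
    rev = pair.reverse_seq.upper()
    rev_rc = reverse_complement(rev)
    out: list[Amplicon] = []
    for t in templates:
        seq = t.seq.upper()
        n = len(seq)
        for s0, e0, mf, mr in _scan_strand(fwd, rev_rc, seq, max_mismatch, max_length):
            out.append(Amplicon(t.id, s0 + 1, e0, mf, mr, "+"))
        rc = reverse_complement(seq)
        for s0, e0, mf, mr in _scan_strand(fwd, rev_rc, rc, max_mismatch, max_length):
            out.append(Amplicon(t.id, n - e0 + 1, n - s0, mf, mr, "-"))
    out.sort(key=lambda a: (a.template_id, a.start, a.end, a.strand))
    return out


def triage_unique(
    cands: Sequence[MarkerCandidate],
    templates: Sequence[Contig],
    max_mismatch: int = 0,
    max_product_report: int = 600,
) -> list[MarkerCandidate]:
    """Assign no_product / multi_product / unique / oversize statuses.

    Uniqueness is judged across the entire template collection,
    including multiple products within one template.
    """
    out: list[MarkerCandidate] = []
    for cand in cands:
        amps = tuple(find_amplicons(cand.pair, templates, max_mismatch))
        if len(amps) == 0:
            status = Status.NO_PRODUCT
        elif len(amps) > 1:
            status = Status.MULTI_PRODUCT
        elif amps[0].length_bp > max_product_report:
            status = Status.OVERSIZE
        else:
            status = Status.UNIQUE
        out.append(replace(cand, amplicons=amps, status=status))
    return out


def _amplicon_seq(amp: Amplicon, by_id: dict[str, Contig]) -> str:
    seq = by_id[amp.template_id].seq.upper()[amp.start - 1 : amp.end]
    return reverse_complement(seq) if amp.strand == "-" else seq


def select_markers(
    uniques: Sequence[MarkerCandidate],
    templates: Sequence[Contig],
    params: ClusterParams | None = None,
) -> list[MarkerCandidate]:
    """Cluster unique products and select the shortest per cluster.

    Amplicon sequences are clustered by single linkage (identity 0.90,
    coverage 0.5 by default); within each cluster the candidate with the
    smallest product gains status=selected (ties by template id, then
    forward primer start).
    """
    if any(c.status is not Status.UNIQUE for c in uniques):
        raise ValueError("select_markers expects unique-status candidates only")
    if not uniques:
        return []
    params = params or ClusterParams(identity_threshold=0.90, coverage_threshold=0.5)
    by_id = {t.id: t for t in templates}
    amp_contigs = [
        Contig(id=f"amp{i}", seq=_amplicon_seq(c.amplicons[0], by_id))
        for i, c in enumerate(uniques)
    ]
    clusters = single_linkage_cluster(amp_contigs, params)
    index = {c.id: i for i, c in enumerate(amp_contigs)}
    out = list(uniques)
    for cluster_no, cl in enumerate(clusters):
        members = [index[m] for m in cl.member_ids]
        best = min(
            members,
            key=lambda i: (
                uniques[i].amplicons[0].length_bp,
                uniques[i].amplicons[0].template_id,
                uniques[i].pair.forward_start,
            ),
        )
        for i in members:
            status = Status.SELECTED if i == best else Status.UNIQUE
            out[i] = replace(out[i], status=status, cluster_id=cluster_no)
    return out


def exclude_known(
    cands: Sequence[MarkerCandidate],
    known: Sequence[Contig],
    sources: Sequence[Contig],
    score_threshold: int = 50,
    params: ClusterParams | None = None,
) -> list[MarkerCandidate]:
    """Flag candidates whose source sequence matches a known marker.

    The candidate's source sequence (not the primers) is locally aligned
    against every known sequence on both strands; a score above
    ``score_threshold`` sets status=known_marker.
    """
    if not known:
        return list(cands)
    params = params or ClusterParams()
    by_id = {s.id: s for s in sources}
    out: list[MarkerCandidate] = []
    for cand in cands:
        src = by_id[cand.source_id].seq.upper()
        hit = any(
            local_score(src, k.seq.upper(), params) > score_threshold for k in known
        )
        out.append(replace(cand, status=Status.KNOWN_MARKER) if hit else cand)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters of the end-to-end marker pipeline."""

    mining: MiningConfig = field(
        default_factory=lambda: MiningConfig(max_interruption=100)
    )
    input_cluster: ClusterParams = field(
        default_factory=lambda: ClusterParams(identity_threshold=0.80)
    )
    amplicon_cluster: ClusterParams = field(
        default_factory=lambda: ClusterParams(
            identity_threshold=0.90, coverage_threshold=0.5
        )
    )
    design: DesignConstraints = field(default_factory=DesignConstraints)
    max_mismatch: int = 0
    known_score_threshold: int = 50


def run_marker_pipeline(
    seqs: Sequence[Contig],
    known: Sequence[Contig],
    cfg: PipelineConfig | None = None,
) -> list[MarkerCandidate]:
    """Run the full marker-design pipeline; see the module docstring.

    Returns every candidate with its terminal status, suitable for a
    provenance report.  Deterministic for fixed inputs and config.
    """
    cfg = cfg or PipelineConfig()

    # (1) keep SSR-containing sequences
    with_ssr = [c for c in seqs if detect_ssrs(c, cfg.mining)]
    if not with_ssr:
        return []

    # (2) deduplicate by greedy clustering, keep the longest per cluster
    clusters = greedy_cluster(with_ssr, cfg.input_cluster)
    by_id = {c.id: c for c in with_ssr}
    retained = [by_id[cl.representative_id] for cl in clusters]

    # (3) one primer pair per SSR locus (best-ranked feasible pair)
    cands: list[MarkerCandidate] = []
    for contig in retained:
        for locus in detect_ssrs(contig, cfg.mining):
            pairs, reasons = design_primers(contig, locus, cfg.design)
            if not pairs:
                logger.debug("no primers for %s: %s", locus.key, reasons)
                continue
            cands.append(MarkerCandidate(pair=pairs[0], source_id=contig.id))

    # (4) in-silico PCR against all retained sequences + triage
    cands = triage_unique(
        cands, retained, cfg.max_mismatch, cfg.design.max_product_report
    )

    # (5) shortest product per amplicon cluster
    uniques = [c for c in cands if c.status is Status.UNIQUE]
    others = [c for c in cands if c.status is not Status.UNIQUE]
    uniques = select_markers(uniques, retained, cfg.amplicon_cluster)

    # (6) known-marker exclusion applies to selected candidates
    selected = [c for c in uniques if c.status is Status.SELECTED]
    not_selected = [c for c in uniques if c.status is not Status.SELECTED]
    selected = exclude_known(
        selected, known, retained, cfg.known_score_threshold
    )

    result = others + not_selected + selected
    result.sort(key=lambda c: (c.source_id, c.pair.target_locus, c.pair.forward_start))
    return result


def write_provenance_tsv(cands: Iterable[MarkerCandidate], handle: TextIO) -> None:
    handle.write(
        "source_id\tlocus\tforward\treverse\tproduct_bp\tn_amplicons\t"
        "cluster_id\tstatus\n"
    )
    for c in cands:
        cluster = c.cluster_id if c.cluster_id is not None else "."
        handle.write(
            f"{c.source_id}\t{c.pair.target_locus}\t{c.pair.forward_seq}\t"
            f"{c.pair.reverse_seq}\t{c.pair.expected_product_bp}\t"
            f"{len(c.amplicons)}\t{cluster}\t{c.status.value}\n"
        )
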