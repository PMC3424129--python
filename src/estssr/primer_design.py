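"""SSR-flanking primer pair enumeration under explicit constraints.

A transparent stand-in for a full thermodynamic design engine: every
candidate pair satisfying the declared length / Tm / GC / product-size /
homopolymer / dimer constraints is enumerated and ranked by a simple
penalty against the stated optima.  Melting temperature uses the Wallace
rule below 14 bases and the GC-fraction formula at and above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .sequence_io import Contig
from .ssr_miner import SSRLocus, reverse_complement


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignConstraints:
    primer_len: tuple[int, int] = (18, 24)
    primer_len_opt: int = 20
    tm: tuple[float, float] = (57.0, 63.0)
    tm_opt: float = 60.0
    gc: tuple[float, float] = (30.0, 70.0)
    product_size: tuple[int, int] = (100, 400)
    max_homopolymer: int = 4
    max_product_report: int = 600
    max_dimer: int = 8  # reject on a perfect self/cross dimer of >= this length

    def __post_init__(self) -> None:
        for lo, hi in (self.primer_len, self.tm, self.gc, self.product_size):
            if lo > hi:
                raise DesignError("empty constraint range")
        if not self.primer_len[0] <= self.primer_len_opt <= self.primer_len[1]:
            raise DesignError("primer length optimum outside range")
        if not self.tm[0] <= self.tm_opt <= self.tm[1]:
            raise DesignError("Tm optimum outside range")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on a template (1-based coordinates).

    ``forward_start`` is the 5' base of the forward primer;
    ``reverse_end`` the template position paired with the reverse
    primer's 5' base.  ``expected_product_bp`` includes both primer
    footprints.
    """

    forward_seq: str
    reverse_seq: str
    forward_start: int
    reverse_end: int
    tm_forward: float
    tm_reverse: float
    target_locus: str
    penalty: float = 0.0
    oversize: bool = False

    @property
    def expected_product_bp(self) -> int:
        return self.reverse_end - self.forward_start + 1

    @property
    def forward_end(self) -> int:
        return self.forward_start + len(self.forward_seq) - 1

    @property
    def reverse_binding_start(self) -> int:
        return self.reverse_end - len(self.reverse_seq) + 1


def melting_temperature(primer: str) -> float:
    """Wallace 2(A+T)+4(G+C) below 14 nt, else 64.9 + 41*(GC-16.4)/len."""
    if len(primer) < 8:
        raise DesignError("primer too short for Tm estimate (< 8 nt)")
    primer = primer.upper()
    if set(primer) - set("ACGT"):
        raise DesignError(f"non-ACGT base in primer {primer!r}")
    gc = primer.count("G") + primer.count("C")
    at = len(primer) - gc
    if len(primer) < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _has_dimer(a: str, b: str, min_len: int) -> bool:
    """Perfect reverse-complement match of >= min_len between a and b."""
    if min_len > min(len(a), len(b)):
        return False
    rc = reverse_complement(b)
    windows = {rc[i : i + min_len] for i in range(len(rc) - min_len + 1)}
    return any(a[i : i + min_len] in windows for i in range(len(a) - min_len + 1))


def _candidate_primers(
    template: str, lo: int, hi: int, k: DesignConstraints
) -> list[tuple[int, str, float]]:
    """All constraint-satisfying primers inside template[lo:hi) (0-based)."""
    out = []
    for ln in range(k.primer_len[0], k.primer_len[1] + 1):
        for s in range(lo, hi - ln + 1):
            seq = template[s : s + ln]
            if set(seq) - set("ACGT"):
                continue
            gc = 100.0 * (seq.count("G") + seq.count("C")) / ln
            if not k.gc[0] <= gc <= k.gc[1]:
                continue
            tm = melting_temperature(seq)
            if not k.tm[0] <= tm <= k.tm[1]:
                continue
            if _max_homopolymer(seq) > k.max_homopolymer:
                continue
            if _has_dimer(seq, seq, k.max_dimer):
                continue
            out.append((s, seq, tm))
    return out


def design_primers(
    template: Contig,
    target: SSRLocus,
    k: DesignConstraints | None = None,
) -> tuple[list[PrimerPair], list[str]]:
    """Enumerate and rank primer pairs bracketing ``target``.

    Returns (ranked pairs, reason codes).  Reason codes are non-empty
    only when the result is empty, naming the first constraint that
    eliminated all candidates.  Pairs whose product exceeds
    ``max_product_report`` are flagged ``oversize`` rather than dropped.
    """
    k = k or DesignConstraints()
    seq = template.seq.upper()
    n = len(seq)
    ssr_lo = target.start - 1  # 0-based inclusive
    ssr_hi = target.end  # 0-based exclusive
    min_len = k.primer_len[0]
    if ssr_lo < min_len or n - ssr_hi < min_len:
        return [], ["insufficient flank"]

    # restrict windows by the maximum product size
    max_prod = k.product_size[1]
    fwd_lo = max(0, ssr_hi - max_prod)
    fwd = _candidate_primers(seq, fwd_lo, ssr_lo, k)
    rev_hi = min(n, ssr_lo + max_prod)
    # reverse candidates: windows on the template whose revcomp is the primer
    rev = [
        (s, reverse_complement(w), tm)
        for s, w, tm in _candidate_primers(seq, ssr_hi, rev_hi, k)
    ]
    if not fwd:
        return [], ["no forward primer satisfies constraints"]
    if not rev:
        return [], ["no reverse primer satisfies constraints"]

    mid = (k.product_size[0] + k.product_size[1]) / 2.0
    # precomputed k-mer sets make the cross-dimer check an intersection
    d = k.max_dimer
    fwd_kmers = [
        {fseq[i : i + d] for i in range(len(fseq) - d + 1)} for _, fseq, _ in fwd
    ]
    rev_kmers = []
    for _, rseq, _ in rev:
        rc = reverse_complement(rseq)
        rev_kmers.append({rc[i : i + d] for i in range(len(rc) - d + 1)})
    pairs: list[PrimerPair] = []
    for (fs, fseq, ftm), fk in zip(fwd, fwd_kmers):
        if fs + len(fseq) > ssr_lo:  # SSR must lie strictly after forward primer
            continue
        for (rs, rseq, rtm), rk in zip(rev, rev_kmers):
            if rs < ssr_hi:  # and strictly before the reverse binding site
                continue
            product = rs + len(rseq) - fs
            if not k.product_size[0] <= product <= k.product_size[1]:
                continue
            if fk & rk:  # cross-dimer
                continue
            penalty = (
                abs(ftm - k.tm_opt)
                + abs(rtm - k.tm_opt)
                + abs(len(fseq) - k.primer_len_opt)
                + abs(len(rseq) - k.primer_len_opt)
                + 0.01 * abs(product - mid)
            )
            pairs.append(
                PrimerPair(
                    forward_seq=fseq,
                    reverse_seq=rseq,
                    forward_start=fs + 1,
                    reverse_end=rs + len(rseq),
                    tm_forward=ftm,
                    tm_reverse=rtm,
                    target_locus=target.key,
                    penalty=penalty,
                    oversize=product > k.max_product_report,
                )
            )
    if not pairs:
        return [], ["no pair satisfies product-size/dimer constraints"]
    pairs.sort(key=lambda p: (p.penalty, p.forward_start, p.expected_product_bp))
    return pairs, []


def write_primers_tsv(pairs: Iterable[PrimerPair], handle: TextIO) -> None:
    handle.write(
        "locus\tforward\treverse\ttm_forward\ttm_reverse\tproduct_bp\tpenalty\tflags\n"
    )
    for p in pairs:
        flags = "oversize" if p.oversize else "."
        handle.write(
            f"{p.target_locus}\t{p.forward_seq}\t{p.reverse_seq}\t"
            f"{p.tm_forward:.2f}\t{p.tm_reverse:.2f}\t{p.expected_product_bp}\t"
            f"{p.penalty:.3f}\t{flags}\n"
        )
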