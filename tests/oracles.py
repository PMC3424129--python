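"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration, independent of the
library's implementations.
"""

from __future__ import annotations

from math import comb


def brute_pure_ssrs(seq: str, min_repeats: dict[int, int]) -> list[tuple[int, int, str, int]]:
    """All pure repeat runs as 1-based (start, end, unit, reps).

    Enumerates every (start, unit length) pair, extends greedily, keeps
    left-maximal primitive runs meeting the per-length minimum, then
    deduplicates overlaps within a unit length by leftmost-greedy
    acceptance (regex-style global matching semantics).
    """
    seq = seq.upper()
    n = len(seq)
    accepted: list[tuple[int, int, str, int]] = []
    for k, min_rep in sorted(min_repeats.items()):
        candidates = []
        for i in range(n - k * min_rep + 1):
            unit = seq[i : i + k]
            if any(ch not in "ACGT" for ch in unit):
                continue
            # primitivity
            if any(
                k % d == 0 and unit == unit[:d] * (k // d) for d in range(1, k)
            ):
                continue
            # left-maximality
            if i >= k and seq[i - k : i] == unit:
                continue
            j = i + k
            while seq[j : j + k] == unit:
                j += k
            reps = (j - i) // k
            if reps >= min_rep:
                candidates.append((i, j, unit, reps))
        taken_until = -1
        for i, j, unit, reps in sorted(candidates):
            if i > taken_until:
                accepted.append((i + 1, j, unit, reps))
                taken_until = j - 1
    accepted.sort()
    return accepted


def brute_merge_compound(
    runs: list[tuple[int, int, str, int]], max_interruption: int
) -> list[list[tuple[int, int, str, int]]]:
    """Group sorted runs whose gap is <= max_interruption bp."""
    groups: list[list[tuple[int, int, str, int]]] = []
    for run in sorted(runs):
        if groups and run[0] - max(r[1] for r in groups[-1]) - 1 <= max_interruption:
            groups[-1].append(run)
        else:
            groups.append([run])
    return groups


def brute_amplicons(
    forward: str,
    reverse: str,
    template_id: str,
    seq: str,
    max_mismatch: int = 0,
    max_length: int = 5000,
) -> list[tuple[str, int, int, str]]:
    """All products as (template_id, start, end, strand), 1-based plus-strand.

    Direct enumeration of every forward/reverse binding-site pair on
    both orientations with an exact 3'-terminal base.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def rc(s: str) -> str:
        return "".join(comp.get(c, "N") for c in reversed(s))

    out = []
    seq = seq.upper()
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        fwd_sites = []
        for i in range(n - len(forward) + 1):
            window = s[i : i + len(forward)]
            if window[-1] != forward[-1]:
                continue
            if sum(1 for a, b in zip(forward, window) if a != b) <= max_mismatch:
                fwd_sites.append(i)
        rev_rc = rc(reverse)
        rev_sites = []
        for j in range(n - len(reverse) + 1):
            window = s[j : j + len(reverse)]
            if window[0] != rev_rc[0]:
                continue
            if sum(1 for a, b in zip(rev_rc, window) if a != b) <= max_mismatch:
                rev_sites.append(j)
        for i in fwd_sites:
            for j in rev_sites:
                if j < i + len(forward):
                    continue
                end0 = j + len(reverse)
                if end0 - i > max_length:
                    continue
                if strand == "+":
                    out.append((template_id, i + 1, end0, "+"))
                else:
                    out.append((template_id, n - end0 + 1, n - i, "-"))
    return sorted(out)


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (overrepresentation) Fisher p for [[a,b],[c,d]].

    Exact tail sum of the hypergeometric distribution, enumerated
    directly from binomial coefficients.
    """
    row1 = a + b
    col1 = a + c
    total = a + b + c + d
    denom = comb(total, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > total - row1:
            continue
        p += comb(row1, x) * comb(total - row1, col1 - x) / denom
    return p


def six_frame_longest_orf(seq: str) -> tuple[int, int, str] | None:
    """Longest stop-free codon run over six frames.

    Returns 1-based (start, end, strand) on the strand's own
    orientation, with a terminal in-frame stop codon included.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    stops = {"TAA", "TAG", "TGA"}

    def rc(s: str) -> str:
        return "".join(comp.get(ch, "N") for ch in reversed(s))

    best = None
    for strand, s in (("+", seq.upper()), ("-", rc(seq.upper()))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            start = 0
            for idx in range(len(codons) + 1):
                hit_stop = idx < len(codons) and codons[idx] in stops
                if hit_stop or idx == len(codons):
                    run = idx - start
                    if run > 0:
                        a = frame + start * 3
                        b = frame + idx * 3 + (3 if hit_stop else 0)
                        if best is None or (b - a, hit_stop) > (best[0], best[4]):
                            best = (b - a, a + 1, b, strand, hit_stop)
                    start = idx + 1
    if best is None:
        return None
    _, a, b, strand, _ = best
    return a, b, strand
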