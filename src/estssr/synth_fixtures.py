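"""Synthetic inputs with known ground truth, plus packaged count tables.

Contig generation plants SSR loci and CDS intervals at recorded
coordinates over a random background at a target GC, with rejection
sampling guaranteeing that no accidental qualifying SSR appears near a
planted one.  All generators are pure functions of their parameters and
an explicit seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .sequence_io import Contig
from .ssr_miner import MiningConfig, detect_ssrs
from .ssr_stats import CountRecord

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class PlantedSSR:
    contig_id: str
    unit: str
    repeat_count: int
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class PlantedCDS:
    contig_id: str
    cds_start: int
    cds_end: int


@dataclass
class PlantingManifest:
    seed: int
    gc: float
    ssrs: list[PlantedSSR] = field(default_factory=list)
    cds: list[PlantedCDS] = field(default_factory=list)

    def write_tsv(self, handle: TextIO) -> None:
        handle.write("contig_id\tunit\trepeat_count\tstart\tend\n")
        for s in self.ssrs:
            handle.write(
                f"{s.contig_id}\t{s.unit}\t{s.repeat_count}\t{s.start}\t{s.end}\n"
            )


def _random_background(
    rng: np.random.Generator, length: int, gc: float
) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _has_accidental_ssr(
    seq: str, planted: Sequence[tuple[int, int]], cfg: MiningConfig, margin: int = 50
) -> bool:
    """True when mining finds a locus not matching a planted interval.

    Only loci within ``margin`` bp of a planted interval or anywhere
    else in the contig count as accidental; planted intervals themselves
    are expected hits.
    """
    expected = {(s, e) for s, e in planted}
    for loc in detect_ssrs(Contig(id="tmp", seq=seq), cfg):
        if (loc.start, loc.end) not in expected:
            return True
    return False


def _primer_site(rng: np.random.Generator, gc_bases: int = 13, length: int = 20) -> str:
    """A 20-mer with fixed GC count, bounded homopolymers, no self-dimer."""
    from .primer_design import _has_dimer, _max_homopolymer

    pool = list("GC" * 50)[:gc_bases] + list("AT" * 50)[: length - gc_bases]
    while True:
        site = "".join(rng.permutation(pool))
        if _max_homopolymer(site) <= 4 and not _has_dimer(site, site, 8):
            return site


def generate_contigs(
    n: int,
    length_range: tuple[int, int] = (300, 800),
    gc: float = 0.4,
    ssr_spec: Sequence[tuple[str, int]] | None = None,
    cds_fraction: float = 0.0,
    seed: int = 0,
    mining_config: MiningConfig | None = None,
    id_prefix: str = "synth",
    plant_primer_sites: bool = False,
) -> tuple[list[Contig], PlantingManifest]:
    """Generate contigs with planted SSRs and optional CDS intervals.

    ``ssr_spec`` lists (unit, repeat_count) pairs planted one per contig,
    cycling when n exceeds the list; ``None`` entries (or no spec) plant
    nothing.  Backgrounds are resampled (up to 1000 attempts) until the
    only detectable loci are the planted ones.  With
    ``plant_primer_sites`` a primer-friendly 20-mer is embedded 40 bp
    either side of each planted SSR, guaranteeing a feasible design
    under default constraints.  Deterministic in ``seed``.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0,1)")
    if length_range[0] > length_range[1] or length_range[0] < 1:
        raise ValueError("invalid length range")
    from .primer_design import _has_dimer

    rng = np.random.default_rng(seed)
    cfg = mining_config or MiningConfig()
    manifest = PlantingManifest(seed=seed, gc=gc)
    contigs: list[Contig] = []
    margin = 70 if plant_primer_sites else 30
    for i in range(n):
        cid = f"{id_prefix}{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        plant = ssr_spec[i % len(ssr_spec)] if ssr_spec else None
        ssr_len = len(plant[0]) * plant[1] if plant else 0
        if plant and length < ssr_len + 2 * margin:
            raise ValueError(
                f"contig {cid}: length {length} cannot hold a {ssr_len} bp SSR "
                "with clean flanks"
            )
        for attempt in range(_MAX_ATTEMPTS):
            bases = _random_background(rng, length, gc)
            planted_intervals: list[tuple[int, int]] = []
            if plant:
                unit, reps = plant
                lo = margin
                hi = length - ssr_len - margin
                pos = int(rng.integers(lo, hi + 1))
                bases[pos : pos + ssr_len] = list(unit * reps)
                planted_intervals.append((pos + 1, pos + ssr_len))
                if plant_primer_sites:
                    from .ssr_miner import reverse_complement

                    fwd_site = _primer_site(rng)
                    while True:
                        rev_window = _primer_site(rng)
                        rev_primer = reverse_complement(rev_window)
                        if not _has_dimer(fwd_site, rev_primer, 8):
                            break
                    bases[pos - 60 : pos - 40] = list(fwd_site)
                    bases[pos + ssr_len + 40 : pos + ssr_len + 60] = list(rev_window)
            seq = "".join(bases)
            if not _has_accidental_ssr(seq, planted_intervals, cfg):
                break
        else:
            raise RuntimeError(f"could not generate clean contig {cid}")
        contigs.append(Contig(id=cid, seq=seq))
        if plant:
            s, e = planted_intervals[0]
            manifest.ssrs.append(PlantedSSR(cid, plant[0], plant[1], s, e))
        if cds_fraction > 0:
            cds_len = max(3, (int(length * cds_fraction) // 3) * 3)
            start = int(rng.integers(1, max(2, length - cds_len)))
            manifest.cds.append(PlantedCDS(cid, start, start + cds_len - 1))
    return contigs, manifest


def generate_marker_outcomes(
    n_loci: int,
    glm_truth: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated marker outcome table for GLM recovery tests.

    Covariates: pipeline label, SSR location label, expected product
    size, summed primer Tm, repeat count and unit length.  PCR success
    is drawn binomial-logit from ``success_intercept`` +
    ``product_size_slope`` * product; allele count Na is drawn
    Poisson-log from ``na_intercept`` + ``repeat_slope`` * repeats.
    """
    truth = {
        "success_intercept": 0.5,
        "product_size_slope": -0.004,
        "na_intercept": 0.3,
        "repeat_slope": 0.13,
    }
    if glm_truth:
        truth.update(glm_truth)
    rng = np.random.default_rng(seed)
    product = rng.integers(100, 401, size=n_loci)
    tm_sum = rng.normal(120.0, 3.0, size=n_loci)
    repeats = rng.integers(4, 15, size=n_loci)
    unit_len = rng.integers(2, 7, size=n_loci)
    pipeline = rng.choice(["alpha", "beta"], size=n_loci)
    location = rng.choice(["coding", "others"], size=n_loci)
    eta = truth["success_intercept"] + truth["product_size_slope"] * product
    success = rng.random(n_loci) < 1.0 / (1.0 + np.exp(-eta))
    mu = np.exp(truth["na_intercept"] + truth["repeat_slope"] * repeats)
    na = rng.poisson(mu)
    return pd.DataFrame(
        {
            "pipeline": pipeline,
            "location": location,
            "product_size": product,
            "tm_sum": tm_sum,
            "repeat_count": repeats,
            "unit_length": unit_len,
            "pcr_success": success.astype(int),
            "na": na,
        }
    )


def table2_fixture() -> list[CountRecord]:
    """The packaged motif-by-location count table as records."""
    text = (
        resources.files("estssr.data")
        .joinpath("motif_location_counts.tsv")
        .read_text()
    )
    records: list[CountRecord] = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        records.append(
            CountRecord(
                group=row["group"],
                motif=row["motif"],
                location=row["location"],
                count=int(row["count"]),
            )
        )
    return records
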