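"""Summary and inferential statistics for SSR analyses.

Covers motif-by-location summary tables, binomial/Poisson GLMs with Wald
z tests, marker diversity indices (Na, Ho, He, PIC), one-sided Fisher
enrichment with Benjamini-Hochberg adjustment, Welch's t-test,
rank/linear correlation, and repeat-count polymorphism forecasts.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .orf_annotator import LocationCall
from .ssr_miner import SSRLocus, display_label

UNIT_GROUPS = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
LOCATIONS = ("three_prime_utr", "five_prime_utr", "coding", "undetermined")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the usual printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountRecord:
    """One cell of a motif-by-location count table.

    ``motif`` is a display label (or '.' for unit-length groups counted
    without motif breakdown).
    """

    group: str
    motif: str
    location: str
    count: int


@dataclass
class SummaryTable:
    """Motif-class-by-location counts with derived totals and percentages."""

    records: list[CountRecord]

    def __post_init__(self) -> None:
        if any(r.count < 0 for r in self.records):
            raise ValueError("negative count")

    # --- totals -------------------------------------------------------
    def cell(self, group: str, motif: str, location: str) -> int:
        return sum(
            r.count
            for r in self.records
            if r.group == group and r.motif == motif and r.location == location
        )

    def motif_total(self, group: str, motif: str) -> int:
        return sum(
            r.count for r in self.records if r.group == group and r.motif == motif
        )

    def group_total(self, group: str) -> int:
        return sum(r.count for r in self.records if r.group == group)

    def location_total(self, location: str) -> int:
        return sum(r.count for r in self.records if r.location == location)

    @property
    def grand_total(self) -> int:
        return sum(r.count for r in self.records)

    @property
    def pure_total(self) -> int:
        return sum(r.count for r in self.records if r.group != "compound")

    # --- percentages --------------------------------------------------
    @staticmethod
    def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
        if denominator == 0:
            raise ZeroDivisionError("empty denominator for percentage")
        return round_half_up(100.0 * numerator / denominator, ndigits)

    def motif_share_of_group(self, group: str, motif: str) -> float:
        """Percent of the unit-length group in one motif class."""
        return self.percent(self.motif_total(group, motif), self.group_total(group))

    def location_share_of_group(self, group: str, location: str) -> float:
        """Percent of the unit-length group located in one region."""
        return self.percent(
            sum(
                r.count
                for r in self.records
                if r.group == group and r.location == location
            ),
            self.group_total(group),
        )

    def cell_share_of_group(self, group: str, motif: str, location: str) -> float:
        return self.percent(self.cell(group, motif, location), self.group_total(group))

    def motif_share_of_pure(self, group: str, motif: str) -> float:
        return self.percent(self.motif_total(group, motif), self.pure_total)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.records])
        return df.pivot_table(
            index=["group", "motif"],
            columns="location",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )


def summarize_by_location(
    loci: Sequence[SSRLocus], calls: Mapping[str, LocationCall]
) -> SummaryTable:
    """Build a SummaryTable from mined loci and their location calls.

    Di- and tri-SSRs are broken down by canonical class (display
    labels); tetra/penta/hexa and compound records are counted as
    groups.  Every locus must carry a call.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for loc in loci:
        call = calls.get(loc.key)
        if call is None:
            raise ValueError(f"no location call for locus {loc.key}")
        if loc.ssr_type == "c":
            group, motif = "compound", "."
        else:
            group = UNIT_GROUPS[loc.unit_length]
            motif = display_label(loc.canonical_class) if group in ("di", "tri") else "."
        key = (group, motif, call.value)
        counts[key] = counts.get(key, 0) + 1
    records = [
        CountRecord(group=g, motif=m, location=l, count=n)
        for (g, m, l), n in sorted(counts.items())
    ]
    return SummaryTable(records)


# ---------------------------------------------------------------------
# Generalized linear models


class GLMFamily(enum.Enum):
    BINOMIAL_LOGIT = "binomial_logit"
    POISSON_LOG = "poisson_log"


@dataclass(frozen=True)
class GLMSpec:
    family: GLMFamily
    response: str
    covariates: tuple[str, ...]
    reference_levels: Mapping[str, str] = field(default_factory=dict)


@dataclass
class GLMResult:
    terms: pd.DataFrame  # index=term, columns: estimate, se, z, p
    converged: bool
    deviance: float
    separation_warning: bool = False


def fit_glm(data: pd.DataFrame, spec: GLMSpec) -> GLMResult:
    """Maximum-likelihood GLM fit with per-term Wald z tests.

    Categorical covariates are dummy-coded against the declared
    reference level (first level otherwise).  Quasi-separated binomial
    fits are flagged rather than raised.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 observations")
    y = data[spec.response].to_numpy(dtype=float)
    X = pd.DataFrame(index=data.index)
    for cov in spec.covariates:
        col = data[cov]
        if col.nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            ref = spec.reference_levels.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {cov!r}")
            for lvl in levels:
                if lvl == ref:
                    continue
                X[f"{cov}[{lvl}]"] = (col == lvl).astype(float)
        else:
            X[cov] = col.astype(float)
    X = sm.add_constant(X, prepend=True)

    if spec.family is GLMFamily.BINOMIAL_LOGIT:
        family = sm.families.Binomial()
    elif spec.family is GLMFamily.POISSON_LOG:
        family = sm.families.Poisson()
    else:  # pragma: no cover
        raise ValueError(spec.family)

    separation = False
    if spec.family is GLMFamily.BINOMIAL_LOGIT and len(np.unique(y)) < 2:
        separation = True
        warnings.warn("binomial response is constant: complete separation")

    model = sm.GLM(y, X, family=family)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    estimates = res.params
    se = res.bse
    if spec.family is GLMFamily.BINOMIAL_LOGIT and (
        np.any(np.abs(estimates) > 15) or np.any(~np.isfinite(se))
    ):
        separation = True
    z = estimates / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"estimate": estimates, "se": se, "z": z, "p": p}, index=X.columns
    )
    return GLMResult(
        terms=terms,
        converged=bool(res.converged),
        deviance=float(res.deviance),
        separation_warning=separation,
    )


# ---------------------------------------------------------------------
# Marker diversity


@dataclass(frozen=True)
class GenotypeDiversity:
    locus_id: str
    n: int
    na: int
    ho: float
    he: float
    pic: float


def diversity_stats(
    genotypes: Sequence[tuple[object, object] | None], locus_id: str = "locus"
) -> GenotypeDiversity:
    """Na/Ho/He/PIC from per-individual two-allele calls.

    ``None`` entries are missing individuals and are excluded.  He is the
    uncorrected expected heterozygosity 1 - sum(p^2); PIC follows the
    two-locus product expansion 1 - sum(p^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    called = [g for g in genotypes if g is not None]
    if not called:
        raise ValueError("all genotype calls missing")
    alleles: list[object] = []
    het = 0
    for a1, a2 in called:
        alleles.extend((a1, a2))
        if a1 != a2:
            het += 1
    freqs = pd.Series(alleles).value_counts(normalize=True).to_numpy()
    he = 1.0 - float(np.sum(freqs**2))
    pic = he - float(
        sum(
            2.0 * freqs[i] ** 2 * freqs[j] ** 2
            for i in range(len(freqs))
            for j in range(i + 1, len(freqs))
        )
    )
    return GenotypeDiversity(
        locus_id=locus_id,
        n=len(called),
        na=len(set(alleles)),
        ho=het / len(called),
        he=he,
        pic=pic,
    )


def unbiased_he(he: float, n: int) -> float:
    """Sample-size-corrected expected heterozygosity (2n/(2n-1) factor)."""
    return 2 * n / (2 * n - 1) * he


# ---------------------------------------------------------------------
# Enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    subset_with: int
    subset_without: int
    background_with: int
    background_without: int
    odds_ratio: float
    p: float
    q: float


def enrich_go(
    annotations: Mapping[str, Iterable[str]],
    subset: Iterable[str],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Per-term Fisher exact tests of subset membership vs term membership.

    The universe is the annotated contig set; ``background`` columns
    count non-subset contigs.  One-sided overrepresentation by default;
    q-values are Benjamini-Hochberg.  Sorted by q then p ascending.
    """
    subset_ids = set(subset)
    universe = set(annotations)
    if not subset_ids:
        raise ValueError("empty subset")
    if not subset_ids <= universe:
        raise ValueError("subset contains unannotated contigs")
    term_members: dict[str, set[str]] = {}
    for cid, terms in annotations.items():
        for t in terms:
            term_members.setdefault(t, set()).add(cid)
    n_subset = len(subset_ids)
    n_bg = len(universe) - n_subset
    rows = []
    for term, members in sorted(term_members.items()):
        a = len(members & subset_ids)
        b = n_subset - a
        c = len(members) - a
        d = n_bg - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append((term, a, b, c, d, odds, p))
    pvals = np.array([r[6] for r in rows])
    qvals = _benjamini_hochberg(pvals)
    results = [
        EnrichmentResult(term, a, b, c, d, float(odds), float(p), float(q))
        for (term, a, b, c, d, odds, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, each q >= its p)."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------
# Classical tests


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both samples")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def rank_and_linear_correlation(
    x: Sequence[float], y: Sequence[float]
) -> dict[str, float | None]:
    """Spearman and Pearson coefficients with p-values.

    Constant inputs yield ``None`` coefficients (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples of length >= 4")
    out: dict[str, float | None] = {}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {
            "spearman_r": None,
            "spearman_p": None,
            "pearson_r": None,
            "pearson_p": None,
        }
    sr = stats.spearmanr(x, y)
    pr = stats.pearsonr(x, y)
    out["spearman_r"] = float(sr.statistic)
    out["spearman_p"] = float(sr.pvalue)
    out["pearson_r"] = float(pr.statistic)
    out["pearson_p"] = float(pr.pvalue)
    return out


# ---------------------------------------------------------------------
# Polymorphism forecast


class Forecast(enum.Enum):
    ALWAYS = "always"
    POSSIBLY = "possibly"
    UNLIKELY = "unlikely"


#: (always_at, possibly_at) repeat-count thresholds per unit length
_FORECAST_THRESHOLDS = {2: (9, 6), 3: (10, 4)}


def polymorphism_forecast(
    unit_length: int, repeat_count: int
) -> tuple[Forecast, bool]:
    """Forecast marker polymorphism from repeat count.

    Returns (forecast, calibrated).  Calibrated thresholds exist for
    di- and tri-SSRs only; other unit lengths return POSSIBLY with
    calibrated=False.
    """
    thresholds = _FORECAST_THRESHOLDS.get(unit_length)
    if thresholds is None:
        return Forecast.POSSIBLY, False
    always_at, possibly_at = thresholds
    if repeat_count >= always_at:
        return Forecast.ALWAYS, True
    if repeat_count >= possibly_at:
        return Forecast.POSSIBLY, True
    return Forecast.UNLIKELY, True
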