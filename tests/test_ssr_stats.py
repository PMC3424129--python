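import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from estssr.orf_annotator import CodingAnnotation, LocationCall, classify_all
from estssr.sequence_io import Contig
from estssr.ssr_miner import MiningConfig, detect_ssrs
from estssr.ssr_stats import (
    Forecast,
    GLMFamily,
    GLMSpec,
    SummaryTable,
    _benjamini_hochberg,
    diversity_stats,
    enrich_go,
    fit_glm,
    polymorphism_forecast,
    rank_and_linear_correlation,
    round_half_up,
    summarize_by_location,
    welch_t,
)
from estssr.synth_fixtures import generate_marker_outcomes, table2_fixture
from oracles import hypergeom_tail_p


@pytest.fixture(scope="module")
def table2():
    return SummaryTable(table2_fixture())


class TestSummaryTableFixture:
    def test_grand_total(self, table2):
        assert table2.grand_total == 4059

    def test_pure_total(self, table2):
        assert table2.pure_total == 4003

    def test_group_subtotals(self, table2):
        assert table2.group_total("di") == 655
        assert table2.group_total("tri") == 1319
        assert table2.group_total("tetra") == 194
        assert table2.group_total("penta") == 741
        assert table2.group_total("hexa") == 1094
        assert table2.group_total("compound") == 56

    def test_location_totals(self, table2):
        assert table2.location_total("three_prime_utr") == 779
        assert table2.location_total("five_prime_utr") == 835
        assert table2.location_total("coding") == 2383
        assert table2.location_total("undetermined") == 62

    @pytest.mark.parametrize(
        "method,args,expected",
        [
            ("motif_share_of_group", ("di", "AT"), 46.3),
            ("motif_share_of_group", ("tri", "AAG"), 25.9),
            ("location_share_of_group", ("tri", "coding"), 72.8),
            ("location_share_of_group", ("hexa", "coding"), 64.3),
            ("location_share_of_group", ("di", "coding"), 42.1),
            ("cell_share_of_group", ("di", "AT", "three_prime_utr"), 23.5),
            ("cell_share_of_group", ("di", "AG", "coding"), 23.7),
            ("cell_share_of_group", ("di", "AT", "five_prime_utr"), 10.7),
            ("motif_share_of_pure", ("di", "AT"), 7.6),
        ],
    )
    def test_printed_percentages(self, table2, method, args, expected):
        assert getattr(table2, method)(*args) == expected

    def test_percentages_recompute_from_counts(self, table2):
        at = table2.motif_total("di", "AT")
        di = table2.group_total("di")
        assert table2.motif_share_of_group("di", "AT") == round_half_up(
            100 * at / di, 1
        )


class TestSummarizeByLocation:
    def test_single_locus(self):
        (locus,) = detect_ssrs(Contig(id="c", seq="ATATATATATAT"), MiningConfig())
        calls = {locus.key: LocationCall.CODING}
        table = summarize_by_location([locus], calls)
        assert table.grand_total == 1
        assert table.cell_share_of_group("di", "AT", "coding") == 100.0

    def test_counts_partition(self):
        contig = Contig(id="c", seq="ATATATATATAT" + "GCGC" + "AAGAAGAAGAAGAAG")
        loci = detect_ssrs(contig, MiningConfig())
        ann = {"c": CodingAnnotation(contig_id="c", cds_start=14, cds_end=16)}
        calls = classify_all(loci, ann)
        table = summarize_by_location(loci, calls)
        assert table.grand_total == len(loci)

    def test_missing_call_raises(self):
        (locus,) = detect_ssrs(Contig(id="c", seq="ATATATATATAT"), MiningConfig())
        with pytest.raises(ValueError):
            summarize_by_location([locus], {})


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(46.25, 46.3), (10.65, 10.7), (7.55, 7.6), (72.84, 72.8)]
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_up(value, 1) == expected


class TestGLM:
    def test_binomial_recovery(self):
        data = generate_marker_outcomes(2000, seed=5)
        res = fit_glm(
            data,
            GLMSpec(
                family=GLMFamily.BINOMIAL_LOGIT,
                response="pcr_success",
                covariates=("product_size",),
            ),
        )
        assert res.converged
        est = res.terms.loc["product_size"]
        assert abs(est["estimate"] - (-0.004)) < 3 * est["se"]
        intercept = res.terms.loc["const"]
        assert abs(intercept["estimate"] - 0.5) < 3 * intercept["se"]
        assert res.terms["z"].equals(res.terms["estimate"] / res.terms["se"])

    def test_poisson_recovery(self):
        data = generate_marker_outcomes(2000, seed=6)
        res = fit_glm(
            data,
            GLMSpec(
                family=GLMFamily.POISSON_LOG,
                response="na",
                covariates=("repeat_count",),
            ),
        )
        est = res.terms.loc["repeat_count"]
        assert abs(est["estimate"] - 0.13) < 3 * est["se"]

    def test_categorical_reference_level(self):
        data = generate_marker_outcomes(500, seed=7)
        res = fit_glm(
            data,
            GLMSpec(
                family=GLMFamily.BINOMIAL_LOGIT,
                response="pcr_success",
                covariates=("pipeline", "product_size"),
                reference_levels={"pipeline": "alpha"},
            ),
        )
        assert "pipeline[beta]" in res.terms.index
        assert "pipeline[alpha]" not in res.terms.index

    def test_constant_response_separation_warning(self):
        data = generate_marker_outcomes(100, seed=8)
        data["pcr_success"] = 1
        with pytest.warns(UserWarning, match="separation"):
            res = fit_glm(
                data,
                GLMSpec(
                    family=GLMFamily.BINOMIAL_LOGIT,
                    response="pcr_success",
                    covariates=("product_size",),
                ),
            )
        assert res.separation_warning

    def test_too_few_observations(self):
        data = generate_marker_outcomes(5, seed=9)
        with pytest.raises(ValueError):
            fit_glm(
                data,
                GLMSpec(
                    family=GLMFamily.POISSON_LOG,
                    response="na",
                    covariates=("repeat_count",),
                ),
            )

    def test_constant_covariate_rejected(self):
        data = generate_marker_outcomes(100, seed=10)
        data["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_glm(
                data,
                GLMSpec(
                    family=GLMFamily.POISSON_LOG,
                    response="na",
                    covariates=("flat",),
                ),
            )

    def test_wald_coverage(self):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            data = generate_marker_outcomes(400, seed=1000 + rep)
            res = fit_glm(
                data,
                GLMSpec(
                    family=GLMFamily.POISSON_LOG,
                    response="na",
                    covariates=("repeat_count",),
                ),
            )
            est = res.terms.loc["repeat_count"]
            lo = est["estimate"] - 1.96 * est["se"]
            hi = est["estimate"] + 1.96 * est["se"]
            hits += lo <= 0.13 <= hi
        assert 0.90 * n_rep <= hits <= 0.999 * n_rep


class TestDiversity:
    def test_monomorphic(self):
        d = diversity_stats([(1, 1)] * 10)
        assert (d.na, d.ho, d.he, d.pic) == (1, 0.0, 0.0, 0.0)

    def test_two_alleles_half(self):
        # allele frequencies exactly 0.5/0.5
        genotypes = [(1, 2)] * 5 + [(1, 1), (2, 2)] * 0 + [(2, 1)] * 5
        d = diversity_stats(genotypes)
        assert d.he == pytest.approx(0.5)
        assert d.pic == pytest.approx(0.375)

    def test_missing_excluded(self):
        d = diversity_stats([(1, 2), None, (1, 1)])
        assert d.n == 2
        assert d.ho == 0.5

    def test_all_missing_error(self):
        with pytest.raises(ValueError):
            diversity_stats([None, None])

    def test_pic_le_he_and_he_matches_brute(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 6))
            genos = [
                (int(rng.integers(0, k)), int(rng.integers(0, k))) for _ in range(25)
            ]
            d = diversity_stats(genos)
            alleles = [a for g in genos for a in g]
            freqs = pd.Series(alleles).value_counts(normalize=True)
            assert d.he == pytest.approx(1 - float((freqs**2).sum()))
            assert d.pic <= d.he + 1e-12
            assert 0 <= d.ho <= 1

    def test_order_invariance(self, rng):
        genos = [(int(rng.integers(0, 4)), int(rng.integers(0, 4))) for _ in range(20)]
        d1 = diversity_stats(genos)
        d2 = diversity_stats(list(reversed(genos)))
        assert d1 == d2


class TestEnrichment:
    def test_uniform_term_p_one(self):
        annotations = {f"c{i}": ["GO:1"] for i in range(100)}
        subset = [f"c{i}" for i in range(20)]
        (res,) = enrich_go(annotations, subset)
        assert res.p == pytest.approx(1.0)

    def test_matches_hypergeom_oracle(self):
        # the worked 2x2: 8/92 in subset, 20/880 in background
        annotations = {}
        idx = 0
        for _ in range(8):
            annotations[f"s{idx}"] = ["T"]; idx += 1
        for _ in range(92):
            annotations[f"s{idx}"] = []; idx += 1
        for _ in range(20):
            annotations[f"b{idx}"] = ["T"]; idx += 1
        for _ in range(880):
            annotations[f"b{idx}"] = []; idx += 1
        subset = [k for k in annotations if k.startswith("s")]
        (res,) = enrich_go(annotations, subset)
        assert (res.subset_with, res.subset_without) == (8, 92)
        assert (res.background_with, res.background_without) == (20, 880)
        assert res.p == pytest.approx(hypergeom_tail_p(8, 92, 20, 880), rel=1e-9)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(25):
            a, b, c, d = (int(rng.integers(0, 30)) for _ in range(4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0:
                continue
            _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(hypergeom_tail_p(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_planted_enrichment_ranks_first(self, rng):
        annotations = {}
        subset = []
        for i in range(500):
            cid = f"c{i}"
            terms = []
            in_subset = i < 100
            if in_subset:
                subset.append(cid)
            for t in range(10):
                base_p = 0.1
                p_term = base_p * 3 if (t == 0 and in_subset) else base_p
                if rng.random() < p_term:
                    terms.append(f"GO:{t}")
            annotations[cid] = terms
        results = enrich_go(annotations, subset)
        assert results[0].term == "GO:0"

    def test_q_ge_p_and_monotone(self, rng):
        pvals = rng.random(50)
        qvals = _benjamini_hochberg(pvals)
        assert np.all(qvals >= pvals - 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(qvals[order]) >= -1e-15)

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        pvals = rng.random(40)
        ours = _benjamini_hochberg(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_empty_subset_error(self):
        with pytest.raises(ValueError):
            enrich_go({"a": ["T"]}, [])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computation(self):
        a = [1, 2, 3, 4, 5]
        b = [2, 3, 4, 5, 6]
        t, df, p = welch_t(a, b)
        # var = 2.5 for both, se = sqrt(1), t = -1
        assert t == pytest.approx(-1.0)
        assert df == pytest.approx(8.0)
        res = sps.ttest_ind(a, b, equal_var=False)
        assert p == pytest.approx(res.pvalue)

    def test_p_monotone_in_shift(self, rng):
        a = rng.normal(0, 1, 200)
        ps = []
        for shift in (0.1, 0.5, 1.0, 2.0):
            _, _, p = welch_t(a, a + shift)
            ps.append(p)
        assert ps == sorted(ps, reverse=True)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            welch_t([1, 1, 1], [2, 2, 2])


class TestCorrelation:
    def test_monotone_nonlinear(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 8, 27, 64, 125]
        out = rank_and_linear_correlation(x, y)
        assert out["spearman_r"] == pytest.approx(1.0)

    def test_identity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        out = rank_and_linear_correlation(x, x)
        assert out["spearman_r"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_fixed_eight_points(self):
        x = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0, 9.0]
        out = rank_and_linear_correlation(x, y)
        # direct formula evaluation
        xm, ym = np.mean(x), np.mean(y)
        r = np.sum((np.array(x) - xm) * (np.array(y) - ym)) / np.sqrt(
            np.sum((np.array(x) - xm) ** 2) * np.sum((np.array(y) - ym) ** 2)
        )
        assert out["pearson_r"] == pytest.approx(float(r))
        assert out["spearman_r"] == pytest.approx(
            float(sps.spearmanr(x, y).statistic)
        )

    def test_constant_vector_missing(self):
        out = rank_and_linear_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert out["pearson_r"] is None

    def test_too_short(self):
        with pytest.raises(ValueError):
            rank_and_linear_correlation([1, 2], [3, 4])


class TestForecast:
    @pytest.mark.parametrize(
        "unit_length,repeats,expected",
        [
            (2, 9, Forecast.ALWAYS),
            (2, 8, Forecast.POSSIBLY),
            (2, 6, Forecast.POSSIBLY),
            (2, 5, Forecast.UNLIKELY),
            (3, 10, Forecast.ALWAYS),
            (3, 9, Forecast.POSSIBLY),
            (3, 4, Forecast.POSSIBLY),
            (3, 3, Forecast.UNLIKELY),
        ],
    )
    def test_calibrated(self, unit_length, repeats, expected):
        forecast, calibrated = polymorphism_forecast(unit_length, repeats)
        assert forecast == expected
        assert calibrated

    def test_uncalibrated(self):
        forecast, calibrated = polymorphism_forecast(4, 12)
        assert forecast == Forecast.POSSIBLY
        assert not calibrated
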