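"""Rarefaction, normalisation, the step-change statistic and FDR control."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ebprkit.changepoint import (
    OtuTable,
    epoch_change_table,
    epoch_fold_change,
    estimate_pi0,
    log_normalize,
    qvalues,
    rarefy,
    simulate_error_rates,
    step_change_test,
    taxon_relative_abundance,
    ubiquitous_filter,
)
from ebprkit.errors import ValidationError
from ebprkit.simulate import OtuSimSpec, gen_otu_counts

from conftest import make_otu_table


class TestRarefy:
    def test_columns_sum_to_depth_and_counts_bounded(self, tiny_table):
        out = rarefy(tiny_table, depth=50, seed=0)
        assert (out.counts.sum(axis=0) == 50).all()
        assert (out.counts.to_numpy() <= tiny_table.counts.to_numpy()).all()

    def test_exhaustive_draw_preserves_column(self):
        t = make_otu_table([[3, 5], [7, 5]])
        out = rarefy(t, depth=10, seed=1)
        assert out.counts.iloc[:, 0].tolist() == [3, 7]

    def test_depth_zero_gives_all_zero_table(self, tiny_table):
        assert (rarefy(tiny_table, 0, seed=0).counts.to_numpy() == 0).all()

    def test_excessive_depth_names_offending_samples(self, tiny_table):
        with pytest.raises(ValidationError, match="2013-05-29"):
            rarefy(tiny_table, depth=10_000, seed=0)

    def test_subsampling_is_mean_preserving(self):
        # hypergeometric expectation: half the depth -> half the count
        t = make_otu_table([[40], [60], [100]])
        draws = np.array(
            [rarefy(t, depth=100, seed=s).counts.iloc[0, 0] for s in range(3000)]
        )
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - 20.0) < 4 * se


class TestLogNormalize:
    def test_exact_powers_and_zero(self, tiny_table):
        t = make_otu_table([[0, 9, 999]])
        out = log_normalize(t)
        assert out.to_numpy().flatten() == pytest.approx([0.0, 1.0, 3.0])

    def test_shape_and_order_preserved(self, tiny_table):
        out = log_normalize(tiny_table)
        assert out.shape == tiny_table.counts.shape
        assert list(out.index) == list(tiny_table.counts.index)


class TestTaxonAggregation:
    def test_summed_relative_abundance_of_genus(self):
        # three OTUs at 1.74%, 0.87% and 0.65% sum to 3.26% collectively
        acc = "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Rhodocyclales; f__Rhodocyclaceae; g__Candidatus Accumulibacter; s__"
        other = "k__Bacteria; p__Proteobacteria; g__; s__"
        counts = np.array([[174], [87], [65], [9674]])
        t = make_otu_table(counts, taxonomy=[acc, acc, acc, other])
        _, overall, ids = taxon_relative_abundance(t, "g__Candidatus Accumulibacter")
        assert len(ids) == 3
        assert overall == pytest.approx(0.0326)

    def test_match_all_gives_unity(self, tiny_table):
        _, overall, _ = taxon_relative_abundance(tiny_table, "k__Bacteria")
        assert overall == pytest.approx(1.0)

    def test_unclassified_rank_never_matches_named_query(self):
        t = make_otu_table(
            [[10], [10]],
            taxonomy=["k__Bacteria; g__; s__", "k__Bacteria; g__Nitrospira; s__"],
        )
        per_sample, overall, ids = taxon_relative_abundance(t, "g__Nitrospira")
        assert list(ids) == ["otu1"]
        assert overall == pytest.approx(0.5)

    def test_zero_match_taxon_gives_zero(self, tiny_table):
        _, overall, ids = taxon_relative_abundance(tiny_table, "g__Missing")
        assert overall == 0.0 and len(ids) == 0


class TestStepChangeTest:
    def test_hand_computed_example(self):
        r = step_change_test([1, 2, 1, 2, 3, 4, 3, 4, 3, 4], (4, 6))
        assert r.difference == pytest.approx(2.0)
        assert r.f_statistic == pytest.approx(30.72)
        assert r.p_value == pytest.approx(5.4e-4, rel=0.02)

    def test_constant_series(self):
        r = step_change_test([2.0] * 10, (4, 6))
        assert r.difference == 0.0 and r.f_statistic == 0.0 and r.p_value == 1.0

    def test_zero_within_variance_flagged(self):
        r = step_change_test([1] * 4 + [2] * 6, (4, 6))
        assert math.isinf(r.f_statistic)
        assert r.flagged and 0 < r.p_value < 1e-100

    def test_matches_anova_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            x = rng.normal(size=10)
            r = step_change_test(x, (4, 6))
            f, p = stats.f_oneway(x[:4], x[4:])
            assert abs(r.f_statistic - f) <= 1e-10 * max(1.0, abs(f))
            assert abs(r.p_value - p) <= 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        base = step_change_test(x, (4, 6))
        for a, b in [(2.5, -1.0), (-3.0, 4.0), (0.1, 100.0)]:
            r = step_change_test(a * x + b, (4, 6))
            assert r.f_statistic == pytest.approx(base.f_statistic)
            assert r.p_value == pytest.approx(base.p_value)
            assert r.difference == pytest.approx(a * base.difference)

    def test_short_segments_rejected(self):
        with pytest.raises(ValidationError):
            step_change_test([1, 2, 3], (1, 2))


class TestQvalues:
    def test_single_certain_null(self):
        q, pi0 = qvalues([1.0])
        assert q.tolist() == [1.0] and pi0 == 1.0

    def test_bh_equivalence_when_pi0_forced_to_one(self):
        p = [0.01, 0.02, 0.03, 0.04]
        q, _ = qvalues(p, pi0=1.0)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_equivalence_oracle_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, size=500)
        q, _ = qvalues(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(bh)

    def test_pi0_near_one_for_uniform_pvalues(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=10_000)
        p = np.clip(p, 1e-12, 1.0)
        pi0 = estimate_pi0(p)
        assert 0.9 <= pi0 <= 1.1

    def test_q_monotone_along_sorted_p(self):
        rng = np.random.default_rng(5)
        p = np.clip(rng.beta(0.5, 3.0, size=400), 1e-12, 1.0)
        q, pi0 = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        # never below the pi0-scaled BH values
        bh, _ = qvalues(p, pi0=1.0)
        assert (q >= pi0 * bh - 1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            qvalues([])
        with pytest.raises(ValidationError):
            qvalues([0.0, 0.5])


class TestFoldChange:
    def test_equal_epoch_means_give_unity(self):
        t = make_otu_table([[10] * 10, [90] * 10])
        fc = epoch_fold_change(t, "otu0", (4, 6))
        assert fc.factor == 1.0 and fc.direction == "none"

    def test_planted_step_factor_recovered(self):
        spec = OtuSimSpec(
            n_otus=50,
            depth=100_000,
            step_factor=[2.0] + [1.0] * 49,
            mean_log_baseline=-2.0,
            log_baseline_sd=0.3,
            log_noise_sd=0.02,
            rng_seed=9,
        )
        fc = epoch_fold_change(gen_otu_counts(spec), "otu0000", (4, 6))
        assert fc.direction == "increase"
        assert fc.factor == pytest.approx(2.0, rel=0.05)

    def test_planted_decrease_reported_as_factor_above_one(self):
        spec = OtuSimSpec(
            n_otus=50,
            depth=100_000,
            step_factor=[1 / 3] + [1.0] * 49,
            mean_log_baseline=-2.0,
            log_baseline_sd=0.3,
            log_noise_sd=0.02,
            rng_seed=10,
        )
        fc = epoch_fold_change(gen_otu_counts(spec), "otu0000", (4, 6))
        assert fc.direction == "decrease"
        assert fc.factor == pytest.approx(3.0, rel=0.08)

    def test_zero_high_epoch_mean_flagged(self):
        t = make_otu_table([[0, 0, 0, 0, 5, 5, 5, 5, 5, 5], [10] * 10])
        fc = epoch_fold_change(t, "otu0", (4, 6))
        assert math.isnan(fc.factor) and fc.direction == "undefined"


class TestPipeline:
    def test_only_ubiquitous_otus_tested(self):
        counts = np.array(
            [[5] * 10, [0] + [5] * 9, [8] * 10]
        )
        t = make_otu_table(counts)
        assert list(ubiquitous_filter(t)) == ["otu0", "otu2"]
        res = epoch_change_table(t, (4, 6))
        assert set(res["otu_id"]) == {"otu0", "otu2"}

    def test_planted_change_ranks_first(self):
        spec = OtuSimSpec(
            n_otus=80,
            depth=50_000,
            step_factor=[4.0] + [1.0] * 79,
            mean_log_baseline=-2.0,
            log_noise_sd=0.05,
            rng_seed=2,
        )
        res = epoch_change_table(gen_otu_counts(spec), (4, 6))
        assert res.iloc[0]["otu_id"] == "otu0000"
        assert res.iloc[0]["q"] < 0.05
        assert res.iloc[0]["difference"] > 0  # second epoch minus first

    def test_table_schema(self, tiny_table):
        res = epoch_change_table(tiny_table, (4, 6))
        assert list(res.columns) == [
            "otu_id", "difference", "f_statistic", "p_raw", "q", "annotation",
        ]


class TestErrorRateSimulation:
    def test_nominal_type_one_error(self):
        report = simulate_error_rates(
            (4, 6), effects=[0.0], rhos=[0.0], alpha=0.05, reps=4000, seed=0
        )
        rate = report.rates["rejection_rate"].iloc[0]
        assert rate == pytest.approx(0.05, abs=0.012)

    def test_large_effect_has_full_power(self):
        report = simulate_error_rates(
            (4, 6), effects=[10.0], rhos=[0.0], alpha=0.05, reps=500, seed=1
        )
        assert report.rates["rejection_rate"].iloc[0] > 0.999

    def test_autocorrelation_inflates_false_positives(self):
        report = simulate_error_rates(
            (4, 6), effects=[0.0], rhos=[0.0, 0.6], alpha=0.05, reps=4000, seed=2
        )
        r0 = report.rates.query("rho == 0.0")["rejection_rate"].iloc[0]
        r6 = report.rates.query("rho == 0.6")["rejection_rate"].iloc[0]
        assert r6 >= r0
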