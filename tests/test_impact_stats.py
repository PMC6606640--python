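import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import median_test as scipy_median_test
from scipy.stats import norm

from cpdtools.cpd_classifier import classify_dataset
from cpdtools.errors import InsufficientDataError, ValidationError
from cpdtools.impact_stats import (
    build_impact_table,
    compare_cpd_vs_nocpd,
    compare_mild_vs_severe,
    fisher_exact_2x2,
    moods_median_test,
    overlap_fraction,
)
from cpdtools.synthetic_data import (
    SimulationConfig,
    gen_msa,
    gen_variant_and_property_tables,
)

counts = st.integers(min_value=0, max_value=40)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 0], [0, 3]], 0.1),  # 2 of 4 margin-preserving tables, 1/20 each
            ([[5, 5], [5, 5]], 1.0),
            ([[1, 0], [0, 1]], 1.0),
        ],
    )
    def test_hand_enumerable_tables(self, table, expected):
        assert fisher_exact_2x2(table).p_value == pytest.approx(expected)

    def test_degenerate_margin_returns_one(self, caplog):
        with caplog.at_level(logging.WARNING):
            result = fisher_exact_2x2([[0, 0], [3, 4]])
        assert result.p_value == 1.0

    @pytest.mark.parametrize("table", [[[-1, 2], [3, 4]], [[1.5, 2], [3, 4]]])
    def test_invalid_counts_rejected(self, table):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(table)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(deadline=None, max_examples=200)
    def test_agrees_with_scipy_reference(self, a, b, c, d):
        ours = fisher_exact_2x2([[a, b], [c, d]]).p_value
        theirs = scipy_fisher([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(float(theirs), rel=1e-9, abs=1e-12)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(deadline=None, max_examples=100)
    def test_invariant_under_row_and_column_swaps(self, a, b, c, d):
        p = fisher_exact_2x2([[a, b], [c, d]]).p_value
        assert fisher_exact_2x2([[c, d], [a, b]]).p_value == pytest.approx(p)
        assert fisher_exact_2x2([[b, a], [d, c]]).p_value == pytest.approx(p)


class TestMoodsMedian:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        result = moods_median_test(x, x)
        assert result.p_value == pytest.approx(1.0)
        assert result.medians == (2.5, 2.5)

    def test_fully_separated_triples(self):
        result = moods_median_test([1, 2, 3], [10, 11, 12])
        # grand median 6.5 dichotomises into [[0,3],[3,0]]; same enumeration
        # as the 3/0/0/3 Fisher table
        assert result.p_value == pytest.approx(0.1)
        assert result.medians == (2.0, 11.0)

    def test_constant_pooled_data_is_degenerate(self, caplog):
        with caplog.at_level(logging.WARNING):
            result = moods_median_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert result.p_value == 1.0
        assert "degenerate" in result.note

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            moods_median_test([], [1.0])

    def test_chi2_backend_matches_scipy_median_test(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.7, 1, 55)
        ours = moods_median_test(x, y, backend="chi2")
        stat, p, _, _ = scipy_median_test(x, y, ties="below", correction=False)
        assert ours.statistic == pytest.approx(stat)
        assert ours.p_value == pytest.approx(p)

    # values rounded to 3 decimals so every transform stays injective in
    # floating point (no underflow-induced ties)
    @given(
        st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)),
                 min_size=3, max_size=25),
        st.lists(st.floats(-50, 50).map(lambda v: round(v, 3)),
                 min_size=3, max_size=25),
    )
    @settings(deadline=None, max_examples=60)
    def test_invariant_under_strictly_monotone_transforms(self, x, y):
        base = moods_median_test(x, y).p_value
        for transform in (
            lambda v: 3.0 * v + 7.0,
            lambda v: v ** 3,
            lambda v: math.atan(v),
        ):
            tx = [transform(v) for v in x]
            ty = [transform(v) for v in y]
            assert moods_median_test(tx, ty).p_value == pytest.approx(base)

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 400)
        y = rng.normal(1.5, 1.0, 400)
        assert moods_median_test(x, y).p_value < 1e-10


@pytest.fixture(scope="module")
def toy_impact_inputs():
    config = SimulationConfig(
        seed=13, genes=("F8",), n_species=10, seq_length=150,
        n_variants=60, cpd_fraction=0.4,
    )
    alignments, truth = gen_msa(config)
    variants, props = gen_variant_and_property_tables(config, truth)
    calls = classify_dataset(variants, alignments)
    return alignments, truth, variants, props, calls


class TestBuildImpactTable:
    def test_composes_blosum_entropy_and_property_join(self, fviii_toy_alignment):
        variants = pd.DataFrame(
            [{"gene": "F8", "wt": "L", "pos": 69, "mut": "V",
              "severity": "mild", "pathogenicity": "pathogenic"}]
        )
        props = pd.DataFrame(
            [{"gene": "F8", "wt": "L", "pos": 69, "mut": "V",
              "ddg": 1.2, "rsa": 30.0}]
        )
        calls = classify_dataset(variants, {"F8": fviii_toy_alignment})
        records = build_impact_table(calls, props, {"F8": fviii_toy_alignment})
        row = records.iloc[0]
        assert row.blosum == 1  # published BLOSUM62 L<->V element
        # column holds L (human, pig) and V (chimp, mouse, rat): p = (2/5, 3/5)
        expected_entropy = -(0.4 * math.log2(0.4) + 0.6 * math.log2(0.6))
        assert row.entropy == pytest.approx(expected_entropy)
        assert row.ddg == pytest.approx(1.2)
        assert row.rsa == pytest.approx(30.0)

    def test_missing_property_rows_left_absent(self, fviii_toy_alignment):
        variants = pd.DataFrame(
            [{"gene": "F8", "wt": "L", "pos": 69, "mut": "V",
              "severity": "mild", "pathogenicity": "pathogenic"}]
        )
        calls = classify_dataset(variants, {"F8": fviii_toy_alignment})
        records = build_impact_table(calls, None, {"F8": fviii_toy_alignment})
        assert records["ddg"].isna().all()
        assert records["rsa"].isna().all()

    def test_empty_call_list(self, fviii_toy_alignment):
        records = build_impact_table([], None, {"F8": fviii_toy_alignment})
        assert len(records) == 0

    def test_entropy_bounds_on_generated_data(self, toy_impact_inputs):
        alignments, _, _, props, calls = toy_impact_inputs
        records = build_impact_table(calls, props, alignments)
        assert records["entropy"].between(0, math.log2(20) + 1e-9).all()
        assert records["rsa"].between(0, 100).all()


class TestGroupComparisons:
    def test_configured_ddg_shift_detected_with_correct_direction(self):
        rng = np.random.default_rng(42)
        n_cpd, n_nocpd = 120, 850
        records = pd.DataFrame(
            {
                "is_cpd": [True] * n_cpd + [False] * n_nocpd,
                "wt_check": "match",
                "severity": "unknown",
                "ddg": np.concatenate(
                    [rng.normal(0.5, 0.8, n_cpd), rng.normal(1.8, 1.2, n_nocpd)]
                ),
            }
        )
        result = compare_cpd_vs_nocpd(records, "ddg")
        assert result.p_value < 1e-3
        assert result.medians[0] < result.medians[1]
        assert result.group_sizes == (n_cpd, n_nocpd)

    def test_group_emptied_by_missing_values(self):
        records = pd.DataFrame(
            {
                "is_cpd": [True, True, False, False, False],
                "wt_check": "match",
                "severity": "unknown",
                "ddg": [np.nan, 1.0, 0.5, 0.7, 0.9],
            }
        )
        with pytest.raises(InsufficientDataError):
            compare_cpd_vs_nocpd(records, "ddg")

    def test_mild_vs_severe_on_generated_cpds(self, toy_impact_inputs):
        alignments, truth, _, props, calls = toy_impact_inputs
        records = build_impact_table(calls, props, alignments)
        result = compare_mild_vs_severe(records, "ddg")
        # severity is coupled to ddg through the logistic model: the severe
        # group should sit at higher stability changes
        assert result.medians[0] <= result.medians[1]

    def test_all_mild_raises(self):
        records = pd.DataFrame(
            {
                "is_cpd": [True] * 4,
                "wt_check": "match",
                "severity": "mild",
                "ddg": [0.1, 0.2, 0.3, 0.4],
            }
        )
        with pytest.raises(InsufficientDataError):
            compare_mild_vs_severe(records, "ddg")

    def test_null_rejection_rate_is_calibrated(self):
        """With both groups drawn from the same distribution the exact
        Mood's test rejects at alpha = 0.05 no more often than nominal
        (binomial check over 200 simulations)."""
        rng = np.random.default_rng(314159)
        rejections = sum(
            moods_median_test(rng.normal(0, 1, 60), rng.normal(0, 1, 60)).p_value
            < 0.05
            for _ in range(200)
        )
        # conservative exact test: between 0 and the upper binomial bound
        assert rejections <= 0.05 * 200 + 3 * math.sqrt(200 * 0.05 * 0.95)


class TestOverlapFraction:
    def test_direct_count(self):
        assert overlap_fraction([5], [1, 2, 3, 10]) == pytest.approx(75.0)

    def test_self_overlap_is_about_half(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=20001)
        assert overlap_fraction(a, a) == pytest.approx(50.0, abs=1.0)

    def test_matches_analytic_cdf(self):
        """For a ~ N(0,1) and b ~ N(1,1), the fraction of b below median(a)
        tends to Phi(-1) ~ 15.9%."""
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, 40000)
        b = rng.normal(1, 1, 40000)
        expected = 100 * norm.cdf(-1)
        assert overlap_fraction(a, b) == pytest.approx(expected, abs=1.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            overlap_fraction([], [1.0])
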