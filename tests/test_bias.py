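"""Homoeolog-bias classification and the nine-category summary."""

import numpy as np
import pytest

from polyeld.bias import (BIAS_CATEGORIES, CATEGORY_ORDER, classify_pair,
                          classify_pairs, homoeolog_contrast, legacy_of,
                          summarize_bias)
from polyeld.containers import GeneModel


class TestPairCategory:
    @pytest.mark.parametrize("parent, hybrid, category", [
        ("+", "+", "maintained_A_bias"),
        ("-", "-", "maintained_C_bias"),
        ("+", "0", "lost_A_bias"),
        ("0", "-", "novel_C_bias"),
        ("0", "0", "parental_equal"),
        ("+", "-", "reversed_to_C"),
    ])
    def test_nine_way_mapping(self, parent, hybrid, category):
        assert classify_pair(parent, hybrid) == category

    def test_mapping_is_total_and_injective(self):
        assert len(BIAS_CATEGORIES) == 9
        assert len(set(BIAS_CATEGORIES.values())) == 9

    def test_legacy_labels(self):
        assert legacy_of("maintained_A_bias") == "maintained"
        assert legacy_of("parental_equal") == "none"
        assert legacy_of("reversed_to_C") == "reversed"

    def test_invalid_sign(self):
        with pytest.raises(ValueError):
            classify_pair("x", "0")


class TestHomoeologContrast:
    def test_symmetric_null(self):
        assert homoeolog_contrast(50, 1000, 1e6, 50, 1000, 1e6) == 0

    def test_length_normalization_cancels(self):
        # A copy twice as long with twice the count: no bias after adjustment
        assert homoeolog_contrast(100, 2000, 1e6, 50, 1000, 1e6) == 0

    def test_both_zero_is_sign_zero(self):
        assert homoeolog_contrast(0, 1000, 1e6, 0, 1000, 1e6) == 0

    def test_strong_bias_detected(self):
        assert homoeolog_contrast(4000, 1000, 1e6, 500, 1000, 1e6) == 1

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            homoeolog_contrast(1, 0, 1e6, 1, 1000, 1e6)


class TestClassifyPairs:
    def test_planted_novel_bias_direction_recovered(self, planted_dataset):
        counts, genes, truth = planted_dataset
        calls = classify_pairs(counts, genes, "AA1", "CC", "AC1")
        truth = truth.set_index("gene_id")
        planted = truth[(truth["true_class"] == "novel_bias")
                        & truth.index.isin(calls.index)]
        a_planted = planted[planted["true_bias"] == "A_bias"].index
        c_planted = planted[planted["true_bias"] == "C_bias"].index
        assert (calls.loc[a_planted, "hybrid_sign"] == 1).mean() >= 0.9
        assert (calls.loc[c_planted, "hybrid_sign"] == -1).mean() >= 0.9

    def test_label_swap_exchanges_bias_totals(self, planted_dataset):
        counts, genes, _ = planted_dataset
        calls = classify_pairs(counts, genes, "AA1", "CC", "AC1")
        swapped_genes = [
            GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand,
                      {"A": "C", "C": "A"}[g.subgenome], g.partner_id)
            for g in genes
        ]
        swapped = classify_pairs(counts, swapped_genes, "CC", "AA1", "AC1")
        t1 = summarize_bias(calls)
        t2 = summarize_bias(swapped)
        assert t1["overall_A_bias"] == t2["overall_C_bias"]
        assert t1["overall_C_bias"] == t2["overall_A_bias"]
        assert t1["category_counts"]["novel_A_bias"] == \
            t2["category_counts"]["novel_C_bias"]
        assert t1["total_pairs"] == t2["total_pairs"]

    def test_null_pairs_mostly_parental_equal(self, null_dataset):
        counts, genes, _ = null_dataset
        calls = classify_pairs(counts, genes, "AA1", "CC", "AC1")
        frac = (calls["category"] == "parental_equal").mean()
        assert frac >= 0.95 ** 2

    def test_universe_flag(self, planted_dataset):
        counts, genes, _ = planted_dataset
        either = classify_pairs(counts, genes, "AA1", "CC", "AC1",
                                universe="either")
        strict = classify_pairs(counts, genes, "AA1", "CC", "AC1",
                                universe="all-samples")
        assert len(strict) <= len(either)
        with pytest.raises(ValueError):
            classify_pairs(counts, genes, "AA1", "CC", "AC1",
                           universe="bogus")


class TestSummarize:
    def test_categories_partition_and_percentages(self, planted_dataset):
        counts, genes, _ = planted_dataset
        calls = classify_pairs(counts, genes, "AA1", "CC", "AC1")
        table = summarize_bias(calls)
        assert sum(table["category_counts"].values()) == table["total_pairs"]
        assert abs(sum(table["category_percent"].values()) - 100) <= \
            0.05 * len(CATEGORY_ORDER)
        # overall bias composition
        c = table["category_counts"]
        assert table["overall_A_bias"] == c["maintained_A_bias"] + \
            c["novel_A_bias"] + c["reversed_to_A"]
        assert table["overall_C_bias"] == c["maintained_C_bias"] + \
            c["novel_C_bias"] + c["reversed_to_C"]

    def test_shared_column_with_second_hybrid(self, planted_dataset):
        counts, genes, _ = planted_dataset
        c1 = classify_pairs(counts, genes, "AA1", "CC", "AC1")
        table = summarize_bias(c1, other_hybrid_calls=c1)
        assert table["shared_pairs"] == len(c1)
        assert sum(table["shared_same_category"].values()) == len(c1)

    def test_empty_calls_rejected(self, planted_dataset):
        counts, genes, _ = planted_dataset
        calls = classify_pairs(counts, genes, "AA1", "CC", "AC1")
        with pytest.raises(ValueError):
            summarize_bias(calls.iloc[0:0])
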