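"""Enrichment, rank tests, AUC, stratification and ECDF export."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from spatialmtr import (
    LabeledScore,
    filter_clinical_variants,
    intolerance_enrichment,
    mann_whitney_u,
    pearson_correlation,
    plddt_stratify,
    roc_auc,
    two_proportion_z,
)
from spatialmtr.validation import ecdf_export, enrichment_from_counts


def labeled(scores, label, **kw):
    return [LabeledScore(score=s, label=label, **kw) for s in scores]


class TestFilterClinicalVariants:
    def test_low_stars_dropped(self):
        assert filter_clinical_variants([LabeledScore(0.5, "benign", stars=1)]) == []

    def test_clean_missense_kept(self):
        rec = LabeledScore(0.5, "benign", stars=2, conflicting=False)
        assert filter_clinical_variants([rec]) == [rec]

    def test_mixed_table_matches_predicate_oracle(self):
        rng = np.random.default_rng(0)
        records = [
            LabeledScore(
                score=float(rng.uniform(0, 2)),
                label="pathogenic" if rng.random() < 0.5 else "benign",
                stars=int(rng.integers(0, 5)),
                conflicting=bool(rng.random() < 0.3),
                consequence="missense" if rng.random() < 0.7 else "synonymous",
            )
            for _ in range(20)
        ]
        got = filter_clinical_variants(records)
        want = [
            r for r in records
            if r.consequence == "missense" and r.stars >= 2 and not r.conflicting
        ]
        assert got == want


class TestIntoleranceEnrichment:
    def test_tenfold_enrichment(self):
        data = (
            labeled([0.1] * 20 + [0.9] * 80, "pathogenic")
            + labeled([0.1] * 2 + [0.9] * 98, "benign")
        )
        assert intolerance_enrichment(data).fold_change == pytest.approx(10.0)

    def test_large_cohort_contingency(self):
        # 287/13,886 benign and 1,220/7,186 pathogenic intolerant
        enr = enrichment_from_counts(1220, 7186, 287, 13886)
        assert round(enr.pathogenic_pct, 2) == 16.98
        assert round(enr.benign_pct, 2) == 2.07
        assert round(enr.fold_change, 2) == 8.21

    def test_no_pathogenic_below_threshold(self):
        data = labeled([0.9] * 10, "pathogenic") + labeled(
            [0.1] * 2 + [0.9] * 8, "benign"
        )
        assert intolerance_enrichment(data).fold_change == 0.0

    def test_no_benign_below_threshold_is_inf(self):
        data = labeled([0.1] * 5 + [0.9] * 5, "pathogenic") + labeled(
            [0.9] * 10, "benign"
        )
        assert intolerance_enrichment(data).fold_change == math.inf

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            intolerance_enrichment(labeled([0.5] * 5, "benign"))

    def test_empty_both_cells_is_undefined(self):
        data = labeled([0.9] * 5, "pathogenic") + labeled([0.9] * 5, "benign")
        assert math.isnan(intolerance_enrichment(data).fold_change)

    def test_invariant_to_dataset_duplication(self):
        data = (
            labeled([0.2, 0.4, 0.9], "pathogenic")
            + labeled([0.3, 0.8, 0.9, 1.1], "benign")
        )
        assert (
            intolerance_enrichment(data).fold_change
            == intolerance_enrichment(data + data).fold_change
        )


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_proportion_z(5, 50, 10, 100)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        z, p = two_proportion_z(20, 100, 2, 100)
        # independent direct computation of the pooled statistic
        p1, p2, pooled = 0.20, 0.02, 22 / 200
        se = math.sqrt(pooled * (1 - pooled) * (1 / 100 + 1 / 100))
        from scipy.stats import norm

        assert z == pytest.approx((p1 - p2) / se, abs=1e-6)
        assert p == pytest.approx(2 * norm.sf(abs((p1 - p2) / se)), abs=1e-6)

    def test_swapping_groups_negates_z(self):
        z1, p1 = two_proportion_z(20, 100, 2, 100)
        z2, p2 = two_proportion_z(2, 100, 20, 100)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion_flagged(self):
        z, p = two_proportion_z(0, 10, 0, 10)
        assert math.isnan(z) and math.isnan(p)


def permutation_p_value(a, b):
    """Exact two-sided permutation test on the rank-sum statistic."""
    from scipy.stats import rankdata

    pooled = np.array(list(a) + list(b))
    n_a = len(a)

    def u_stat(indices_a):
        ranks = rankdata(pooled)
        ra = ranks[list(indices_a)].sum()
        return ra - n_a * (n_a + 1) / 2

    observed = abs(u_stat(range(n_a)) - len(a) * len(b) / 2)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        # permute labels: U for this assignment
        ranks = rankdata(pooled)
        ra = ranks[list(combo)].sum()
        u = abs(ra - n_a * (n_a + 1) / 2 - len(a) * len(b) / 2)
        count += u >= observed - 1e-9
        total += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_lists_p_near_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_permutation_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=6)
        b = rng.normal(0.8, 1, size=6)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(permutation_p_value(a, b), abs=0.01)

    def test_normal_approximation_close_to_exact_boundary(self):
        # same data through both methods at moderate n stay within 0.01
        rng = np.random.default_rng(5)
        a = list(rng.normal(0, 1, size=12))
        b = list(rng.normal(0.5, 1, size=12))
        from scipy.stats import mannwhitneyu

        p_exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        p_asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p_exact == pytest.approx(p_asym, abs=0.01)


class TestRocAuc:
    def test_perfect_separation_low_scores_pathogenic(self):
        data = labeled([0.1, 0.2], "pathogenic") + labeled([0.8, 0.9], "benign")
        assert roc_auc(data) == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(0, 1, size=4000)
        lab = rng.random(4000) < 0.5
        data = [
            LabeledScore(float(s), "pathogenic" if l else "benign")
            for s, l in zip(scores, lab)
        ]
        assert roc_auc(data) == pytest.approx(0.5, abs=0.05)

    def test_matches_trapezoidal_integration_oracle(self):
        rng = np.random.default_rng(7)
        path = rng.normal(0.4, 0.3, size=100)
        ben = rng.normal(0.9, 0.3, size=100)
        data = labeled(path, "pathogenic") + labeled(ben, "benign")
        y = [1] * 100 + [0] * 100
        # geometric oracle: trapezoidal ROC integration on the negated score
        want = roc_auc_score(y, [-s.score for s in data])
        assert roc_auc(data) == pytest.approx(want, abs=1e-12)

    def test_ties_counted_half(self):
        data = labeled([0.5], "pathogenic") + labeled([0.5], "benign")
        assert roc_auc(data) == 0.5

    def test_label_swap_complement(self):
        rng = np.random.default_rng(8)
        data = labeled(rng.normal(0.4, 0.2, 50), "pathogenic") + labeled(
            rng.normal(0.8, 0.2, 60), "benign"
        )
        swapped = [
            LabeledScore(r.score, "benign" if r.label == "pathogenic" else "pathogenic")
            for r in data
        ]
        assert roc_auc(data) + roc_auc(swapped) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(labeled([0.5, 0.6], "benign"))


class TestPlddtStratify:
    def test_band_membership(self):
        recs = [
            LabeledScore(0.5, "benign", plddt=90.0),
            LabeledScore(0.5, "benign", plddt=60.0),
            LabeledScore(0.5, "benign", plddt=30.0),
        ]
        bands = plddt_stratify(recs)
        assert [len(bands[b]) for b in ("high", "medium", "low")] == [1, 1, 1]

    def test_boundaries_fall_in_medium(self):
        recs = [
            LabeledScore(0.5, "benign", plddt=70.0),
            LabeledScore(0.5, "benign", plddt=50.0),
        ]
        bands = plddt_stratify(recs)
        assert len(bands["medium"]) == 2

    def test_partition_sizes_sum(self):
        rng = np.random.default_rng(4)
        recs = [
            LabeledScore(0.5, "benign", plddt=float(p))
            for p in rng.uniform(0, 100, size=57)
        ]
        bands = plddt_stratify(recs)
        assert sum(len(v) for v in bands.values()) == 57

    def test_out_of_range_plddt_rejected(self):
        with pytest.raises(ValueError):
            plddt_stratify([LabeledScore(0.5, "benign", plddt=120.0)])


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        y = 0.3 * x + rng.normal(size=100)
        want = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_correlation(x, y) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEcdf:
    def test_step_heights(self):
        data = labeled([0.2, 0.4, 0.4, 1.0], "benign") + labeled([0.5], "pathogenic")
        tables = ecdf_export(data)
        ben = tables["benign"]
        assert list(ben["score"]) == [0.2, 0.4, 1.0]
        assert list(ben["cum_fraction"]) == pytest.approx([0.25, 0.75, 1.0])

    def test_single_point(self):
        tables = ecdf_export(labeled([0.7], "pathogenic"))
        assert list(tables["pathogenic"]["cum_fraction"]) == [1.0]

    def test_final_fraction_is_one_per_class(self):
        rng = np.random.default_rng(9)
        data = labeled(rng.uniform(0, 2, 30), "pathogenic") + labeled(
            rng.uniform(0, 2, 40), "benign"
        )
        for table in ecdf_export(data).values():
            assert table["cum_fraction"].iloc[-1] == pytest.approx(1.0)
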