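"""Density estimation, subject-variability AUROC, classification and MI."""

import numpy as np
import pandas as pd
import pytest

from neuroacw.classify import (
    cp_classification,
    mutual_information_score,
    variability_split_auroc,
)
from neuroacw.density import bimodality_report, estimate_density, minmax_scale


class TestMinmaxScale:
    def test_scales_to_unit_interval(self):
        np.testing.assert_allclose(minmax_scale([2, 4, 6]), [0.0, 0.5, 1.0])

    def test_endpoints_are_exact(self):
        scaled = minmax_scale(np.random.default_rng(0).normal(size=100))
        assert scaled.min() == 0.0 and scaled.max() == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_scale(np.full(5, 2.0))


class TestDensity:
    def test_normal_sample_is_unimodal_with_unit_integral(self):
        values = np.random.default_rng(0).normal(size=10_000)
        estimate = estimate_density(values)
        assert estimate.integral() == pytest.approx(1.0, abs=0.02)
        assert estimate.n_modes() == 1

    def test_separated_clusters_yield_two_modes(self):
        rng = np.random.default_rng(1)
        values = np.r_[rng.normal(0, 1, 4000), rng.normal(8, 1, 4000)]
        estimate = estimate_density(values)
        assert estimate.n_modes() == 2
        assert estimate.integral() == pytest.approx(1.0, abs=0.02)

    def test_integral_near_one_for_heterogeneous_inputs(self):
        rng = np.random.default_rng(2)
        for values in (
            rng.exponential(size=500),
            rng.uniform(size=200),
            rng.standard_t(3, size=1000),
        ):
            assert estimate_density(values).integral() == pytest.approx(1.0, abs=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.arange(5.0))

    def test_bimodality_report_discriminates(self):
        rng = np.random.default_rng(3)
        bimodal = np.r_[rng.normal(0, 1, 2000), rng.normal(7, 1, 2000)]
        unimodal = rng.normal(size=4000)
        assert bimodality_report(bimodal)["bimodal"]
        assert not bimodality_report(unimodal)["bimodal"]


class TestVariabilityAuroc:
    @staticmethod
    def series(values):
        return pd.Series(values, index=[f"sub{i:02d}" for i in range(len(values))])

    def test_task_identical_to_rest_is_perfectly_separable(self):
        rest = self.series(np.linspace(50, 150, 20))
        assert variability_split_auroc(rest, rest.copy()) == pytest.approx(1.0)

    def test_independent_task_values_are_chance_level(self):
        rng = np.random.default_rng(0)
        rest = self.series(rng.normal(100, 10, 200))
        task = self.series(rng.normal(100, 10, 200))
        assert variability_split_auroc(rest, task) == pytest.approx(0.5, abs=0.08)

    def test_invariant_to_monotone_transform_of_task_values(self):
        rng = np.random.default_rng(1)
        rest = self.series(rng.normal(100, 10, 40))
        task = self.series(rest.to_numpy() + rng.normal(0, 5, 40))
        direct = variability_split_auroc(rest, task)
        warped = variability_split_auroc(rest, np.exp(task / 50.0))
        assert direct == pytest.approx(warped, abs=1e-9)

    def test_too_few_subjects_rejected(self):
        rest = self.series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            variability_split_auroc(rest, rest)


class TestCpClassification:
    @staticmethod
    def samples(n_per_class, gap, seed=0):
        rng = np.random.default_rng(seed)
        features = pd.DataFrame(
            {
                "acw50_ms": np.r_[
                    rng.normal(10, 1, n_per_class), rng.normal(10 + gap, 1, n_per_class)
                ],
                "acw0_ms": np.r_[
                    rng.normal(80, 10, n_per_class),
                    rng.normal(80 + 10 * gap, 10, n_per_class),
                ],
            }
        )
        labels = np.r_[["periphery"] * n_per_class, ["core"] * n_per_class]
        return features, labels

    @pytest.mark.parametrize("classifier", ["logistic", "svm_rbf"])
    def test_separated_classes_classified_perfectly(self, classifier):
        features, labels = self.samples(100, gap=20.0)
        report = cp_classification(features, labels, classifier=classifier)
        assert report.accuracy == pytest.approx(100.0)
        assert report.auroc == pytest.approx(100.0)
        assert report.n_folds == 20

    def test_label_independent_features_are_chance_level(self):
        features, labels = self.samples(1000, gap=0.0)
        report = cp_classification(features, labels, classifier="logistic")
        assert report.auroc == pytest.approx(50.0, abs=7.0)

    def test_fold_assignment_is_seed_stable(self):
        features, labels = self.samples(60, gap=1.0)
        a = cp_classification(features, labels, seed=5)
        b = cp_classification(features, labels, seed=5)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)

    def test_single_class_rejected(self):
        features, _ = self.samples(30, gap=0.0)
        with pytest.raises(ValueError, match="classes"):
            cp_classification(features, ["core"] * len(features))


class TestMutualInformation:
    def test_independent_feature_scores_near_zero(self):
        rng = np.random.default_rng(0)
        score = mutual_information_score(
            rng.normal(size=5000), rng.integers(0, 2, 5000)
        )
        assert score < 0.02

    def test_label_plus_tiny_noise_approaches_label_entropy(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 5000)
        feature = labels + rng.normal(0, 1e-3, 5000)
        score = mutual_information_score(feature, labels)
        assert score == pytest.approx(np.log(2), abs=0.05)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            mutual_information_score(np.arange(60.0), np.zeros(60))
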