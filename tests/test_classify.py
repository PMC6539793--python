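"""Fisher LDA, LOOCV, sub-sample-trained validation, confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from glycomark.classify import (
    confusion_metrics,
    fit_lda,
    generate_training_patterns,
    loocv,
    subsample_validate,
)
from glycomark.quantify import CASE_LABEL, CONTROL_LABEL, FeatureTable
from glycomark.synthdata import CohortConfig, generate_cohort


def make_table(X, y):
    n = len(y)
    ids = [f"s{i}" for i in range(n)]
    groups = pd.Series(
        [CASE_LABEL if v else CONTROL_LABEL for v in y], index=ids
    )
    return FeatureTable(pd.DataFrame(np.asarray(X), index=ids), groups)


class TestFitLda:
    def test_separated_1d_classes(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(10, 1, 50), rng.normal(0, 1, 50)])[:, None]
        y = np.arange(100) < 50
        model = fit_lda(X, y)
        assert model.weights[0] > 0
        assert (model.predict(X) == y).mean() >= 0.99

    def test_identical_means_chance_level(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 2))
        y = np.arange(200) < 100
        model = fit_lda(X, y)
        assert 0.35 <= (model.predict(X) == y).mean() <= 0.65

    def test_diagonal_covariance_closed_form(self):
        # with diagonal pooled covariance, w_i is mean-difference / variance
        rng = np.random.default_rng(2)
        n = 20000
        sd = np.array([1.0, 2.0])
        delta = np.array([1.0, 3.0])
        Xc = rng.normal(0, 1, size=(n, 2)) * sd + delta
        Xn = rng.normal(0, 1, size=(n, 2)) * sd
        X = np.vstack([Xc, Xn])
        y = np.arange(2 * n) < n
        model = fit_lda(X, y)
        expected = delta / sd**2
        ratio = model.weights / expected
        assert ratio[0] == pytest.approx(ratio[1], rel=0.05)

    def test_matches_sklearn_direction(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        y = np.arange(60) < 30
        X[y] += [0.5, 0.2, -0.3, 1.0]
        ours = fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5]).fit(X, y)
        # same direction up to positive scale
        cos = ours.weights @ sk.coef_[0] / (
            np.linalg.norm(ours.weights) * np.linalg.norm(sk.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_ridge_fallback_on_singular_covariance(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(20)
        X = np.column_stack([base, base])  # rank-1 pooled covariance
        y = np.arange(20) < 10
        X[y] += 2.0
        model = fit_lda(X, y)
        assert model.ridged

    def test_recovers_planted_discriminant_direction(self):
        rng = np.random.default_rng(5)
        d = 5
        direction = np.array([1.0, -0.5, 0.25, 0.0, 2.0])
        n = 200
        Xc = rng.standard_normal((n, d)) + direction
        Xn = rng.standard_normal((n, d))
        model = fit_lda(np.vstack([Xc, Xn]), np.arange(2 * n) < n)
        cos = model.weights @ direction / (
            np.linalg.norm(model.weights) * np.linalg.norm(direction)
        )
        assert cos > 0.9

    def test_rejects_tiny_class(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((3, 2)), np.array([True, False, False]))


class TestLoocv:
    def test_separable_cohort_is_perfect(self):
        rng = np.random.default_rng(6)
        Xc = rng.normal(20, 1, size=(20, 3))
        Xn = rng.normal(5, 1, size=(18, 3))
        table = make_table(np.vstack([Xc, Xn]), np.arange(38) < 20)
        report = loocv(table)
        assert report.accuracy == 100.0
        assert (report.tp, report.tn) == (20, 18)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(7)
        table, _ = generate_cohort(CohortConfig(seed=77))
        X = np.log(table.abundances.iloc[:, :5])
        accs = []
        for _ in range(30):
            y = rng.permutation(table.case_mask)
            accs.append(loocv(X, y=y).accuracy)
        assert 35 <= np.mean(accs) <= 65

    def test_permutation_consistency(self, cohort):
        table, _ = cohort
        sub = list(table.abundances.columns[:6])
        base = loocv(table, sub)
        rng = np.random.default_rng(8)
        order = rng.permutation(table.abundances.index)
        shuffled = FeatureTable(
            table.abundances.loc[order],
            table.groups.loc[order],
            table.protein_conc.loc[order],
        )
        other = loocv(shuffled, sub)
        assert (base.tp, base.fp, base.tn, base.fn) == (
            other.tp,
            other.fp,
            other.tn,
            other.fn,
        )

    def test_rejects_tiny_cohort(self):
        table = make_table(np.zeros((3, 1)), [True, True, False])
        with pytest.raises(ValueError):
            loocv(table)


class TestSubsampleTraining:
    def test_shared_fraction_invariant_holds(self, cohort):
        table, _ = cohort
        sub = list(table.abundances.columns[:10])
        training = generate_training_patterns(table, sub, n_per_class=50, seed=9)
        X = table.abundances[sub].to_numpy()
        d = len(sub)
        for vec in training.X:
            shared = (X == vec).sum(axis=1) / d
            assert shared.max() < 0.25

    def test_balanced_and_deterministic(self, cohort):
        table, _ = cohort
        a = generate_training_patterns(table, n_per_class=20, seed=10)
        b = generate_training_patterns(table, n_per_class=20, seed=10)
        assert np.array_equal(a.X, b.X)
        assert a.y.sum() == 20 and (~a.y).sum() == 20

    def test_no_rejections_when_unconstrained(self, cohort):
        table, _ = cohort
        t = generate_training_patterns(table, n_per_class=10, max_shared=1.0, seed=11)
        assert t.X.shape == (20, 42)

    def test_values_come_from_class_pools(self, cohort):
        table, _ = cohort
        sub = list(table.abundances.columns[:4])
        training = generate_training_patterns(table, sub, n_per_class=30, seed=12)
        case_pool = table.abundances[sub].to_numpy()[table.case_mask]
        for j in range(len(sub)):
            assert np.isin(training.X[training.y, j], case_pool[:, j]).all()

    def test_unsatisfiable_constraint_diagnosed(self):
        # identical rows within each class: every draw reproduces the class
        # prototype, sharing 100% of its values with an original
        X = np.vstack([np.tile([1.0] * 8, (4, 1)), np.tile([2.0] * 8, (4, 1))])
        table = make_table(X, np.arange(8) < 4)
        with pytest.raises(RuntimeError, match="degenerate"):
            generate_training_patterns(table, n_per_class=2, seed=13, max_tries=20)

    def test_constraint_disabled_for_tiny_feature_sets(self, cohort):
        # with d <= 4 the 25% limit permits no matches at all; the generator
        # warns and proceeds unconstrained instead of failing
        table, _ = cohort
        sub = list(table.abundances.columns[:2])
        with pytest.warns(UserWarning, match="constraint disabled"):
            t = generate_training_patterns(table, sub, n_per_class=5, seed=1)
        assert t.X.shape == (10, 2)


class TestSubsampleValidate:
    def test_separable_cohort_high_accuracy(self):
        rng = np.random.default_rng(14)
        Xc = rng.normal(20, 1, size=(20, 3))
        Xn = rng.normal(5, 1, size=(18, 3))
        table = make_table(np.vstack([Xc, Xn]), np.arange(38) < 20)
        loo = loocv(table)
        sub = subsample_validate(table, seed=15)
        assert sub.accuracy >= loo.accuracy - 10

    def test_overlapping_single_feature_chance(self):
        rng = np.random.default_rng(16)
        X = rng.normal(10, 1, size=(40, 1))
        table = make_table(X, np.arange(40) < 20)
        report = subsample_validate(table, seed=17)
        assert 30 <= report.accuracy <= 70


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((17, 0, 18, 3), (92.11, 100.0, 85.0)),
            ((15, 2, 16, 5), (81.58, 88.89, 75.0)),
            ((15, 1, 17, 5), (84.21, 94.44, 75.0)),
            ((20, 0, 18, 0), (100.0, 100.0, 100.0)),
        ],
    )
    def test_percentages(self, counts, expected):
        assert confusion_metrics(*counts) == expected

    def test_rejects_empty_class(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 5, 0)
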