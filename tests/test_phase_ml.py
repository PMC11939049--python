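"""Splits, SMOTE oversampling, grid search, evaluation, and Shapley grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.ensemble import RandomForestClassifier

from pepmine.dataset_model import PeptideRecord
from pepmine.encoding import FeatureGroupMap
from pepmine.phase_ml import (
    GridSearchSpec,
    SplitSpec,
    evaluate,
    grid_search_fit,
    group_attributions,
    make_splits,
    oversample_train,
    publication_leakage,
    random_baseline,
    shapley_attributions,
)


def _records(n, n_pubs, phase_cycle=("fiber", "hydrogel")):
    return [
        PeptideRecord(
            sequence="FF",
            phase=phase_cycle[i % len(phase_cycle)],
            concentration=1.0 + i,
            source_id=f"p{i % n_pubs}",
        )
        for i in range(n)
    ]


class TestSplits:
    def test_random_split_sizes_on_n1012(self):
        records = _records(1012, 75)
        tr, va, te = make_splits(records, SplitSpec(mode="random", seed=5))
        assert (len(tr), len(va), len(te)) == (607, 152, 253)

    def test_publication_split_counts_on_75_papers(self):
        records = _records(1012, 75)
        tr, va, te = make_splits(records, SplitSpec(mode="by_publication", seed=5))
        pubs = lambda idx: {records[i].source_id for i in idx}
        assert (len(pubs(tr)), len(pubs(va)), len(pubs(te))) == (45, 11, 19)
        assert publication_leakage(records, [tr, va, te]) == 0

    @given(n=st.integers(10, 300), seed=st.integers(0, 50))
    def test_partitions_disjoint_and_exhaustive(self, n, seed):
        records = _records(n, max(2, n // 10))
        for mode in ("random", "by_publication"):
            tr, va, te = make_splits(records, SplitSpec(mode=mode, seed=seed))
            combined = np.concatenate([tr, va, te])
            assert len(combined) == n
            assert set(combined) == set(range(n))
            if mode == "by_publication":
                assert publication_leakage(records, [tr, va, te]) == 0

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.8, -0.1, 0.3))


def on_segment(s, A, tol=1e-9):
    """Oracle: does s lie on the segment between some pair of rows of A?"""
    for i in range(len(A)):
        for j in range(len(A)):
            if i == j:
                continue
            a, b = A[i], A[j]
            d = b - a
            mask = np.abs(d) > tol
            if not mask.any():
                if np.allclose(s, a, atol=tol):
                    return True
                continue
            u = (s[mask] - a[mask]) / d[mask]
            if np.ptp(u) < 1e-6 and -1e-9 <= u[0] <= 1 + 1e-9:
                if np.allclose(a + u[0] * d, s, atol=1e-8):
                    return True
    return False


class TestSmote:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = np.vstack(
            [rng.normal(0, 1, (10, 4)), rng.normal(5, 1, (4, 4))]
        )
        self.y = np.array(["A"] * 10 + ["B"] * 4)

    def test_full_balance_counts(self):
        Xo, yo = oversample_train(self.X, self.y, seed=1)
        assert (yo == "A").sum() == 10 and (yo == "B").sum() == 10

    def test_originals_unchanged_and_prefixed(self):
        Xo, yo = oversample_train(self.X, self.y, seed=1)
        assert np.array_equal(Xo[: len(self.X)], self.X)
        assert np.array_equal(yo[: len(self.y)], self.y)

    def test_synthetic_rows_lie_on_same_class_segments(self):
        Xo, yo = oversample_train(self.X, self.y, seed=1)
        originals_B = self.X[self.y == "B"]
        for s in Xo[len(self.X) :]:
            assert on_segment(s, originals_B)

    def test_majority_class_untouched(self):
        Xo, yo = oversample_train(self.X, self.y, seed=1)
        assert (yo == "A").sum() == (self.y == "A").sum()

    def test_explicit_strategy(self):
        Xo, yo = oversample_train(self.X, self.y, strategy={"B": 7}, seed=1)
        assert (yo == "B").sum() == 7

    def test_singleton_class_strict_raises(self):
        X = np.vstack([self.X, [[9, 9, 9, 9]]])
        y = np.append(self.y, "C")
        with pytest.raises(ValueError, match="interpolate"):
            oversample_train(X, y, strict=True)
        Xo, yo = oversample_train(X, y, strict=False)  # logged + skipped
        assert (yo == "C").sum() == 1

    def test_determinism(self):
        a = oversample_train(self.X, self.y, seed=3)
        b = oversample_train(self.X, self.y, seed=3)
        assert np.array_equal(a[0], b[0])


class TestGridSearch:
    def _data(self):
        rng = np.random.default_rng(2)
        X = rng.random((120, 6))
        y = np.where(X[:, 0] + X[:, 1] > 1, "fiber", "hydrogel")
        return X, y

    def test_grid_cardinality_and_argmax(self):
        X, y = self._data()
        spec = GridSearchSpec(
            family="rf",
            grid={
                "n_estimators": [10, 30, 50],
                "max_depth": [3, 6, None],
                "min_samples_split": [2, 4, 8],
            },
        )
        model, table = grid_search_fit(X, y, spec, seed=0)
        assert len(table) == 27
        # argmax oracle: the selected cell attains the table maximum
        best_row = table.loc[table["rank"] == 1].iloc[0]
        assert best_row["mean_cv_score"] == table["mean_cv_score"].max()
        fitted_params = model.get_params()
        for axis in spec.resolved_grid():
            assert fitted_params[axis] == best_row[axis] or (
                fitted_params[axis] is None and pd.isna(best_row[axis])
            )

    def test_same_seed_identical_table(self):
        X, y = self._data()
        spec = GridSearchSpec(
            family="knc", grid={"n_neighbors": [3, 5], "weights": ["uniform", "distance"], "p": [1, 2]}
        )
        _, t1 = grid_search_fit(X, y, spec, seed=7)
        _, t2 = grid_search_fit(X, y, spec, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_grid_shape_validation(self):
        with pytest.raises(ValueError, match="3 hyperparameter axes"):
            GridSearchSpec(family="rf", grid={"n_estimators": [1, 2]}).resolved_grid()
        with pytest.raises(ValueError, match="2 candidates"):
            GridSearchSpec(
                family="rf",
                grid={"n_estimators": [10], "max_depth": [1, 2], "min_samples_split": [2, 3]},
            ).resolved_grid()


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 3))
        y = np.where(X[:, 0] > 0.5, "fiber", "hydrogel")
        model = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        res = evaluate(model, X, y)  # training data: perfectly separable
        assert res.precision == res.recall == res.f1 == 1.0
        cm = res.confusion.to_numpy()
        assert np.all(cm == np.diag(np.diag(cm)))

    def test_metrics_recomputed_from_confusion_matrix(self, rule_dataset, rule_encoded):
        matrix, _ = rule_encoded
        tr, va, te = make_splits(rule_dataset, SplitSpec(seed=1))
        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(
            matrix.X[tr], matrix.y[tr]
        )
        res = evaluate(model, matrix.X[te], matrix.y[te])
        cm = res.confusion.to_numpy().astype(float)
        support = cm.sum(axis=1)
        with np.errstate(invalid="ignore"):
            prec = np.nan_to_num(np.diag(cm) / cm.sum(axis=0))
            rec = np.nan_to_num(np.diag(cm) / support)
            f1 = np.nan_to_num(2 * prec * rec / (prec + rec))
        w = support / support.sum()
        assert res.precision == pytest.approx((w * prec).sum())
        assert res.recall == pytest.approx((w * rec).sum())
        assert res.f1 == pytest.approx((w * f1).sum())
        assert res.n_test == len(te)

    def test_confusion_row_sums_equal_class_counts(self, rule_dataset, rule_encoded):
        matrix, _ = rule_encoded
        tr, _, te = make_splits(rule_dataset, SplitSpec(seed=1))
        model = RandomForestClassifier(n_estimators=20, random_state=0).fit(
            matrix.X[tr], matrix.y[tr]
        )
        res = evaluate(model, matrix.X[te], matrix.y[te])
        for phase, row_sum in res.confusion.sum(axis=1).items():
            assert row_sum == (matrix.y[te] == phase).sum()

    def test_empty_test_set_errors(self):
        model = RandomForestClassifier().fit([[0.0], [1.0]], ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, np.empty((0, 1)), np.array([]))


class TestRandomBaseline:
    @pytest.mark.parametrize("n,expected", [(8, 0.125), (2, 0.5), (1, 1.0)])
    def test_values(self, n, expected):
        assert random_baseline(n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            random_baseline(0)


class TestShapley:
    def _fitted(self):
        rng = np.random.default_rng(1)
        X = rng.random((80, 5))
        X[:, 4] = 0.7  # constant feature
        y = np.where(X[:, 0] > 0.5, "fiber", "hydrogel")
        model = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        return model, X

    def test_efficiency_per_record_and_class(self):
        """With a single background row the telescoping sum is exact:
        attributions add up to f(x) - f(background) per record and class."""
        model, X = self._fitted()
        explain, background = X[:6], X[10:11]
        phi = shapley_attributions(model, explain, background, n_permutations=6, seed=0)
        f_x = model.predict_proba(explain)
        f_b = model.predict_proba(background)[0]
        assert np.allclose(phi.sum(axis=1), f_x - f_b, atol=1e-10)

    def test_grouped_sum_equals_raw_sum_exactly(self):
        model, X = self._fitted()
        phi = shapley_attributions(model, X[:4], X[:20], n_permutations=4, seed=0)
        gmap = FeatureGroupMap(spans={"a": (0, 2), "b": (2, 4), "c": (4, 5)})
        grouped, names = group_attributions(phi, gmap)
        assert names == ["a", "b", "c"]
        # conservation to machine precision (summation association differs)
        np.testing.assert_allclose(grouped.sum(axis=1), phi.sum(axis=1), atol=1e-12)
        # each group equals the plain sum of its own dimensions, exactly
        np.testing.assert_array_equal(grouped[:, 0, :], phi[:, 0:2, :].sum(axis=1))
        np.testing.assert_array_equal(grouped[:, 2, :], phi[:, 4, :])

    def test_constant_feature_gets_zero_attribution(self):
        model, X = self._fitted()
        phi = shapley_attributions(model, X[:6], X[10:40], n_permutations=8, seed=0)
        assert np.abs(phi[:, 4, :]).max() == 0.0

    def test_dimension_mismatch_errors(self):
        gmap = FeatureGroupMap(spans={"a": (0, 3)})
        with pytest.raises(ValueError, match="dimension"):
            group_attributions(np.zeros((2, 5, 2)), gmap)
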