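import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrlymph.classification import (
    CVConfig,
    Scenario,
    allocate_test_counts,
    fit_final_and_evaluate,
    grid_search_cv,
    random_oversample,
    run_scenario,
    stratified_split,
)
from bcrlymph.errors import ValidationError
from bcrlymph.featurization import build_schema
from bcrlymph.synthetic_cohort import CohortConfig, generate_cohort

from conftest import fast_preset


def labels_series(sizes: dict[str, int]) -> pd.Series:
    ids, labels = [], []
    for cls, n in sizes.items():
        for i in range(n):
            ids.append(f"{cls}_{i}")
            labels.append(cls)
    return pd.Series(labels, index=ids)


class TestStratifiedSplit:
    def test_cohort_sized_split_allocation(self):
        sizes = {"HD": 291, "NLPBL": 90, "DLBCL": 182, "CLL": 348}
        counts = allocate_test_counts(sizes, 0.2)
        assert counts == {"HD": 58, "NLPBL": 18, "DLBCL": 37, "CLL": 70}
        plan = stratified_split(labels_series(sizes), 0.2, seed=0)
        assert {c: len(v) for c, v in plan.test_ids.items()} == counts
        assert {c: len(v) for c, v in plan.train_ids.items()} == {
            "HD": 233, "NLPBL": 72, "DLBCL": 145, "CLL": 278
        }

    def test_largest_remainder_hand_example(self):
        assert allocate_test_counts({"A": 6, "B": 4}, 0.25) == {"A": 2, "B": 1}

    def test_single_class(self):
        plan = stratified_split(labels_series({"A": 10}), 0.2, seed=1)
        assert len(plan.test) == 2
        assert len(plan.train) == 8

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            allocate_test_counts({"A": 5, "B": 0}, 0.2)

    def test_deterministic_given_seed(self):
        labels = labels_series({"A": 20, "B": 10})
        a = stratified_split(labels, 0.2, seed=3)
        b = stratified_split(labels, 0.2, seed=3)
        assert a.test == b.test
        assert stratified_split(labels, 0.2, seed=4).test != a.test

    @settings(max_examples=200, deadline=None)
    @given(
        sizes=st.dictionaries(
            st.sampled_from(["A", "B", "C", "D", "E"]),
            st.integers(min_value=1, max_value=400),
            min_size=1, max_size=5,
        ),
        frac=st.sampled_from([0.1, 0.2, 0.25, 0.33]),
        seed=st.integers(0, 1000),
    )
    def test_partition_and_allocation_properties(self, sizes, frac, seed):
        labels = labels_series(sizes)
        plan = stratified_split(labels, frac, seed=seed)
        train, test = set(plan.train), set(plan.test)
        assert train | test == set(labels.index)
        assert train & test == set()
        assert len(test) == int(np.ceil(frac * len(labels)))
        expected = allocate_test_counts(sizes, frac)
        assert {c: len(v) for c, v in plan.test_ids.items()} == expected


class TestRandomOversample:
    def test_equalizes_to_majority(self):
        y = np.repeat(["HD", "NLPBL", "DLBCL", "CLL"], [233, 72, 145, 278])
        idx = random_oversample(y, seed=0)
        _, counts = np.unique(y[idx], return_counts=True)
        assert np.all(counts == 278)
        assert idx.size == 4 * 278

    def test_majority_class_untouched(self):
        y = np.array(["A"] * 5 + ["B"] * 2)
        idx = random_oversample(y, seed=1)
        majority = np.flatnonzero(y == "A")
        assert np.all(np.isin(majority, idx))
        assert np.sum(y[idx] == "A") == 5

    def test_balanced_input_unchanged(self):
        y = np.array(["A", "A", "B", "B"])
        idx = random_oversample(y, seed=2)
        assert sorted(idx) == [0, 1, 2, 3]

    def test_single_class_unchanged(self):
        y = np.array(["A"] * 4)
        assert sorted(random_oversample(y, seed=0)) == [0, 1, 2, 3]


def gaussian_classes(rng, n_per_class, centers, n_features=5):
    X, y = [], []
    for label, center in centers.items():
        pts = rng.normal(0, 1.0, size=(n_per_class, n_features))
        pts[:, 0] += center
        X.append(pts)
        y += [label] * n_per_class
    return np.vstack(X), np.array(y)


class TestGridSearchCV:
    def test_separable_classes_reach_high_f1(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_classes(rng, 30, {"A": -8.0, "B": 8.0})
        res = grid_search_cv(X, y, "logistic", CVConfig(seed=0))
        assert res.best_mean_f1 >= 0.95

    def test_permuted_labels_are_chance_level(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        y = np.array(["A", "B", "C", "D"] * 50)
        res = grid_search_cv(X, y, "logistic", CVConfig(seed=1))
        assert res.best_mean_f1 < 0.40

    def test_k_exceeding_class_count_rejected(self):
        X = np.zeros((5, 2))
        y = np.array(["A", "A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            grid_search_cv(X, y, "logistic", CVConfig(k=3, seed=0))

    def test_unknown_family_rejected(self):
        X = np.zeros((6, 2))
        y = np.array(["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValidationError):
            grid_search_cv(X, y, "svm", CVConfig(seed=0))

    def test_table_covers_full_grid(self):
        rng = np.random.default_rng(2)
        X, y = gaussian_classes(rng, 10, {"A": -2.0, "B": 2.0})
        cfg = CVConfig(seed=0)
        res = grid_search_cv(X, y, "logistic", cfg)
        assert len(res.table) == len(cfg.grids["logistic"])


class TestFinalEvaluation:
    def test_perfect_predictions(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0], [0.0], [10.0]])
        y = np.array(["A", "A", "B", "B", "A", "B"])
        _, report = fit_final_and_evaluate(
            X[:4], y[:4], X[4:], y[4:], "logistic", {"C": 1.0}, seed=0
        )
        assert report.accuracy == 1.0
        assert report.weighted_f1 == 1.0

    def test_hand_computed_confusion_metrics(self):
        # force predictions (A, B, B, B) against truth (A, A, B, B)
        X_train = np.array([[0.0], [1.0], [2.0], [3.0]])
        y_train = np.array(["A", "A", "B", "B"])
        X_test = np.array([[0.0], [2.0], [2.5], [3.0]])
        y_test = np.array(["A", "A", "B", "B"])
        _, report = fit_final_and_evaluate(
            X_train, y_train, X_test, y_test, "logistic", {"C": 100.0}, seed=0
        )
        assert report.precision["A"] == pytest.approx(1.0)
        assert report.recall["A"] == pytest.approx(0.5)
        assert report.f1["A"] == pytest.approx(2 / 3)
        assert report.precision["B"] == pytest.approx(2 / 3)
        assert report.recall["B"] == pytest.approx(1.0)
        assert report.f1["B"] == pytest.approx(0.8)
        assert report.accuracy == pytest.approx(0.75)
        assert report.weighted_f1 == pytest.approx(0.7333, abs=1e-4)

    def test_empty_test_rejected(self):
        X = np.zeros((4, 1))
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            fit_final_and_evaluate(
                X, y, np.zeros((0, 1)), np.array([]), "logistic", {}, seed=0
            )

    def test_unseen_test_class_rejected(self):
        X = np.zeros((4, 1))
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            fit_final_and_evaluate(
                X, y, np.ones((1, 1)), np.array(["C"]), "logistic", {}, seed=0
            )

    def test_supports_sum_to_test_size(self):
        rng = np.random.default_rng(3)
        X, y = gaussian_classes(rng, 20, {"A": -3.0, "B": 0.0, "C": 3.0})
        _, report = fit_final_and_evaluate(
            X[:45], y[:45], X[45:], y[45:], "forest",
            {"n_estimators": 50}, seed=0,
        )
        assert sum(report.support.values()) == 15


@pytest.fixture(scope="module")
def small_cohort():
    presets = {
        "HD": fast_preset("HD", dominance_alpha=1.0, dominance_beta=19.0,
                          richness_range=(80, 120)),
        "NLPBL": fast_preset("NLPBL", dominance_alpha=3.5,
                             dominance_beta=6.5, richness_range=(40, 80)),
        "DLBCL": fast_preset("DLBCL", dominance_alpha=7.5,
                             dominance_beta=2.5, richness_range=(20, 50)),
        "CLL": fast_preset("CLL", dominance_alpha=18.0, dominance_beta=2.0,
                           richness_range=(5, 30)),
    }
    config = CohortConfig(
        counts={c: 12 for c in presets}, seed=5, presets=presets
    )
    reps, _ = generate_cohort(config)
    return reps


class TestRunScenario:
    def test_results_table_shape(self, small_cohort):
        scenario = Scenario(
            "all", ("HD", "NLPBL", "DLBCL", "CLL"), n_values=(1, 2, 3)
        )
        results, reports, models = run_scenario(
            small_cohort, scenario, CVConfig(seed=0), families=("logistic",)
        )
        assert len(results) == 3
        assert set(results.n_clonotypes) == {1, 2, 3}
        assert set(reports) == {("logistic", 1), ("logistic", 2), ("logistic", 3)}

    def test_missing_class_rejected(self, small_cohort):
        scenario = Scenario("bad", ("HD", "XX"), n_values=(1,))
        with pytest.raises(ValidationError, match="XX"):
            run_scenario(small_cohort, scenario, CVConfig(seed=0))

    def test_schema_never_contains_test_only_gene(self, small_cohort):
        """Leakage guard: vocabulary comes from training repertoires only."""
        scenario_classes = ("HD", "CLL")
        reps = [r for r in small_cohort if r.label in scenario_classes]
        labels = pd.Series([r.label for r in reps],
                           index=[r.sample_id for r in reps])
        plan = stratified_split(labels, 0.2, seed=0)
        by_id = {r.sample_id: r for r in reps}
        marker = "IGHV9-MARKER"
        for sid in plan.test:
            by_id[sid].clonotypes.loc[0, "v_gene"] = marker
        schema = build_schema([by_id[s] for s in plan.train], n=3)
        assert marker not in schema.v_vocab

    def test_oversampling_stays_within_fold(self):
        """Duplicated indices produced for a fold's training part never
        reference held-out samples."""
        from sklearn.model_selection import StratifiedKFold

        y = np.array(["A"] * 9 + ["B"] * 3)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        for tr, va in skf.split(np.zeros((12, 1)), y):
            os_idx = tr[random_oversample(y[tr], seed=0)]
            assert set(os_idx) <= set(tr)
            assert not set(os_idx) & set(va)
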