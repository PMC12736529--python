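import numpy as np
import pytest
from hypothesis import given, strategies as st

from hometwin import classify as clf


class TestWindowSpec:
    def test_counts_from_start_enumeration(self):
        """10 s at 100 Hz with 1.3 s windows and 50% overlap gives
        floor((1000-130)/65)+1 = 14 windows."""
        spec = clf.WindowSpec(1.3)
        angles = np.zeros((1000, 2))
        labels = np.zeros(1000, dtype=int)
        rooms = np.full(1000, "study", dtype=object)
        ds = clf.segment_windows(angles, labels, rooms, "s01", spec)
        assert len(ds) == 14

    def test_overlap_fixed_at_half(self):
        with pytest.raises(ValueError, match="50%"):
            clf.WindowSpec(1.0, overlap=0.4)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            clf.WindowSpec(0.01, rate_hz=100.0)

    def test_short_stream_yields_empty_dataset_with_warning(self):
        spec = clf.WindowSpec(1.3)
        with pytest.warns(UserWarning, match="shorter than one window"):
            ds = clf.segment_windows(
                np.zeros((50, 2)), np.zeros(50, int),
                np.full(50, "x", object), "s01", spec,
            )
        assert len(ds) == 0


class TestModalLabel:
    def test_majority(self):
        labels = np.array([0] * 70 + [1] * 60)
        assert clf.modal_label(labels) == 0

    def test_exact_tie_goes_to_earlier_run(self):
        labels = np.array([1] * 65 + [0] * 65)
        assert clf.modal_label(labels) == 1

    def test_window_labels_are_modal(self):
        spec = clf.WindowSpec(1.3)
        labels = np.array([3] * 500 + [7] * 500)
        rooms = np.array(["a"] * 400 + ["b"] * 600, dtype=object)
        ds = clf.segment_windows(np.zeros((1000, 1)), labels, rooms, "s", spec)
        w, step = spec.n_samples, spec.step
        for k, s0 in enumerate(range(0, 1000 - w + 1, step)):
            assert ds.activity[k] == clf.modal_label(labels[s0 : s0 + w])
            assert ds.room[k] == clf.modal_label(rooms[s0 : s0 + w])


class TestFeatures:
    def test_constant_channel(self):
        w = np.full((100, 1), 7.5)
        f = clf.extract_features(w, 100.0)
        assert f[0] == pytest.approx(7.5)
        assert np.allclose(f[1:], 0.0)

    def test_linear_ramp_first_derivative(self):
        t = np.arange(100) / 100.0
        w = (3.0 * t)[:, None]
        f = clf.extract_features(w, 100.0)
        assert f[2] == pytest.approx(3.0)  # d1 mean = slope
        assert f[3] == pytest.approx(0.0, abs=1e-9)  # d1 sd

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(130, 5))
        f = clf.extract_features(w, 100.0)
        expected = []
        for c in range(5):
            x = w[:, c]
            d1 = np.diff(x) * 100.0
            d2 = np.diff(x, 2) * 100.0**2
            expected += [x.mean(), x.std(), d1.mean(), d1.std(), d2.mean(), d2.std()]
        assert np.max(np.abs(f - np.array(expected))) < 1e-9

    def test_vectorized_windows_match_single_window_features(self):
        rng = np.random.default_rng(1)
        angles = rng.normal(size=(400, 3))
        spec = clf.WindowSpec(1.0)
        ds = clf.segment_windows(
            angles, np.zeros(400, int), np.full(400, "x", object), "s", spec
        )
        for k, s0 in enumerate(range(0, 400 - 100 + 1, 50)):
            f = clf.extract_features(angles[s0 : s0 + 100], 100.0)
            assert np.max(np.abs(ds.features[k] - f)) < 1e-9

    def test_nan_rejected(self):
        w = np.zeros((10, 2))
        w[3, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            clf.extract_features(w, 100.0)


def _bruteforce_knn(train_x, train_y, test_x, k):
    """Exhaustive-distance oracle with the documented tie-breaks."""
    sc = clf._Scaler.fit(train_x)
    a, b = sc.transform(train_x), sc.transform(test_x)
    out = np.empty(b.shape[0], dtype=train_y.dtype)
    for i, q in enumerate(b):
        d = np.linalg.norm(a - q, axis=1)
        order = np.lexsort((np.arange(len(d)), d))[:k]
        labels = train_y[order]
        vals, counts = np.unique(labels, return_counts=True)
        winners = set(vals[counts == counts.max()])
        out[i] = next(lab for lab in labels if lab in winners)
    return out


class TestKnn:
    def test_k1_returns_exact_match_label(self):
        x = np.array([[0.0], [10.0]])
        y = np.array([3, 4])
        assert clf.knn_classify(x, y, np.array([[0.0]]), k=1)[0] == 3
        assert clf.knn_classify(x, y, np.array([[2.0]]), k=1)[0] == 3

    def test_matches_exhaustive_oracle_on_200_random_queries(self):
        rng = np.random.default_rng(2)
        train_x = rng.normal(size=(500, 12))
        train_y = rng.integers(0, 19, 500)
        test_x = rng.normal(size=(200, 12))
        for k in (1, 9, 49):
            mine = clf.knn_classify(train_x, train_y, test_x, k=k)
            oracle = _bruteforce_knn(train_x, train_y, test_x, k)
            assert np.array_equal(mine, oracle), k

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            clf.knn_classify(np.empty((0, 2)), np.empty(0, int), np.zeros((1, 2)), 1)

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError):
            clf.knn_classify(np.zeros((3, 2)), np.zeros(3, int), np.zeros((1, 2)), 5)


class TestSvm:
    def test_linearly_separable_training_accuracy(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-5, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        pred = clf.svm_rbf_classify(x, y, x)
        assert np.mean(pred == y) == 1.0

    def test_agrees_with_knn_on_well_separated_classes(self):
        rng = np.random.default_rng(4)
        centers = rng.normal(0, 10, (5, 8))
        x = np.concatenate([c + rng.normal(0, 0.4, (40, 8)) for c in centers])
        y = np.repeat(np.arange(5), 40)
        test = np.concatenate([c + rng.normal(0, 0.4, (20, 8)) for c in centers])
        svm = clf.svm_rbf_classify(x, y, test)
        knn = clf.knn_classify(x, y, test, k=9)
        assert np.mean(svm == knn) >= 0.95

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            clf.svm_rbf_classify(np.zeros((4, 2)), np.zeros(4, int), np.zeros((1, 2)), C=-1.0)


def _toy_dataset(n_subjects=3, per=40, seed=0):
    rng = np.random.default_rng(seed)
    feats, acts, subs = [], [], []
    for s in range(n_subjects):
        for c in range(4):
            feats.append(rng.normal(5.0 * c, 0.2, (per, 3)))
            acts.append(np.full(per, c))
            subs.append(np.full(per, f"s{s:02d}", dtype=object))
    n = n_subjects * 4 * per
    return clf.LabeledWindowDataset(
        features=np.concatenate(feats),
        activity=np.concatenate(acts),
        room=np.full(n, "study", dtype=object),
        subject=np.concatenate(subs),
        start_s=np.arange(n, dtype=float),
        spec=clf.WindowSpec(1.3),
    )


class TestLosoCv:
    def test_fold_count_equals_subjects(self):
        ds = _toy_dataset(4)
        res = clf.loso_cv(ds, {"kind": "knn", "k": 1})
        assert len(res.fold_subjects) == 4

    def test_separable_classes_give_perfect_diagonal(self):
        ds = _toy_dataset()
        res = clf.loso_cv(ds)
        assert res.mean_accuracy == 1.0
        off = res.confusion.counts.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    def test_no_subject_leakage(self):
        """No test window's subject appears in its fold's training set."""
        ds = _toy_dataset()
        for s in sorted(set(ds.subject)):
            test = ds.subject == s
            assert not np.any(ds.subject[~test] == s)
            assert np.all(ds.subject[test] == s)

    def test_window_order_permutation_invariant(self):
        ds = _toy_dataset()
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(ds))
        shuffled = clf.LabeledWindowDataset(
            ds.features[perm], ds.activity[perm], ds.room[perm],
            ds.subject[perm], ds.start_s[perm], ds.spec,
        )
        a = clf.loso_cv(ds)
        b = clf.loso_cv(shuffled)
        assert a.fold_accuracy == b.fold_accuracy
        assert np.array_equal(a.confusion.counts, b.confusion.counts)

    def test_scaler_fit_on_training_folds_only(self):
        """The train-fitted scaler differs from one fit on the test fold —
        i.e. no peeking at test statistics."""
        ds = _toy_dataset()
        test = ds.subject == "s00"
        sc_train = clf._Scaler.fit(ds.features[~test])
        sc_test = clf._Scaler.fit(ds.features[test])
        assert not np.allclose(sc_train.mean, sc_test.mean)

    def test_single_subject_rejected(self):
        ds = _toy_dataset(1)
        with pytest.raises(ValueError):
            clf.loso_cv(ds)


class TestConfusionMatrix:
    def test_row_percentages_sum_to_100(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 19, 500)
        p = rng.integers(0, 19, 500)
        cm = clf.ConfusionMatrix.from_predictions(y, p)
        sums = cm.row_percent.sum(axis=1)
        nonempty = cm.counts.sum(axis=1) > 0
        assert np.allclose(sums[nonempty], 100.0)

    def test_trace_over_total_is_accuracy(self):
        y = np.array([0, 0, 1, 2])
        p = np.array([0, 1, 1, 2])
        cm = clf.ConfusionMatrix.from_predictions(y, p)
        assert cm.overall_accuracy == 0.75


@pytest.fixture(scope="module")
def tiny_streams():
    rng = np.random.default_rng(7)
    streams = {}
    for s in range(2):
        n = 12000  # 120 s at 100 Hz; large enough for the 99-neighbor cell
        angles = np.concatenate(
            [rng.normal(6.0 * c, 4.0, (n // 3, 4)) for c in range(3)]
        )
        labels = np.repeat([0, 1, 2], n // 3)
        rooms = np.full(n, "study", dtype=object)
        streams[f"s{s:02d}"] = (angles, labels, rooms)
    return streams


class TestGridEvaluate:
    def test_table_shape_is_full_grid(self, tiny_streams):
        table = clf.grid_evaluate(tiny_streams)
        assert table.shape == (20, 5)
        assert list(table.columns) == ["KNN5", "KNN9", "KNN49", "KNN99", "SVM"]

    def test_accuracies_bounded_and_best_selected(self, tiny_streams):
        table = clf.grid_evaluate(
            tiny_streams, window_lengths=(0.5, 1.3), knn_ks=(5, 9), include_svm=False
        )
        assert ((table.to_numpy() >= 0) & (table.to_numpy() <= 1)).all()
        best = table.attrs["best"]
        assert best["accuracy"] == table.to_numpy().max()


@given(st.lists(st.integers(min_value=0, max_value=3), min_size=2, max_size=60))
def test_modal_label_is_a_member_with_max_count(labels):
    arr = np.array(labels)
    m = clf.modal_label(arr)
    counts = {v: int((arr == v).sum()) for v in set(labels)}
    assert counts[int(m)] == max(counts.values())
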