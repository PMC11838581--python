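import dataclasses

import numpy as np
import pandas as pd
import pytest

from spanr import (
    Atom, ContactSet, DatasetEntry, EvalReport, PotentialContact,
    ProteinStructure, SpanrClassifier, evaluate, grid_search_thresholds,
    label_entry, load_model, make_feature_frame, mismatch_augment,
    predict_confidence, save_model, spearman_matrix, train_spanr,
)


@pytest.mark.parametrize("tm,expected", [
    (0.51, "consistent"),
    (0.50, "inconsistent"),   # strictly greater than 0.5 required
    (0.31, "inconsistent"),
    (1.0, "consistent"),
])
def test_label_entry(tm, expected):
    assert label_entry(tm) == expected


def test_label_entry_range_check():
    with pytest.raises(ValueError):
        label_entry(1.2)


class TestMismatchAugment:
    def _entries(self, n):
        return [DatasetEntry(entry_id=f"e{i}") for i in range(n)]

    def test_doubles_dataset(self):
        for n in (2, 7, 3085):
            assert len(mismatch_augment(self._entries(n), seed=1)) == 2 * n

    def test_never_pairs_with_self(self):
        entries = self._entries(5)
        for seed in range(1000):
            out = mismatch_augment(entries, seed=seed)
            for orig, twin in zip(entries, out[5:]):
                assert twin.mismatched
                assert twin.donor_id != orig.entry_id

    def test_too_small(self):
        with pytest.raises(ValueError):
            mismatch_augment(self._entries(1), seed=0)


def _cloud_entries(n, rng, center_good=(0.8, 0.1), center_bad=(0.1, 0.8),
                   spread=0.05):
    entries = []
    for k in range(n):
        good = k % 2 == 0
        cx, cy = center_good if good else center_bad
        entries.append(DatasetEntry(
            entry_id=f"c{k}",
            cs=float(np.clip(rng.normal(cx, spread), 0, 1)),
            ds=float(np.clip(rng.normal(cy, spread), 0, 1)),
            tm=0.9 if good else 0.2,
        ))
    return entries


class TestTraining:
    def test_separable_clouds_high_accuracy(self):
        rng = np.random.default_rng(0)
        _, report = train_spanr(_cloud_entries(500, rng), ("CS-DS",),
                                split_seed=1)
        assert report.balanced_accuracy >= 99.0

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(1)
        entries = _cloud_entries(2000, rng)
        tms = [e.tm for e in entries]
        rng.shuffle(tms)
        shuffled = [dataclasses.replace(e, tm=t) for e, t in zip(entries, tms)]
        _, report = train_spanr(shuffled, ("CS-DS",), split_seed=2)
        assert 45.0 <= report.balanced_accuracy <= 55.0

    def test_refit_same_seed_identical_report(self):
        rng = np.random.default_rng(2)
        entries = _cloud_entries(200, rng)
        _, r1 = train_spanr(entries, ("CS-DS",), split_seed=3)
        _, r2 = train_spanr(entries, ("CS-DS",), split_seed=3)
        assert r1 == r2

    def test_single_class_rejected(self):
        entries = [DatasetEntry(entry_id=f"x{i}", cs=0.5, ds=0.5, tm=0.9)
                   for i in range(10)]
        with pytest.raises(ValueError):
            train_spanr(entries, ("CS-DS",))

    def test_pae_refuses_mismatched(self):
        entries = [DatasetEntry(entry_id=f"x{i}", cs=0.5, ds=0.5,
                                mean_pae=5.0, long_range_mean_pae=6.0,
                                tm=0.9, mismatched=(i == 0))
                   for i in range(10)]
        with pytest.raises(ValueError, match="PAE"):
            make_feature_frame(entries, ("CS-DS", "PAE"))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    entries = _cloud_entries(400, rng)
    model, _ = train_spanr(entries, ("CS-DS",), split_seed=5)
    return model


class TestConfidence:

    def test_deep_consistent_point(self, fitted):
        assert predict_confidence(fitted, {"cs": 0.8, "ds": 0.1}) > 0.9

    def test_symmetric_point_near_half(self):
        # exactly mirrored classes: swapping (cs, ds) maps one class onto
        # the other, so the midpoint on the symmetry axis must score ~0.5
        rng = np.random.default_rng(7)
        entries = []
        for k in range(500):
            a = rng.normal(0.8, 0.1)
            b = rng.normal(0.1, 0.1)
            entries.append(DatasetEntry(entry_id=f"g{k}", cs=a, ds=b, tm=0.9))
            entries.append(DatasetEntry(entry_id=f"b{k}", cs=b, ds=a, tm=0.2))
        X, y = make_feature_frame(entries, ("CS-DS",))
        model = SpanrClassifier(random_state=7).fit(X.values, y.values)
        p = model.consistent_proba(np.array([[0.45, 0.45]]))[0]
        assert p == pytest.approx(0.5, abs=0.05)

    def test_missing_feature_named(self, fitted):
        with pytest.raises(KeyError, match="ds"):
            predict_confidence(fitted, {"cs": 0.8})

    def test_serialization_round_trip(self, fitted, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(fitted, path)
        back = load_model(path)
        grid = np.random.default_rng(0).uniform(0, 1, size=(50, 2))
        assert np.allclose(back.consistent_proba(grid),
                           fitted.consistent_proba(grid), atol=1e-12)

    def test_version_check(self, fitted, tmp_path):
        import joblib
        path = tmp_path / "old.joblib"
        joblib.dump({"format_version": 99, "model": fitted}, path)
        with pytest.raises(ValueError, match="version"):
            load_model(path)


class TestEvaluate:
    class _Always:
        def predict(self, X):
            return np.array(["consistent"] * len(np.asarray(X)))

    def test_perfect_classifier(self):
        rng = np.random.default_rng(9)
        entries = _cloud_entries(300, rng)
        model, report = train_spanr(entries, ("CS-DS",), split_seed=9)
        assert report.balanced_accuracy >= 99.0

    def test_always_consistent(self):
        X = np.zeros((10, 2))
        y = np.array(["inconsistent"] * 3 + ["consistent"] * 7)
        report = evaluate(self._Always(), X, y)
        assert report.neg_id_rate == 0.0
        assert report.pos_id_rate == 100.0
        assert report.balanced_accuracy == 50.0
        assert report.total_accuracy == 70.0

    def test_balanced_is_mean_of_rates(self):
        assert EvalReport(60.0, 80.0, 72.0, 70.0).balanced_accuracy == 70.0

    def test_empty_class_undefined(self):
        X = np.zeros((4, 2))
        y = np.array(["consistent"] * 4)
        report = evaluate(self._Always(), X, y)
        assert report.neg_id_rate is None
        assert report.balanced_accuracy is None


class TestSpearman:
    def test_monotone_columns(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x ** 3, "c": -x})
        rho, _ = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho.values), 1.0)

    def test_hand_computed_tie_table(self):
        # ranks of y: [1, 2.5, 2.5, 4, 5] -> rho = 9.5/sqrt(10*9.5)
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 2, 2, 4, 5]})
        rho, _ = spearman_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(9.5 / np.sqrt(95.0))

    def test_constant_column_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "k": [7.0] * 4})
        rho, _ = spearman_matrix(df)
        assert np.isnan(rho.loc["x", "k"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1, 2]}))


def _planted_corpus():
    """Six single-contact entries whose CS–TM concordance peaks at 10 Å."""
    tms = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
    dists = [5.0, 8.0, 9.0, 12.0, 13.0, 20.0]
    corpus = []
    for tm, d in zip(tms, dists):
        positions = {i: [1000.0 * i, 0.0, 0.0] for i in range(1, 12)}
        positions[1] = [0.0, 0.0, 0.0]
        positions[7] = [d, 0.0, 0.0]
        structure = ProteinStructure(
            [Atom(i, "ALA", "CA", "C", p) for i, p in positions.items()])
        contacts = ContactSet(
            by_peak={0: [PotentialContact(0, 1, 7, "HB", 0.0)]}, n_resi=11)
        corpus.append((contacts, structure, tm))
    return corpus


class TestGridSearch:
    def test_single_point_grid(self):
        res = grid_search_thresholds(_planted_corpus(), [12.0], [10.0])
        assert res["eps_cs"] == 12.0 and res["eps_d"] == 10.0

    def test_planted_optimum_recovered(self):
        res = grid_search_thresholds(_planted_corpus(),
                                     [6.0, 10.0, 14.0], [6.0, 10.0, 14.0])
        assert res["eps_cs"] == 10.0
        table = res["cs_table"]
        best_rho = table.loc[table.eps_cs == 10.0, "spearman_cs_tm"].iloc[0]
        assert best_rho == table.spearman_cs_tm.max()

    def test_tie_breaks_toward_smaller(self):
        # 10.5 and 11 separate the same distances -> identical correlations
        res = grid_search_thresholds(_planted_corpus(),
                                     [10.5, 11.0], [10.5, 11.0])
        assert res["eps_cs"] == 10.5
        assert res["eps_d"] == 10.5

    def test_degenerate_corpus(self):
        corpus = [(c, s, 0.5) for c, s, _ in _planted_corpus()]
        with pytest.raises(ValueError, match="constant"):
            grid_search_thresholds(corpus, [10.0], [10.0])
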