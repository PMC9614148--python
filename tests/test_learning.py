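"""Forest importance scores, feature selection and the three classifiers."""

import numpy as np
import pandas as pd
import pytest

from prvarr import learning as L


def _planted_data(rng, n=500, p=10):
    """One perfectly informative feature among pure-noise columns."""
    y = rng.integers(1, 3, n)
    X = rng.standard_normal((n, p))
    X[:, 0] = y * 2.0 + rng.normal(0, 0.1, n)
    cols = [f"f{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestImportance:
    def test_informative_feature_ranks_first_on_both_scores(self, rng):
        X, y = _planted_data(rng)
        tbl = L.rf_importance(X, y, ntree=50, seed=0).table
        assert tbl["mda"].idxmax() == 0
        assert tbl["gini"].idxmax() == 0

    def test_permutation_null_is_flat(self, rng):
        X, y = _planted_data(rng)
        informative = L.rf_importance(X, y, ntree=50, seed=0).table["mda"].max()
        y_null = rng.permutation(y)
        null = L.rf_importance(X, y_null, ntree=50, seed=0).table["mda"]
        assert null.abs().max() * 5.0 <= informative

    def test_one_row_per_feature(self, rng):
        X, y = _planted_data(rng, p=19)
        tbl = L.rf_importance(X, y, ntree=5, seed=0).table
        assert len(tbl) == 19
        assert list(tbl["name"]) == [f"f{i}" for i in range(19)]

    def test_single_class_rejected(self, rng):
        X, _ = _planted_data(rng, n=50)
        with pytest.raises(ValueError):
            L.rf_importance(X, np.ones(50), ntree=5)

    def test_agreement_of_the_two_scores(self, rng):
        """The two rankings put the planted feature first in nearly every
        seeded run."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, y = _planted_data(r, n=300, p=8)
            tbl = L.rf_importance(X, y, ntree=30, seed=seed).table
            hits += tbl["mda"].idxmax() == 0 and tbl["gini"].idxmax() == 0
        assert hits >= 19


class TestSelect:
    @staticmethod
    def _table(rng, p=19):
        return L.ImportanceTable(
            pd.DataFrame(
                {
                    "name": [f"f{i}" for i in range(p)],
                    "mda": rng.uniform(size=p),
                    "gini": rng.uniform(size=p),
                    "h": 0,
                }
            )
        )

    def test_top_15_of_19(self, rng):
        tbl = self._table(rng)
        names = L.select_features(tbl, 15)
        assert len(names) == 15
        assert tbl.table["h"].sum() == 15
        assert (tbl.table["h"] == 0).sum() == 4
        assert set(tbl.selected()) == set(names)

    def test_keep_all(self, rng):
        tbl = self._table(rng)
        assert len(L.select_features(tbl, 19)) == 19

    def test_k_one_is_combined_rank_argmax(self, rng):
        tbl = self._table(rng)
        (top,) = L.select_features(tbl, 1)
        df = tbl.table
        r = (
            df["mda"].rank(ascending=False) + df["gini"].rank(ascending=False)
        ) / 2.0
        best = df.loc[r.sort_values(kind="stable").index[0], "name"]
        combined_min = r.min()
        candidates = df.loc[r == combined_min]
        expected = candidates.sort_values("mda", ascending=False)["name"].iloc[0]
        assert top == expected

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            L.select_features(self._table(rng), 0)


class TestDecisionTree:
    def test_separable_data_fits_exactly(self, rng):
        X = rng.standard_normal((80, 2))
        y = (X[:, 0] > 0).astype(int) + 1
        model = L.train_dt(X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_xor_is_shattered(self, rng):
        X = rng.uniform(-1, 1, (200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int) + 1
        model = L.train_dt(X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.integers(1, 4, 100)
        a = L.train_dt(X, y, seed=3).predict(X)
        b = L.train_dt(X, y, seed=3).predict(X)
        assert np.array_equal(a, b)


class TestELM:
    def test_output_weights_solve_least_squares(self, rng):
        X = rng.standard_normal((120, 6))
        y = rng.integers(1, 6, 120)
        model = L.train_elm(X, y, n_hidden=40, seed=0)
        core = model.core
        H = core.hidden(model.scaler.transform(model.imputer.transform(X)))
        T = (y[:, None] == core.classes_[None, :]).astype(float)
        lw_ref, *_ = np.linalg.lstsq(H, T, rcond=None)
        res_got = np.linalg.norm(H @ core.LW - T)
        res_ref = np.linalg.norm(H @ lw_ref - T)
        assert res_got == pytest.approx(res_ref, abs=1e-6)

    def test_separated_blobs(self, rng):
        n = 400
        y = rng.integers(1, 3, n)
        X = rng.standard_normal((n, 2)) + 8.0 * (y[:, None] - 1.5)
        tr, te = np.arange(0, n, 2), np.arange(1, n, 2)
        model = L.train_elm(X[tr], y[tr], seed=0)
        assert np.mean(model.predict(X[te]) == y[te]) >= 0.98

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.integers(1, 4, 60)
        a = L.train_elm(X, y, seed=9)
        b = L.train_elm(X, y, seed=9)
        assert np.array_equal(a.core.IW, b.core.IW)
        assert np.array_equal(a.core.B, b.core.B)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_invalid_hidden_size(self, rng):
        with pytest.raises(ValueError):
            L.train_elm(rng.standard_normal((10, 2)), np.arange(10) % 2, n_hidden=0)


class TestBPNN:
    def test_separable_data(self, rng):
        n = 200
        y = rng.integers(1, 3, n)
        X = rng.standard_normal((n, 2)) + 6.0 * (y[:, None] - 1.5)
        model = L.train_bpnn(X, y, seed=0)
        assert np.mean(model.predict(X) == y) >= 0.99

    def test_untrained_net_is_at_chance(self, rng):
        n = 2000
        y = np.repeat(np.arange(1, 6), n // 5)
        X = rng.standard_normal((n, 5)) + y[:, None]
        model = L.train_bpnn(X, y, max_iter=0, seed=1)
        acc = np.mean(model.predict(X) == y)
        assert 0.1 <= acc <= 0.3  # chance is 0.2 on balanced 5-class data

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((80, 3))
        y = rng.integers(1, 3, 80)
        a = L.train_bpnn(X, y, max_iter=20, seed=5)
        b = L.train_bpnn(X, y, max_iter=20, seed=5)
        assert np.array_equal(a.predict(X), b.predict(X))


class TestPredictSchema:
    def test_column_order_is_aligned_by_name(self, rng):
        cols = ["a", "b", "c"]
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=cols)
        y = (X["a"] > 0).astype(int).to_numpy() + 1
        model = L.train_dt(X, y, seed=0)
        shuffled = X[["c", "a", "b"]]
        assert np.array_equal(model.predict(shuffled), model.predict(X))

    def test_missing_feature_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        y = np.arange(30) % 2 + 1
        model = L.train_dt(X, y, seed=0)
        with pytest.raises(ValueError, match="missing feature"):
            model.predict(X.rename(columns={"b": "z"}))

    def test_width_mismatch_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.arange(30) % 2 + 1
        model = L.train_dt(X, y, seed=0)
        with pytest.raises(ValueError):
            model.predict(X[:, :3])

    def test_pure_leaf_tree_reproduces_training_labels(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.integers(1, 5, 60)
        model = L.train_dt(X, y, seed=0)
        assert np.array_equal(model.predict(X), y)

    def test_sentinels_imputed_with_training_medians(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int).to_numpy() + 1
        X.loc[::7, "b"] = np.nan
        model = L.train_dt(X, y, seed=0)
        out = model.predict(X)  # must not raise on NaN cells
        assert out.shape == y.shape
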