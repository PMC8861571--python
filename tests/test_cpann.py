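"""Counter-propagation network: winner selection, training dynamics,
lookup prediction, LOO cross-validation, and map exports."""

import numpy as np
import pandas as pd
import pytest

from fdqsar import cpann
from fdqsar.cpann import TrainingSchedule


def _schedule(epochs=50, **kw):
    return TrainingSchedule(epochs=epochs, **kw)


class TestInit:
    def test_determinism(self):
        a = cpann.init((4, 4), 3, 2, seed=5)
        b = cpann.init((4, 4), 3, 2, seed=5)
        assert np.array_equal(a.kohonen, b.kohonen)
        assert np.array_equal(a.output, b.output)

    def test_single_neuron(self):
        m = cpann.init((1, 1), 2, 1, seed=0)
        assert m.kohonen.shape == (1, 2)

    def test_study_grid_dimensions(self):
        m = cpann.init((14, 14), 2, 6, seed=1)
        assert m.kohonen.shape == (196, 2)
        assert m.output.shape == (196, 6)

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            cpann.init((0, 3), 2, 1, seed=0)


class TestFindWinner:
    def test_single_neuron_always_wins(self):
        m = cpann.init((1, 1), 2, 1, seed=0)
        assert cpann.find_winner(m, [0.3, 0.9]) == (0, 0)

    def test_exact_match(self):
        m = cpann.init((4, 5), 3, 1, seed=2)
        target = m.kohonen[2 * 5 + 3]
        assert cpann.find_winner(m, target) == (2, 3)

    def test_tie_breaks_to_lower_row_major_index(self):
        m = cpann.init((2, 2), 2, 1, seed=0)
        m.kohonen[:] = 0.5  # all neurons equidistant from anything
        assert cpann.find_winner(m, [0.1, 0.9]) == (0, 0)

    def test_length_mismatch(self):
        m = cpann.init((2, 2), 2, 1, seed=0)
        with pytest.raises(ValueError):
            cpann.find_winner(m, [0.1, 0.2, 0.3])

    def test_winner_ignores_output_layer(self):
        m = cpann.init((5, 5), 2, 3, seed=3)
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(20, 2))
        before = [cpann.find_winner(m, x) for x in X]
        m.output = rng.permutation(m.output)
        assert [cpann.find_winner(m, x) for x in X] == before


class TestTrain:
    def test_single_object_converges(self):
        m = cpann.init((1, 1), 2, 2, seed=0)
        x, y = np.array([[0.3, 0.7]]), np.array([[0.2, 0.9]])
        trained = cpann.train(m, x, y, _schedule(100))
        assert np.allclose(trained.output[0], y[0], atol=1e-3)
        assert np.allclose(trained.kohonen[0], x[0], atol=1e-3)

    def test_r0_zero_updates_only_winner(self):
        m = cpann.init((1, 2), 1, 1, seed=4)
        before = m.kohonen.copy()
        x = np.array([[m.kohonen[0, 0] + 1e-3]])  # neuron 0 wins
        trained = cpann.train(m, x, np.array([[0.5]]), _schedule(3, r0=0))
        assert trained.kohonen[1, 0] == before[1, 0]  # loser untouched
        assert trained.kohonen[0, 0] != before[0, 0]

    def test_single_neuron_closed_form(self):
        """With r0=0 and one neuron the output weight is the exponentially
        weighted mean of presented responses (closed form to 1e-10)."""
        sched = _schedule(7, r0=0, eta_max=0.4, eta_min=0.1)
        m = cpann.init((1, 1), 1, 1, seed=9)
        ys = np.array([[0.2], [0.9], [0.4]])
        trained = cpann.train(m, np.full((3, 1), 0.5), ys, sched)
        o = m.output[0, 0]
        for t in range(sched.epochs):
            eta = sched.eta_min + (sched.eta_max - sched.eta_min) * (1 - t / 7)
            for y in ys[:, 0]:
                o = o + eta * (y - o)
        assert trained.output[0, 0] == pytest.approx(o, abs=1e-10)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X, Y = rng.uniform(size=(30, 3)), rng.uniform(size=(30, 2))
        m = cpann.init((6, 6), 3, 2, seed=11)
        a = cpann.train(m, X, Y, _schedule(40))
        b = cpann.train(m, X, Y, _schedule(40))
        assert np.array_equal(a.kohonen, b.kohonen)
        assert np.array_equal(a.output, b.output)

    def test_weights_stay_in_convex_hull(self):
        rng = np.random.default_rng(2)
        X, Y = rng.uniform(0.2, 0.8, (25, 2)), rng.uniform(0.2, 0.8, (25, 1))
        m = cpann.init((5, 5), 2, 1, seed=3)
        trained = cpann.train(m, X, Y, _schedule(60))
        lo = min(m.kohonen.min(), X.min())
        hi = max(m.kohonen.max(), X.max())
        assert trained.kohonen.min() >= lo - 1e-12
        assert trained.kohonen.max() <= hi + 1e-12

    def test_empty_training_set(self):
        m = cpann.init((2, 2), 1, 1, seed=0)
        with pytest.raises(ValueError):
            cpann.train(m, np.empty((0, 1)), np.empty((0, 1)), _schedule())

    def test_two_cluster_topology_preservation(self):
        X, Y, labels = _two_clusters()
        m = cpann.init((8, 8), 2, 1, seed=11)
        trained = cpann.train(m, X, Y, _schedule(80))
        within, between = _winner_distances(trained, X, labels)
        assert within < between


def _two_clusters(n=60, seed=11):
    rng = np.random.default_rng(seed)
    half = n // 2
    a = rng.normal([0.2, 0.2], 0.03, size=(half, 2))
    b = rng.normal([0.8, 0.8], 0.03, size=(n - half, 2))
    X = np.vstack([a, b])
    Y = np.concatenate([np.zeros(half), np.ones(n - half)])[:, None]
    labels = np.array([0] * half + [1] * (n - half))
    return X, Y, labels


def _winner_distances(model, X, labels):
    cells = np.array([cpann.find_winner(model, x) for x in X], dtype=float)
    dists = np.abs(cells[:, None, :] - cells[None, :, :]).max(axis=2)
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(X), dtype=bool)
    return dists[same & off_diag].mean(), dists[~same].mean()


class TestPredict:
    def test_memorized_object(self):
        m = cpann.init((1, 1), 2, 2, seed=0)
        x, y = np.array([[0.3, 0.7]]), np.array([[0.2, 0.9]])
        trained = cpann.train(m, x, y, _schedule(100))
        assert np.allclose(cpann.predict(trained, x[0]), y[0], atol=1e-3)

    def test_piecewise_constant(self):
        rng = np.random.default_rng(5)
        m = cpann.init((3, 3), 2, 1, seed=5)
        trained = cpann.train(
            m, rng.uniform(size=(10, 2)), rng.uniform(size=(10, 1)), _schedule(20)
        )
        x = rng.uniform(size=2)
        x2 = x + 1e-12  # same winner
        assert np.array_equal(cpann.predict(trained, x), cpann.predict(trained, x2))

    def test_denormalization_round_trip(self):
        from fdqsar.dataset_io import normalize

        frame = pd.DataFrame({"y": [10.0, 30.0, 50.0]})
        _, params = normalize(frame)
        m = cpann.init((1, 1), 1, 1, seed=0)
        m.norm_out = params
        m.output[0, 0] = 0.5
        assert cpann.predict(m, [0.3])[0] == pytest.approx(30.0)


class TestLooCv:
    def test_twin_oracle(self):
        """Duplicating every object makes LOO behave like resubstitution."""
        rng = np.random.default_rng(21)
        X = rng.uniform(size=(20, 2))
        Y = (X.sum(axis=1, keepdims=True) + rng.normal(0, 0.02, (20, 1))) / 2
        X2, Y2 = np.repeat(X, 2, axis=0), np.repeat(Y, 2, axis=0)
        sched = _schedule(60)
        cv = cpann.loo_cv(X2, Y2, (7, 7), sched, seed=2)
        m = cpann.train(cpann.init((7, 7), 2, 1, seed=2), X2, Y2, sched)
        preds = cpann.predict_batch(m, X2)
        from fdqsar.regression_stats import pearson_r2

        r2 = pearson_r2(Y2[:, 0], preds[:, 0])
        assert cv.loc["y0", "q2cv"] == pytest.approx(r2, abs=0.05)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            cpann.loo_cv(np.zeros((2, 1)), np.zeros((2, 1)), (2, 2), _schedule(), 0)

    def test_constant_response_error(self):
        X = np.random.default_rng(0).uniform(size=(5, 1))
        with pytest.raises(ValueError, match="constant"):
            cpann.loo_cv(X, np.ones((5, 1)), (2, 2), _schedule(), 0)

    def test_equals_explicit_retraining(self):
        """The batched LOO reproduces literal per-fold retraining."""
        rng = np.random.default_rng(33)
        X = rng.uniform(size=(6, 2))
        Y = rng.uniform(size=(6, 1))
        sched = _schedule(15)
        cv_preds = []
        for i in range(len(X)):
            rest = [j for j in range(len(X)) if j != i]
            m = cpann.train(
                cpann.init((3, 3), 2, 1, seed=4), X[rest], Y[rest], sched
            )
            cv_preds.append(cpann.predict(m, X[i])[0])
        cv = cpann.loo_cv(X, Y, (3, 3), sched, seed=4)
        from fdqsar.regression_stats import pearson_r2

        assert cv.loc["y0", "q2cv"] == pytest.approx(
            pearson_r2(Y[:, 0], np.array(cv_preds)), abs=1e-12
        )


class TestMapsAndSerialization:
    def _trained(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            {
                "a": rng.uniform(0, 10, 20),
                "b": rng.uniform(0, 5, 20),
                "resp": rng.uniform(100, 200, 20),
            },
            index=[f"c{i}" for i in range(20)],
        )
        model, _ = cpann.fit_cpann(
            frame, ["a", "b"], ["resp"], list(frame.index), None,
            (4, 4), _schedule(30), seed=6, loo=False,
        )
        return model, frame

    def test_weight_map_shape_and_range(self):
        model, frame = self._trained()
        grid = cpann.weight_map(model, "resp")
        assert grid.shape == (4, 4)
        lo, hi = frame["resp"].min(), frame["resp"].max()
        span = hi - lo
        assert grid.min() >= lo - span and grid.max() <= hi + span

    def test_weight_map_unknown_plane(self):
        model, _ = self._trained()
        with pytest.raises(KeyError):
            cpann.weight_map(model, "nope")

    def test_weight_map_csv_round_trip(self, tmp_path):
        model, _ = self._trained()
        grid = cpann.weight_map(model, "a")
        p = tmp_path / "map.csv"
        pd.DataFrame(grid).to_csv(p, header=False, index=False)
        back = pd.read_csv(p, header=None, float_precision="round_trip")
        assert np.array_equal(back.to_numpy(), grid)

    def test_top_map_covers_all_ids(self):
        model, frame = self._trained()
        Xn = model.norm_in.apply(frame)
        cells = cpann.top_map(model, Xn.to_numpy(), list(frame.index))
        everything = [i for ids in cells.values() for i in ids]
        assert sorted(everything) == sorted(frame.index)

    def test_duplicate_compounds_share_cell(self):
        model, frame = self._trained()
        Xn = model.norm_in.apply(frame).to_numpy()
        X2 = np.vstack([Xn[0], Xn[0]])
        cells = cpann.top_map(model, X2, ["t1", "t2"])
        assert len(cells) == 1

    def test_save_load_round_trip(self, tmp_path):
        model, _ = self._trained()
        p = tmp_path / "model.json"
        cpann.save_model(model, str(p))
        back = cpann.load_model(str(p))
        assert np.array_equal(back.kohonen, model.kohonen)
        assert np.array_equal(back.output, model.output)
        assert back.input_names == model.input_names
        assert np.array_equal(back.norm_out.scale, model.norm_out.scale)
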