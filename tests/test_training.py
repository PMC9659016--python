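import numpy as np
import pandas as pd
import pytest

from berryopt import FactorialDesign, MLPTopology, ResponseSurfaceSpec, simulate
from berryopt.errors import InvalidInputError, UndefinedMetricError
from berryopt.network import AffineTransform, INPUT_BOUNDS, NetworkWeights, forward
from berryopt.synthdata import RESPONSES
from berryopt.training import (
    DataSplit,
    LMConfig,
    evaluate_fit,
    r2_adj,
    rmse,
    split_dataset,
    topology_search,
    train_lm,
)


class TestRmse:
    def test_identical_vectors_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        assert rmse([1.0, 2.0], [4.0, 5.0]) == pytest.approx(3.0)

    def test_direct_arithmetic(self):
        assert rmse([1.0, 3.0], [2.0, 5.0]) == pytest.approx(np.sqrt(2.5))

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            rmse([1.0], [1.0, 2.0])


class TestR2Adj:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert r2_adj(y, y, k=3) == pytest.approx(1.0)

    def test_mean_predictor_penalised(self):
        act = np.arange(10, dtype=float)
        pred = np.full(10, act.mean())
        # R^2 = 0, so adjusted value is 1 - (N-1)/(N-k-1) = -0.5
        assert r2_adj(pred, act, k=3) == pytest.approx(-0.5)

    def test_matches_bruteforce_recomputation(self, rng):
        act = rng.normal(size=30)
        pred = act + rng.normal(scale=0.3, size=30)
        sse = np.sum((pred - act) ** 2)
        sst = np.sum((act - act.mean()) ** 2)
        expected = 1 - (1 - (1 - sse / sst)) * (30 - 1) / (30 - 3 - 1)
        assert r2_adj(pred, act, k=3) == pytest.approx(expected)

    def test_adjusted_below_unadjusted(self, rng):
        act = rng.normal(size=25)
        pred = act + rng.normal(scale=0.5, size=25)
        r2_plain = 1 - np.sum((pred - act) ** 2) / np.sum((act - act.mean()) ** 2)
        assert r2_adj(pred, act, k=3) <= r2_plain

    def test_undefined_cases(self):
        with pytest.raises(UndefinedMetricError):
            r2_adj([1.0, 2.0], [1.0, 2.0], k=3)
        with pytest.raises(UndefinedMetricError):
            r2_adj(np.zeros(10), np.zeros(10), k=3)


class TestSplitDataset:
    def test_sizes_largest_remainder(self, noisy_table):
        tr, te, va = split_dataset(noisy_table, DataSplit(seed=1))
        assert (len(tr), len(te), len(va)) == (168, 36, 36)

    def test_disjoint_cover(self, noisy_table):
        tr, te, va = split_dataset(noisy_table, DataSplit(seed=5))
        combined = pd.concat([tr, te, va]).sort_values(
            list(noisy_table.columns)).reset_index(drop=True)
        original = noisy_table.sort_values(
            list(noisy_table.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(combined, original)

    def test_all_train_split(self, noisy_table):
        tr, te, va = split_dataset(noisy_table, DataSplit(1.0, 0.0, 0.0))
        assert len(tr) == len(noisy_table) and len(te) == 0 and len(va) == 0

    def test_seeded_reproducibility(self, noisy_table):
        a = split_dataset(noisy_table, DataSplit(seed=9))
        b = split_dataset(noisy_table, DataSplit(seed=9))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_fraction_validation(self):
        with pytest.raises(InvalidInputError):
            DataSplit(0.5, 0.5, 0.5)

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            split_dataset(pd.DataFrame(), DataSplit())


def _random_teacher_table(rng, n_rows=300):
    """Data generated by a random 3-4-4 tansig/pureline teacher network."""
    teacher = NetworkWeights(
        hidden_weights=rng.uniform(-1, 1, (4, 3)),
        hidden_bias=rng.uniform(-1, 1, 4),
        output_weights=rng.uniform(-1, 1, (4, 4)),
        output_bias=rng.uniform(-0.2, 0.2, 4),
        input_transforms=tuple(
            AffineTransform.from_range(lo, hi) for lo, hi in INPUT_BOUNDS
        ),
        # spread outputs onto plausible physical scales
        output_transforms=(
            AffineTransform(200.0, 500.0),
            AffineTransform(2.0, 5.0),
            AffineTransform(1.0, 3.5),
            AffineTransform(0.5, 3.0),
        ),
        topology=MLPTopology(4, "tansig", "pureline"),
    )
    X = np.column_stack([
        rng.uniform(lo, hi, n_rows) for lo, hi in INPUT_BOUNDS
    ])
    out = forward(teacher, X[:, 0], X[:, 1], X[:, 2])
    table = pd.DataFrame(X, columns=["bt_s", "t_c", "v_ms"])
    table["rep"] = 1
    for name in RESPONSES:
        table[name] = out[name]
    return table


class TestTrainLM:
    def test_linear_problem_recovered_exactly(self, rng):
        # pureline everywhere makes the fit a linear least-squares problem;
        # LM converges to machine precision
        X = np.column_stack([rng.uniform(lo, hi, 120) for lo, hi in INPUT_BOUNDS])
        W = rng.normal(size=(4, 3))
        Y = X @ W.T + np.array([1.0, -2.0, 0.5, 3.0])
        table = pd.DataFrame(X, columns=["bt_s", "t_c", "v_ms"])
        table["rep"] = 1
        for j, name in enumerate(RESPONSES):
            table[name] = Y[:, j]
        tr, va = table.iloc[:90], table.iloc[90:]
        net, metrics = train_lm(
            tr, va, MLPTopology(3, "pureline", "pureline"),
            LMConfig(restarts=1, max_epochs=100), seed=0,
        )
        for name in RESPONSES:
            scale = table[name].abs().mean()
            assert metrics.rmse[name] / scale < 1e-6

    def test_teacher_function_recovery(self):
        # function recovery from a noise-free teacher: held-out RMSE < 1e-3
        # in scaled units (weights themselves are not identifiable)
        rng = np.random.default_rng(7)
        table = _random_teacher_table(rng)
        tr, va = table.iloc[:240], table.iloc[240:]
        net, metrics = train_lm(
            tr, va, MLPTopology(4, "tansig", "pureline"),
            LMConfig(restarts=5, max_epochs=400), seed=7,
        )
        for j, name in enumerate(RESPONSES):
            span = net.output_transforms[j].gain * 2
            assert metrics.rmse[name] / span < 1e-3

    def test_epoch_cap_returns_best_so_far(self, noisefree_table):
        from berryopt.training import split_dataset

        tr, te, va = split_dataset(noisefree_table, DataSplit(seed=2))
        net, metrics = train_lm(
            tr, va, MLPTopology(4, "tansig", "pureline"),
            LMConfig(restarts=1, max_epochs=2), seed=2,
        )
        assert all(np.isfinite(v) for v in metrics.rmse.values())

    def test_sklearn_oracle_agrees_on_fit_quality(self):
        # independent fitting oracle: scikit-learn's LBFGS MLP reaches a
        # comparable fit on the same noise-free surface, confirming the
        # problem is learnable to the accuracy our trainer reports
        sklearn = pytest.importorskip("sklearn.neural_network")
        table = simulate(FactorialDesign(), ResponseSurfaceSpec(noise_cv=0.0),
                         seed=55)
        tr, te, va = split_dataset(table, DataSplit(seed=55))
        net, metrics = train_lm(
            tr, va, MLPTopology(8, "tansig", "pureline"),
            LMConfig(restarts=3, max_epochs=300), seed=55,
        )
        ours = evaluate_fit(net, te).r2_adj

        X = tr[["bt_s", "t_c", "v_ms"]].to_numpy()
        Xte = te[["bt_s", "t_c", "v_ms"]].to_numpy()
        lo, hi = INPUT_BOUNDS[:, 0], INPUT_BOUNDS[:, 1]
        Xs, Xtes = (2 * (X - lo) / (hi - lo) - 1), (2 * (Xte - lo) / (hi - lo) - 1)
        for name in RESPONSES:
            y = tr[name].to_numpy()
            mlp = sklearn.MLPRegressor(
                hidden_layer_sizes=(8,), activation="tanh", solver="lbfgs",
                max_iter=3000, random_state=0, alpha=0.0,
            ).fit(Xs, (y - y.mean()) / y.std())
            pred = mlp.predict(Xtes) * y.std() + y.mean()
            oracle = r2_adj(pred, te[name].to_numpy(), k=3)
            assert ours[name] > min(0.99, oracle - 0.01)


class TestTopologySearch:
    def test_report_covers_grid(self, noisefree_table):
        grid = (MLPTopology(2, "tansig", "pureline"),
                MLPTopology(4, "tansig", "pureline"))
        report, best = topology_search(
            noisefree_table, grid, DataSplit(seed=3),
            LMConfig(restarts=1, max_epochs=60), seed=3,
        )
        assert len(report) == 2
        assert best in grid

    def test_dominant_row_selected(self, noisefree_table):
        # a clearly better cell (more neurons, sane output activation) wins
        # over logsig output, which cannot reach [-1, 1]-scaled targets
        grid = (MLPTopology(6, "tansig", "pureline"),
                MLPTopology(6, "tansig", "logsig"))
        report, best = topology_search(
            noisefree_table, grid, DataSplit(seed=4),
            LMConfig(restarts=2, max_epochs=120), seed=4,
        )
        assert best.output_activation == "pureline"

    def test_default_grid_is_16_cells(self):
        from berryopt.network import DEFAULT_TOPOLOGY_GRID

        assert len(DEFAULT_TOPOLOGY_GRID) == 16

    def test_empty_grid_rejected(self, noisefree_table):
        with pytest.raises(InvalidInputError):
            topology_search(noisefree_table, ())
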