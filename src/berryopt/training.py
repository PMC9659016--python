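"""Network training: data split, fit metrics, Levenberg-Marquardt, topology search.

Training minimises the summed squared error over all four responses in
scaled space with a damped Gauss-Newton (Levenberg-Marquardt) loop: the
damping factor mu is increased when a step is rejected and decreased when
accepted, so accepted training error is nonincreasing.  Early stopping
monitors a held-out validation set.  The topology search trains each cell
of a (hidden width x hidden activation x output activation) grid with
random restarts and picks the topology whose *worst* response-wise
adjusted R^2 on the test set is best — the "all responses must fit" rule
used to select the published 3-8-4 tansig/pureline network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DivergenceError, InvalidInputError, UndefinedMetricError
from .network import (
    INPUT_BOUNDS,
    RESPONSE_NAMES,
    AffineTransform,
    DEFAULT_TOPOLOGY_GRID,
    MLPTopology,
    NetworkWeights,
    activation,
    activation_derivative,
    forward,
)

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "r2_adj",
    "DataSplit",
    "split_dataset",
    "LMConfig",
    "train_lm",
    "FitMetrics",
    "evaluate_fit",
    "topology_search",
]


def rmse(pred, act) -> float:
    """Root-mean-square error between prediction and actual vectors."""
    pred = np.asarray(pred, dtype=float)
    act = np.asarray(act, dtype=float)
    if pred.shape != act.shape:
        raise InvalidInputError(f"length mismatch: {pred.shape} vs {act.shape}")
    if pred.size == 0:
        raise InvalidInputError("need at least one observation")
    return float(np.sqrt(np.mean(np.square(pred - act))))


def r2_adj(pred, act, k: int = 3) -> float:
    """Adjusted coefficient of determination.

    ``1 - (1 - R^2) (N-1)/(N-k-1)`` with ``R^2 = 1 - SSE/SST``; ``k`` is
    the number of predictors (three process factors by default).
    """
    pred = np.asarray(pred, dtype=float)
    act = np.asarray(act, dtype=float)
    if pred.shape != act.shape:
        raise InvalidInputError(f"length mismatch: {pred.shape} vs {act.shape}")
    n = pred.size
    if n <= k + 1:
        raise UndefinedMetricError(f"adjusted R^2 undefined for N={n}, k={k}")
    sst = float(np.sum(np.square(act - act.mean())))
    if sst == 0:
        raise UndefinedMetricError("actuals have zero variance")
    sse = float(np.sum(np.square(pred - act)))
    return 1.0 - (sse / sst) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class DataSplit:
    """Random row-level partition fractions (train / test / validation)."""

    train: float = 0.70
    test: float = 0.15
    validation: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train, self.test, self.validation)
        if any(f < 0 for f in fr) or self.train <= 0:
            raise InvalidInputError("fractions must be nonnegative, train > 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise InvalidInputError(f"fractions must sum to 1, got {sum(fr)}")


def split_dataset(table: pd.DataFrame, split: DataSplit | None = None):
    """Shuffle rows and partition into (train, test, validation) tables.

    Subset sizes follow largest-remainder rounding of the fractions, so
    they always sum to the table length.  The shuffle is seeded and
    reproducible; replicate rows are split independently (row level).
    """
    split = split or DataSplit()
    n = len(table)
    if n == 0:
        raise InvalidInputError("cannot split an empty table")
    fracs = np.array([split.train, split.test, split.validation])
    ideal = fracs * n
    sizes = np.floor(ideal).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(ideal - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    rng = np.random.default_rng(split.seed)
    perm = rng.permutation(n)
    bounds = np.cumsum(sizes)
    idx = np.split(perm, bounds[:-1])
    return tuple(table.iloc[i].reset_index(drop=True) for i in idx)


@dataclass(frozen=True)
class LMConfig:
    """Levenberg-Marquardt hyperparameters (all unitless).

    mu0/mu_factor/mu_max : initial damping, its up/down factor and overflow
        cap; max_epochs caps iterations; grad_tol stops on a small gradient;
        patience stops after that many consecutive validation-error
        increases; init_scale is the half-width of the uniform weight
        initialisation; restarts is the number of random restarts kept-best.
    """

    mu0: float = 1e-3
    mu_factor: float = 10.0
    mu_max: float = 1e10
    max_epochs: int = 1000
    grad_tol: float = 1e-7
    patience: int = 6
    init_scale: float = 0.5
    restarts: int = 5


def _pack(hw, hb, ow, ob):
    return np.concatenate([hw.ravel(), hb, ow.ravel(), ob])


def _unpack(theta, n_hidden):
    i = 0
    hw = theta[i:i + n_hidden * 3].reshape(n_hidden, 3); i += n_hidden * 3
    hb = theta[i:i + n_hidden]; i += n_hidden
    ow = theta[i:i + 4 * n_hidden].reshape(4, n_hidden); i += 4 * n_hidden
    ob = theta[i:i + 4]
    return hw, hb, ow, ob


def _forward_scaled(theta, Xs, topo: MLPTopology):
    hw, hb, ow, ob = _unpack(theta, topo.hidden_neurons)
    F = activation(Xs @ hw.T + hb, topo.hidden_activation)
    G = activation(F @ ow.T + ob, topo.output_activation)
    return F, G


def _residual_jacobian(theta, Xs, Ys, topo: MLPTopology):
    """Residuals (N*4,) and Jacobian (N*4, P) of the scaled-space fit."""
    n_hidden = topo.hidden_neurons
    hw, hb, ow, ob = _unpack(theta, n_hidden)
    F, G = _forward_scaled(theta, Xs, topo)
    N = Xs.shape[0]
    r = (G - Ys).ravel()

    Gp = activation_derivative(G, topo.output_activation)      # (N, 4)
    Fp = activation_derivative(F, topo.hidden_activation)      # (N, n)
    P = theta.size
    J = np.empty((N, 4, P))
    # back-prop factor into hidden pre-activations: (N, 4, n)
    back = Gp[:, :, None] * ow[None, :, :] * Fp[:, None, :]
    i = 0
    J[:, :, i:i + n_hidden * 3] = (back[:, :, :, None] * Xs[:, None, None, :]).reshape(
        N, 4, n_hidden * 3
    ); i += n_hidden * 3
    J[:, :, i:i + n_hidden] = back; i += n_hidden
    # output weights: dG_k/dow[k, j] = Gp_k * F_j, zero for other output rows
    ow_block = np.zeros((N, 4, 4, n_hidden))
    kk = np.arange(4)
    ow_block[:, kk, kk, :] = Gp[:, :, None] * F[:, None, :]
    J[:, :, i:i + 4 * n_hidden] = ow_block.reshape(N, 4, 4 * n_hidden); i += 4 * n_hidden
    ob_block = np.zeros((N, 4, 4))
    ob_block[:, kk, kk] = Gp
    J[:, :, i:i + 4] = ob_block
    return r, J.reshape(N * 4, P)


def _lm_fit(Xs, Ys, Xv, Yv, topo: MLPTopology, config: LMConfig, rng):
    """One LM run from a random init; returns (theta_best, val_sse_best)."""
    n_hidden = topo.hidden_neurons
    n_params = n_hidden * 3 + n_hidden + 4 * n_hidden + 4
    theta = rng.uniform(-config.init_scale, config.init_scale, n_params)

    def val_sse(th):
        _, Gv = _forward_scaled(th, Xv, topo)
        return float(np.sum(np.square(Gv - Yv)))

    r, J = _residual_jacobian(theta, Xs, Ys, topo)
    loss = float(r @ r)
    if not np.isfinite(loss):
        raise DivergenceError("non-finite loss at initialisation")
    mu = config.mu0
    best_theta, best_val = theta.copy(), val_sse(theta)
    val_increases = 0
    prev_val = best_val
    for epoch in range(config.max_epochs):
        g = J.T @ r
        if np.max(np.abs(g)) < config.grad_tol:
            break
        H = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                step = np.linalg.solve(H + mu * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                mu *= config.mu_factor
                continue
            cand = theta + step
            r_new, J_new = _residual_jacobian(cand, Xs, Ys, topo)
            loss_new = float(r_new @ r_new)
            if not np.isfinite(loss_new):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}; last mu={mu}"
                )
            if loss_new < loss:
                theta, r, J, loss = cand, r_new, J_new, loss_new
                mu = max(mu / config.mu_factor, 1e-20)
                accepted = True
                break
            mu *= config.mu_factor
        if not accepted:  # damping overflow
            break
        v = val_sse(theta)
        if v < best_val:
            best_val, best_theta = v, theta.copy()
        val_increases = val_increases + 1 if v > prev_val else 0
        prev_val = v
        if val_increases >= config.patience:
            break
    else:
        logger.warning(
            "LM stopped at the epoch cap (%d); returning best-so-far weights",
            config.max_epochs,
        )
    return best_theta, best_val


@dataclass(frozen=True)
class FitMetrics:
    """Per-response RMSE and adjusted R^2 (physical units) plus N and k."""

    rmse: dict
    r2_adj: dict
    N: int
    k: int = 3

    def worst_r2(self) -> float:
        return min(self.r2_adj.values())


def _tables_to_arrays(table: pd.DataFrame):
    X = table[["bt_s", "t_c", "v_ms"]].to_numpy(dtype=float)
    Y = table[list(RESPONSE_NAMES)].to_numpy(dtype=float)
    return X, Y


def evaluate_fit(net: NetworkWeights, table: pd.DataFrame, k: int = 3) -> FitMetrics:
    """RMSE and adjusted R^2 of a network on an experiment table."""
    X, Y = _tables_to_arrays(table)
    pred = forward(net, X[:, 0], X[:, 1], X[:, 2], check_domain=False)
    return FitMetrics(
        rmse={name: rmse(pred[name], Y[:, j]) for j, name in enumerate(RESPONSE_NAMES)},
        r2_adj={
            name: r2_adj(pred[name], Y[:, j], k=k)
            for j, name in enumerate(RESPONSE_NAMES)
        },
        N=len(table),
        k=k,
    )


def train_lm(
    train_table: pd.DataFrame,
    val_table: pd.DataFrame,
    topology: MLPTopology | None = None,
    config: LMConfig | None = None,
    seed: int = 0,
) -> tuple[NetworkWeights, FitMetrics]:
    """Train a 3-n-4 network on an experiment table.

    Inputs are scaled to [-1, 1] over the optimization bounds; outputs to
    [-1, 1] over the training-data range of each response.  Runs
    ``config.restarts`` random restarts and keeps the one with the lowest
    validation error.  Returns the trained network and its validation-set
    fit metrics in physical units.
    """
    topology = topology or MLPTopology()
    config = config or LMConfig()
    if len(train_table) == 0 or len(val_table) == 0:
        raise InvalidInputError("train and validation tables must be nonempty")
    in_tr = tuple(AffineTransform.from_range(lo, hi) for lo, hi in INPUT_BOUNDS)
    X, Y = _tables_to_arrays(train_table)
    Xv, Yv = _tables_to_arrays(val_table)
    out_tr = []
    for j in range(4):
        lo, hi = float(Y[:, j].min()), float(Y[:, j].max())
        if lo >= hi:
            raise InvalidInputError(f"response {RESPONSE_NAMES[j]} is constant")
        out_tr.append(AffineTransform.from_range(lo, hi))
    Xs = np.column_stack([in_tr[i].scale(X[:, i]) for i in range(3)])
    Xvs = np.column_stack([in_tr[i].scale(Xv[:, i]) for i in range(3)])
    Ys = np.column_stack([out_tr[j].scale(Y[:, j]) for j in range(4)])
    Yvs = np.column_stack([out_tr[j].scale(Yv[:, j]) for j in range(4)])

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, config.restarts)):
        theta, val = _lm_fit(Xs, Ys, Xvs, Yvs, topology, config, rng)
        if best is None or val < best[1]:
            best = (theta, val)
    hw, hb, ow, ob = _unpack(best[0], topology.hidden_neurons)
    net = NetworkWeights(
        hidden_weights=hw,
        hidden_bias=hb,
        output_weights=ow,
        output_bias=ob,
        input_transforms=in_tr,
        output_transforms=tuple(out_tr),
        topology=topology,
        provenance=f"trained by Levenberg-Marquardt (seed={seed})",
    )
    return net, evaluate_fit(net, val_table)


def topology_search(
    table: pd.DataFrame,
    grid=DEFAULT_TOPOLOGY_GRID,
    split: DataSplit | None = None,
    config: LMConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, MLPTopology]:
    """Train every topology in the grid and select the best.

    All cells share one random split of ``table``.  The report carries one
    row per topology with per-response RMSE and adjusted R^2 on the train,
    test and validation subsets.  Selection: the topology whose minimum
    adjusted R^2 across the four responses on the *test* set is largest;
    ties go to the smaller hidden layer.  Cells that fail to train are
    recorded with NaN metrics and never selected.
    """
    if len(grid) == 0:
        raise InvalidInputError("topology grid must be nonempty")
    split = split or DataSplit()
    config = config or LMConfig()
    train_t, test_t, val_t = split_dataset(table, split)
    rows = []
    nets = {}
    for cell, topo in enumerate(grid, start=1):
        row = {
            "group": cell,
            "hidden_activation": topo.hidden_activation,
            "hidden_neurons": topo.hidden_neurons,
            "output_activation": topo.output_activation,
        }
        try:
            net, _ = train_lm(train_t, val_t, topo, config, seed=seed + cell)
            for subset, sub_table in (
                ("train", train_t), ("test", test_t), ("val", val_t)
            ):
                m = evaluate_fit(net, sub_table)
                for name in RESPONSE_NAMES:
                    row[f"r2_adj_{name}_{subset}"] = m.r2_adj[name]
                    row[f"rmse_{name}_{subset}"] = m.rmse[name]
            row["min_r2_adj_test"] = min(
                row[f"r2_adj_{name}_test"] for name in RESPONSE_NAMES
            )
            nets[cell] = net
        except (DivergenceError, UndefinedMetricError) as exc:
            logger.warning("topology cell %d failed to train: %s", cell, exc)
            row["min_r2_adj_test"] = np.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    ok = report.dropna(subset=["min_r2_adj_test"])
    if ok.empty:
        raise DivergenceError("every topology cell failed to train")
    # best worst-response fit; ties -> fewer neurons
    ranked = ok.sort_values(
        ["min_r2_adj_test", "hidden_neurons"], ascending=[False, True],
        kind="stable",
    )
    selected = grid[int(ranked.iloc[0]["group"]) - 1]
    return report, selected
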