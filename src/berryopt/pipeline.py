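"""End-to-end study replication: published network -> NSGA-II -> report.

Chains the reconstructed published surrogate into the four-objective
optimizer with the published algorithm settings, post-processes the
resulting front, and compares it against the packaged reference front
and validation fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import RESPONSE_NAMES, forward, published_network
from .nsga2 import NSGA2Config, fast_nondominated_sort, run, surrogate_problem
from .pareto import (
    OBJECTIVE_COLUMNS,
    OBJECTIVE_SENSES,
    load_reference_front,
    load_reference_validation,
    report,
    validation_error,
)

__all__ = ["replicate_study", "grid_scan_check"]


def grid_scan_check(front_F: np.ndarray, problem, points_per_axis: int = 50) -> int:
    """Number of front points dominated by a dense grid scan of the problem.

    Evaluates the surrogate on a regular grid over the decision bounds and
    counts how many front objective vectors are strictly dominated by any
    grid point (0 for a well-converged front).
    """
    axes = [
        np.linspace(lo, hi, points_per_axis) for lo, hi in problem.bounds
    ]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))
    sign = problem.sign()
    FG = problem.evaluate(G) * sign
    Ff = np.asarray(front_F, dtype=float) * sign
    dominated = 0
    for f in Ff:
        no_worse = np.all(FG <= f, axis=1)
        better = np.any(FG < f, axis=1)
        if np.any(no_worse & better):
            dominated += 1
    return dominated


def replicate_study(seed: int = 0, config: NSGA2Config | None = None) -> dict:
    """Re-run the published optimization with the reconstructed network.

    Returns a dict with the optimized front (DataFrame in the reference
    front's layout), the reference-relative comparison report, the
    selected solution under the study's min-DT policy, the surrogate's
    prediction at the published optimum, validation errors against the
    published confirmation experiment, and convergence information.
    """
    config = config or NSGA2Config(front_size=30, seed=seed)
    problem = surrogate_problem()
    result = run(problem, config, seed=seed)
    front = result.to_frame(problem.var_names, problem.obj_names)

    comparison, selected = report(front, reference_id=1, policy="min_DT")

    net = published_network()
    ref_val = load_reference_validation().set_index("kind")
    measured = ref_val.loc["validation"]
    pred = forward(net, float(measured["bt_s"]), float(measured["t_c"]),
                   float(measured["v_ms"]))
    val_errors = {
        name: validation_error(pred[name], float(measured[name]))
        for name in RESPONSE_NAMES
    }

    return {
        "front": front,
        "comparison": comparison,
        "selected": selected,
        "generations": result.generations,
        "history": result.history,
        "prediction_at_reference_optimum": pred,
        "validation_errors_pct": val_errors,
        "reference_front": load_reference_front(),
    }
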