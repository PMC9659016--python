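"""Pareto-front post-processing and reporting.

Reference-relative percentage comparisons between front solutions,
prediction-vs-experiment validation errors, Pearson correlation matrices,
and deterministic solution-selection policies.  Ships the published
30-solution reference front and its validation experiment as packaged
CSV fixtures.

Two distinct denominator conventions are deliberately kept apart:
``relative_change`` is signed and relative to a *reference solution*
(how the study compares front groups), while ``validation_error`` is
absolute and relative to the *measured* value (how it scores predictions
against the confirmation experiment).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .nsga2 import dominates

__all__ = [
    "relative_change",
    "validation_error",
    "pearson_matrix",
    "report",
    "select_solution",
    "load_reference_front",
    "load_reference_validation",
    "mutually_nondominated",
    "certainly_dominated_pairs",
]

OBJECTIVE_COLUMNS = ("dt_min", "sec_mj_kg", "vc_mg_100g", "rc")
OBJECTIVE_SENSES = ("min", "min", "max", "max")
POLICIES = ("min_DT", "min_SEC", "max_VC", "max_RC", "knee")


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def relative_change(ref: float, val: float, decimals: int = 1) -> float:
    """Signed percent change of ``val`` relative to ``ref``: 100*(val-ref)/ref.

    Rounded half-up to ``decimals`` places (one, in the reference study's
    style).  The sign conveys direction: positive means ``val`` exceeds the
    reference.
    """
    if ref == 0:
        raise InvalidInputError("reference value must be nonzero")
    return _round_half_up(100.0 * (val - ref) / ref, decimals)


def validation_error(pred: float, meas: float, decimals: int = 2) -> float:
    """Absolute percent error of a prediction against a measured value.

    ``100*|pred - meas|/meas``, rounded half-up to ``decimals`` places
    (two, matching the validation-table style).  The denominator is always
    the measurement.
    """
    if meas <= 0:
        raise InvalidInputError(f"measured value must be > 0, got {meas}")
    return _round_half_up(100.0 * abs(pred - meas) / meas, decimals)


def pearson_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix over the requested numeric columns.

    Zero-variance columns yield NaN for all their pairs (their diagonal
    stays 1); at least three rows are required.
    """
    columns = list(columns) if columns is not None else list(table.columns)
    data = table[columns]
    if len(data) < 3:
        raise InvalidInputError("need at least 3 rows for a correlation matrix")
    mat = data.corr(method="pearson")
    np.fill_diagonal(mat.values, 1.0)
    return mat


def load_reference_front() -> pd.DataFrame:
    """The published 30-solution Pareto front (packaged fixture)."""
    ref = resources.files("berryopt") / "_data" / "reference_front.csv"
    with ref.open() as fh:
        return pd.read_csv(fh)


def load_reference_validation() -> pd.DataFrame:
    """The published prediction/validation pair at the selected optimum."""
    ref = resources.files("berryopt") / "_data" / "reference_validation.csv"
    with ref.open() as fh:
        return pd.read_csv(fh)


def _objectives(front: pd.DataFrame) -> np.ndarray:
    sign = np.array([1.0 if s == "min" else -1.0 for s in OBJECTIVE_SENSES])
    return front[list(OBJECTIVE_COLUMNS)].to_numpy(dtype=float) * sign


def mutually_nondominated(front: pd.DataFrame) -> bool:
    """True iff no row of the front strictly Pareto-dominates another."""
    F = _objectives(front)
    for i in range(len(F)):
        for j in range(len(F)):
            if i != j and dominates(F[i], F[j]):
                return False
    return True


def certainly_dominated_pairs(front: pd.DataFrame, ulps: np.ndarray | None = None):
    """Dominance pairs that survive printed-precision rounding uncertainty.

    Tabulated objective values are rounded; a value printed with
    resolution u could be anything within +-u/2.  Row i *certainly*
    dominates row j only if i is better than j by more than the combined
    half-ulps in every objective.  Returns the list of (id_i, id_j) pairs
    of certain dominance — empty for a genuinely nondominated printed
    front.  ``ulps`` gives each column's printed resolution (defaults
    inferred per column from the fixture's formatting).
    """
    F = _objectives(front)
    if ulps is None:
        ulps = np.array([0.1, 0.01, 0.01, 0.01])
    ids = front["pareto_id"].to_numpy() if "pareto_id" in front else np.arange(1, len(F) + 1)
    margin = ulps  # half-ulp of i plus half-ulp of j
    pairs = []
    for i in range(len(F)):
        for j in range(len(F)):
            if i == j:
                continue
            no_worse = np.all(F[i] <= F[j] - margin)
            better = np.any(F[i] < F[j] - margin)
            if no_worse and better:
                pairs.append((int(ids[i]), int(ids[j])))
    return pairs


def select_solution(front: pd.DataFrame, policy: str) -> pd.Series:
    """Pick one front row under a named deterministic policy.

    min_DT / min_SEC / max_VC / max_RC pick the extreme of one response
    (first row on ties); ``knee`` maximises the minimum normalized margin
    from the front's worst value across all four objectives.
    """
    if policy not in POLICIES:
        raise InvalidInputError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if len(front) == 0:
        raise InvalidInputError("empty front")
    if policy == "min_DT":
        idx = front["dt_min"].idxmin()
    elif policy == "min_SEC":
        idx = front["sec_mj_kg"].idxmin()
    elif policy == "max_VC":
        idx = front["vc_mg_100g"].idxmax()
    elif policy == "max_RC":
        idx = front["rc"].idxmax()
    else:  # knee
        F = _objectives(front)  # minimised space
        lo, hi = F.min(axis=0), F.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        margin = (hi - F) / span  # 1 = best, 0 = worst per objective
        idx = front.index[int(np.argmax(margin.min(axis=1)))]
    return front.loc[idx]


def report(front: pd.DataFrame, reference_id: int = 1, policy: str = "min_DT"):
    """Reference-relative comparison table plus a selected solution.

    Every row gains the signed percent change of each response versus the
    reference solution (identified by ``pareto_id``); the returned tuple is
    ``(comparison_table, selected_row)``.
    """
    if "pareto_id" not in front.columns:
        front = front.copy()
        front.insert(0, "pareto_id", np.arange(1, len(front) + 1))
    ref_rows = front[front["pareto_id"] == reference_id]
    if ref_rows.empty:
        raise InvalidInputError(f"reference pareto_id {reference_id} not in front")
    ref = ref_rows.iloc[0]
    out = front.copy()
    for col in OBJECTIVE_COLUMNS:
        out[f"{col}_vs_ref_pct"] = [
            relative_change(float(ref[col]), float(v)) for v in front[col]
        ]
    return out, select_solution(front, policy)
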